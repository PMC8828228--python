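"""Multiband image container and flat-field conversion to transmittance."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ShapeMismatchError
from .spectral import BandSet

log = logging.getLogger("amus")


@dataclass
class MultibandImage:
    """Stack of co-registered single-band intensity planes.

    ``planes`` has shape ``(height, width, n_bands)`` with band order
    matching ``band_set`` (ascending wavelength).  Raw frames are in
    arbitrary linear units; after flat-field correction values are
    transmittance fractions in ``[0, 1]`` and ``is_transmittance`` is set.
    ``pixel_pitch_mm`` is the edge length of one (square) pixel.
    """

    planes: np.ndarray
    band_set: BandSet = field(default_factory=BandSet)
    pixel_pitch_mm: float = 0.05
    is_transmittance: bool = False

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3:
            raise ShapeMismatchError("planes must be (height, width, n_bands)")
        if self.planes.shape[2] != len(self.band_set):
            raise ShapeMismatchError(
                f"{self.planes.shape[2]} planes for {len(self.band_set)} bands"
            )
        if np.any(self.planes < 0):
            raise DomainError("intensities must be non-negative")
        if self.pixel_pitch_mm <= 0:
            raise DomainError("pixel_pitch_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.planes.shape[2]

    def pixels(self) -> np.ndarray:
        """Flattened (n_pixels, n_bands) view of the spectra."""
        return self.planes.reshape(-1, self.n_bands)


def transmittance_from_raw(
    raw: MultibandImage, flatfield: MultibandImage
) -> MultibandImage:
    """Per-pixel, per-band ratio ``raw / flatfield``, clipped to ``[0, 1]``.

    The flat-field stack is an image of the empty, illuminated dish; the
    ratio converts arbitrary sensor counts to spectral transmittance.
    Values above 1 (sensor noise) are clipped; the clip count is logged.

    Raises
    ------
    ShapeMismatchError
        If shapes or band sets differ.
    DomainError
        If any flat-field pixel is zero (coordinates are reported).
    """
    if raw.planes.shape != flatfield.planes.shape:
        raise ShapeMismatchError(
            f"raw {raw.planes.shape} vs flatfield {flatfield.planes.shape}"
        )
    if raw.band_set != flatfield.band_set:
        raise ShapeMismatchError("raw and flatfield band sets differ")
    zero = np.argwhere(flatfield.planes == 0)
    if zero.size:
        r, c, b = zero[0]
        raise DomainError(
            f"flat-field is zero at {len(zero)} position(s), "
            f"first at row={r}, col={c}, band={b}"
        )
    ratio = raw.planes / flatfield.planes
    n_clipped = int(np.count_nonzero(ratio > 1.0))
    if n_clipped:
        log.info("transmittance clipping: %d value(s) above 1.0 clipped", n_clipped)
    return MultibandImage(
        planes=np.clip(ratio, 0.0, 1.0),
        band_set=raw.band_set,
        pixel_pitch_mm=raw.pixel_pitch_mm,
        is_transmittance=True,
    )
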