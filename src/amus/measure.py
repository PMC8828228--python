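"""Whole-image segmentation, area quantification, and core-length estimation.

``segment_image`` classifies every pixel of a transmittance stack with the
spectral-angle classifier, optionally suppresses tiny whitish-core specks,
and reports per-class pixel counts and areas in mm².  ``estimate_core_length_mm``
approximates the manual stereomicroscope length measurement by summing
morphological-skeleton path lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

from .errors import DomainError, ShapeMismatchError
from .image import MultibandImage
from .scoring import PathologyScores, consolidate_two_raters
from .spectral import RED_COMPONENT, WHITISH_CORE, ReferenceLibrary, SpectralAngleClassifier

SQRT2 = math.sqrt(2.0)


@dataclass
class SegmentationResult:
    """Per-pixel class labels with per-class pixel counts and areas.

    ``label_mask`` holds indices into ``class_names`` (library declaration
    order).  ``areas_mm2[c] == pixel_counts[c] * pixel_pitch_mm**2`` exactly,
    and counts always sum to the pixel total.
    """

    label_mask: np.ndarray
    class_names: list[str]
    pixel_pitch_mm: float

    def __post_init__(self) -> None:
        self.label_mask = np.asarray(self.label_mask)
        if self.label_mask.ndim != 2:
            raise ShapeMismatchError("label_mask must be 2-D")
        if self.label_mask.size and self.label_mask.max() >= len(self.class_names):
            raise DomainError("label index outside class_names")
        if self.pixel_pitch_mm <= 0:
            raise DomainError("pixel_pitch_mm must be positive")

    @property
    def pixel_counts(self) -> dict[str, int]:
        counts = np.bincount(self.label_mask.ravel(), minlength=len(self.class_names))
        return {name: int(n) for name, n in zip(self.class_names, counts)}

    @property
    def areas_mm2(self) -> dict[str, float]:
        return {
            name: area_mm2(n, self.pixel_pitch_mm)
            for name, n in self.pixel_counts.items()
        }

    def class_mask(self, name: str) -> np.ndarray:
        return self.label_mask == self.class_names.index(name)

    @property
    def whitish_area_mm2(self) -> float:
        return self.areas_mm2[WHITISH_CORE]


@dataclass
class SampleMeasurement:
    """One needle pass: manual core length, imaged core area, outcome, scores."""

    sample_id: str
    group: str  # "isolation" | "no_isolation"
    svwc_length_mm: float
    whitish_area_mm2: float
    diagnosis_success: bool
    scores_e1: PathologyScores | None = None
    scores_e2: PathologyScores | None = None

    def __post_init__(self) -> None:
        if self.group not in ("isolation", "no_isolation"):
            raise DomainError(f"unknown group {self.group!r}")
        if self.svwc_length_mm < 0 or self.whitish_area_mm2 < 0:
            raise DomainError("measurements must be non-negative")
        self.diagnosis_success = bool(self.diagnosis_success)

    @property
    def scores(self) -> PathologyScores | None:
        """Consolidated scores (fieldwise minimum of the two evaluators)."""
        if self.scores_e1 is None or self.scores_e2 is None:
            return None
        return consolidate_two_raters(self.scores_e1, self.scores_e2)


def area_mm2(pixel_count: int, pixel_pitch_mm: float) -> float:
    """Area of ``pixel_count`` square pixels of edge ``pixel_pitch_mm``."""
    if pixel_count < 0:
        raise DomainError("pixel count must be non-negative")
    if pixel_pitch_mm <= 0:
        raise DomainError("pixel pitch must be positive")
    return float(pixel_count) * pixel_pitch_mm**2


def segment_image(
    img: MultibandImage,
    library: ReferenceLibrary,
    min_component_px: int = 16,
    fallback_label: str = RED_COMPONENT,
) -> SegmentationResult:
    """Classify every pixel, then suppress tiny whitish-core components.

    Whitish-core connected components (8-connectivity) smaller than
    ``min_component_px`` are reassigned pixelwise to the runner-up class
    (second-highest similarity), which preserves the pixel-count total.
    ``min_component_px = 0`` disables the filter and reproduces the pure
    per-pixel argmax.
    """
    if not img.is_transmittance:
        raise DomainError("segment_image requires a transmittance image")
    if img.band_set != library.band_set:
        raise ShapeMismatchError("image and library band sets differ")

    clf = SpectralAngleClassifier.from_library(library, fallback_label=fallback_label)
    names = library.class_names
    sims = clf.similarity(img.pixels())  # (n_pixels, n_classes)
    idx = np.argmax(sims, axis=1)
    zero = ~np.isfinite(sims).any(axis=1)
    if np.any(zero):
        idx[zero] = names.index(fallback_label)
    mask = idx.reshape(img.shape)

    core_idx = names.index(WHITISH_CORE)
    if min_component_px > 0:
        core = mask == core_idx
        comps = cc_label(core, connectivity=2)
        sizes = np.bincount(comps.ravel())
        small = np.isin(comps, np.flatnonzero(sizes < min_component_px)) & core
        if np.any(small):
            runner = np.array(sims, copy=True)
            runner[:, core_idx] = -np.inf
            runner_idx = np.argmax(runner, axis=1).reshape(img.shape)
            # zero-norm pixels have all -inf rows: keep the fallback class
            runner_idx[zero.reshape(img.shape)] = names.index(fallback_label)
            mask = mask.copy()
            mask[small] = runner_idx[small]

    return SegmentationResult(
        label_mask=mask.astype(np.int32),
        class_names=list(names),
        pixel_pitch_mm=img.pixel_pitch_mm,
    )


def _skeleton_length_px(skel: np.ndarray) -> float:
    """Path length of a 1-px-wide skeleton in pixel units.

    Axial neighbour pairs contribute 1, diagonal pairs sqrt(2); a diagonal
    pair is skipped when either of its two common 4-neighbours is also on
    the skeleton (the path already runs through that pixel).
    """
    s = skel.astype(bool)
    length = float(np.count_nonzero(s[:, :-1] & s[:, 1:]))  # horizontal
    length += float(np.count_nonzero(s[:-1, :] & s[1:, :]))  # vertical
    # diagonal down-right: common 4-neighbours are right and below
    dr = s[:-1, :-1] & s[1:, 1:] & ~(s[:-1, 1:] | s[1:, :-1])
    dl = s[:-1, 1:] & s[1:, :-1] & ~(s[:-1, :-1] | s[1:, 1:])
    length += SQRT2 * (np.count_nonzero(dr) + np.count_nonzero(dl))
    return length


def estimate_core_length_mm(core_mask: np.ndarray, pixel_pitch_mm: float) -> float:
    """Total centreline length (mm) of the core regions in a binary mask.

    The mask is reduced to its morphological skeleton and the 8-connected
    path length is summed over all components — an approximation of
    measuring each strand with a ruler under the stereomicroscope.  An
    empty mask returns 0.
    """
    if pixel_pitch_mm <= 0:
        raise DomainError("pixel pitch must be positive")
    core_mask = np.asarray(core_mask).astype(bool)
    if not core_mask.any():
        return 0.0
    skel = skeletonize(core_mask)
    length_px = _skeleton_length_px(skel)
    if length_px == 0.0:  # single-pixel components still have extent ~1 px
        length_px = float(np.count_nonzero(skel))
    return length_px * pixel_pitch_mm
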