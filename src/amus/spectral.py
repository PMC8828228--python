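"""Spectral data types and the cosine-similarity pixel classifier.

The imaging device acquires one intensity plane per narrow-band LED
(nine bands, 405-700 nm).  Each pixel's per-band spectral transmittance is
treated as a vector ``A``; reference transmittance vectors ``B`` (whitish
tissue core) and ``C`` (red component: blood and fibrin) are measured once,
and every pixel is assigned to the reference with the highest cosine
similarity.  In remote sensing the same mathematics is called the spectral
angle mapper; its key property is invariance to overall brightness, which is
what suppresses varying blood-film density.

The classifier is exposed as a scikit-learn style estimator,
:class:`SpectralAngleClassifier`; :func:`classify_pixel` is a convenience
wrapper over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import DegenerateInputError, DomainError, ShapeMismatchError

#: Peak wavelengths (nm) of the nine narrow-band LEDs.
DEFAULT_WAVELENGTHS_NM: tuple[int, ...] = (405, 430, 465, 505, 545, 600, 630, 660, 700)

#: Canonical class names for the two segmentation targets.
WHITISH_CORE = "whitish_core"
RED_COMPONENT = "red_component"
BACKGROUND = "background"


@dataclass(frozen=True)
class BandSet:
    """Ordered set of band-center wavelengths in nanometres.

    Wavelengths must be strictly increasing and positive.  The default
    instrument configuration has nine bands between 405 and 700 nm.
    """

    wavelengths_nm: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM

    def __post_init__(self) -> None:
        wl = tuple(float(w) for w in self.wavelengths_nm)
        object.__setattr__(self, "wavelengths_nm", wl)
        if len(wl) == 0:
            raise DomainError("BandSet needs at least one wavelength")
        if any(w <= 0 for w in wl):
            raise DomainError("wavelengths must be positive")
        if any(b <= a for a, b in zip(wl, wl[1:])):
            raise DomainError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return len(self.wavelengths_nm)

    @property
    def as_array(self) -> np.ndarray:
        return np.asarray(self.wavelengths_nm, dtype=float)


@dataclass(frozen=True)
class SpectrumVector:
    """Per-band transmittance fractions aligned to a :class:`BandSet`.

    Values are dimensionless fractions in ``[0, 1]``.
    """

    values: np.ndarray
    band_set: BandSet = field(default_factory=BandSet)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ShapeMismatchError("spectrum must be one-dimensional")
        if len(v) != len(self.band_set):
            raise ShapeMismatchError(
                f"spectrum has {len(v)} values for {len(self.band_set)} bands"
            )
        if np.any(~np.isfinite(v)):
            raise DomainError("spectrum contains non-finite values")
        if np.any(v < 0) or np.any(v > 1):
            raise DomainError("transmittance values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


def _as_vector(a: SpectrumVector | Iterable[float]) -> np.ndarray:
    if isinstance(a, SpectrumVector):
        return a.values
    return np.asarray(a, dtype=float)


def cosine_similarity(
    a: SpectrumVector | Iterable[float], b: SpectrumVector | Iterable[float]
) -> float:
    """Cosine similarity ``dot(a, b) / (|a| |b|)`` between two spectra.

    For non-negative spectra the result lies in ``[0, 1]``; it is symmetric
    and invariant to positive rescaling of either argument.

    Raises
    ------
    ShapeMismatchError
        If the vectors differ in length.
    DegenerateInputError
        If either vector has zero norm.
    """
    va, vb = _as_vector(a), _as_vector(b)
    if va.shape != vb.shape:
        raise ShapeMismatchError(f"length mismatch: {va.shape} vs {vb.shape}")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise DegenerateInputError("cosine similarity undefined for zero-norm vector")
    return float(np.dot(va, vb) / (na * nb))


@dataclass
class ReferenceLibrary:
    """Ordered mapping from class name to reference spectrum.

    Must contain at least the two segmentation targets ``whitish_core`` and
    ``red_component``; an optional ``background`` entry lets callers exclude
    empty-dish pixels from both areas.  Declaration order is preserved and
    defines the tie-break priority of the classifier.
    """

    entries: dict[str, SpectrumVector]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise DomainError("reference library needs at least two classes")
        for required in (WHITISH_CORE, RED_COMPONENT):
            if required not in self.entries:
                raise DomainError(f"reference library must contain {required!r}")
        band_sets = {sv.band_set for sv in self.entries.values()}
        if len(band_sets) != 1:
            raise ShapeMismatchError("all reference spectra must share one band set")
        for name, sv in self.entries.items():
            if sv.norm == 0.0:
                raise DegenerateInputError(f"reference {name!r} has zero norm")

    @property
    def band_set(self) -> BandSet:
        return next(iter(self.entries.values())).band_set

    @property
    def class_names(self) -> list[str]:
        return list(self.entries.keys())

    @property
    def matrix(self) -> np.ndarray:
        """(n_classes, n_bands) array of reference spectra, declaration order."""
        return np.stack([sv.values for sv in self.entries.values()])

    # --- JSON round-trip -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "bands_nm": list(self.band_set.wavelengths_nm),
            "classes": {name: sv.values.tolist() for name, sv in self.entries.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceLibrary":
        payload = json.loads(Path(path).read_text())
        band_set = BandSet(tuple(payload["bands_nm"]))
        entries = {
            name: SpectrumVector(np.asarray(vals, dtype=float), band_set)
            for name, vals in payload["classes"].items()
        }
        return cls(entries)

    @classmethod
    def from_arrays(
        cls, spectra: Mapping[str, Iterable[float]], band_set: BandSet | None = None
    ) -> "ReferenceLibrary":
        bs = band_set or BandSet()
        return cls(
            {name: SpectrumVector(np.asarray(v, float), bs) for name, v in spectra.items()}
        )


class SpectralAngleClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-reference classifier under the cosine (spectral-angle) metric.

    ``fit`` accepts one or more example spectra per class; each class's
    reference direction is the unit-normalised mean of its unit-normalised
    examples, so a library with exactly one spectrum per class reproduces
    plain nearest-reference matching.  ``predict`` assigns each row of ``X``
    to the class of highest cosine similarity.

    Parameters
    ----------
    fallback_label : str
        Class assigned to zero-norm (fully opaque) pixels.  Defaults to
        ``"red_component"``, which never inflates the whitish-core area.

    Attributes
    ----------
    classes_ : ndarray of str
        Class labels in *first-appearance* order of ``y`` (not sorted):
        exact similarity ties resolve to the earliest class, so the order
        is part of the classifier's contract.
    references_ : ndarray, shape (n_classes, n_bands)
        Unit-norm reference directions.
    n_features_in_ : int
    """

    def __init__(self, fallback_label: str = RED_COMPONENT) -> None:
        self.fallback_label = fallback_label

    # --- construction helpers -------------------------------------------
    @classmethod
    def from_library(
        cls, library: ReferenceLibrary, fallback_label: str | None = None
    ) -> "SpectralAngleClassifier":
        """Fit a classifier directly from a :class:`ReferenceLibrary`."""
        fallback = fallback_label if fallback_label is not None else RED_COMPONENT
        clf = cls(fallback_label=fallback)
        X = library.matrix
        y = np.asarray(library.class_names, dtype=object)
        return clf.fit(X, y)

    # --- estimator API ---------------------------------------------------
    def fit(self, X, y) -> "SpectralAngleClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2:
            raise ShapeMismatchError("X must be (n_samples, n_bands)")
        if len(y) != X.shape[0]:
            raise ShapeMismatchError("X and y length mismatch")
        if np.any(X < 0):
            raise DomainError("spectra must be non-negative")
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            raise DegenerateInputError("training spectra must have positive norm")

        # first-appearance order, not sorted: order defines tie-break priority
        _, first_idx = np.unique(y, return_index=True)
        classes = y[np.sort(first_idx)]
        unit = X / norms[:, None]
        refs = np.stack([unit[y == c].mean(axis=0) for c in classes])
        refs /= np.linalg.norm(refs, axis=1)[:, None]

        self.classes_ = classes
        self.references_ = refs
        self.n_features_in_ = X.shape[1]
        return self

    def similarity(self, X) -> np.ndarray:
        """Cosine similarity of each row of ``X`` to each class reference.

        Zero-norm rows get ``-inf`` similarity to every class (they are
        handled by the fallback rule in :meth:`predict`).
        """
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ShapeMismatchError(
                f"expected {self.n_features_in_} bands, got {X.shape[1]}"
            )
        norms = np.linalg.norm(X, axis=1)
        safe = np.where(norms == 0, 1.0, norms)
        sims = (X / safe[:, None]) @ self.references_.T
        sims[norms == 0] = -np.inf
        return sims

    def predict(self, X) -> np.ndarray:
        """Class label of highest similarity for each row of ``X``.

        Ties resolve to the earliest class in ``classes_`` (``argmax``
        returns the first maximum).  Zero-norm rows get ``fallback_label``.
        """
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        sims = self.similarity(X)
        idx = np.argmax(sims, axis=1)
        labels = self.classes_[idx]
        zero = ~np.isfinite(sims).any(axis=1)
        if np.any(zero):
            if self.fallback_label not in self.classes_:
                raise DomainError(
                    f"fallback label {self.fallback_label!r} is not a known class"
                )
            labels = labels.copy()
            labels[zero] = self.fallback_label
        return labels[0] if single else labels

    def _check_fitted(self) -> None:
        if not hasattr(self, "references_"):
            raise DomainError("classifier is not fitted")


def classify_pixel(
    a: SpectrumVector | Iterable[float],
    library: ReferenceLibrary,
    fallback_label: str = RED_COMPONENT,
) -> str:
    """Assign one spectrum to the library class of highest cosine similarity.

    Scale-invariant: ``classify_pixel(k * a) == classify_pixel(a)`` for any
    ``k > 0``.  Zero-norm pixels go to ``fallback_label``.
    """
    clf = SpectralAngleClassifier.from_library(library, fallback_label=fallback_label)
    return str(clf.predict(_as_vector(a)))
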