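"""Readers and writers: TIFF stacks with JSON sidecars, mask PNGs,
measurement CSVs, and JSON reports.

A multiband stack is stored as a multi-page TIFF (one page per band,
ascending wavelength) next to a JSON sidecar of the same basename carrying
the band list, pixel pitch, and the transmittance flag.  Label masks are
single-channel PNGs whose pixel value is the class index (declaration
order of the reference library), with the class list in a sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, SchemaError
from .image import MultibandImage
from .measure import SampleMeasurement, SegmentationResult
from .scoring import PathologyScores
from .spectral import BandSet

_SCORE_FIELDS = ("adequacy", "tumor_content", "blood_contamination")
COHORT_COLUMNS = [
    "sample_id",
    "group",
    "svwc_length_mm",
    "whitish_area_mm2",
    "diagnosis_success",
]


def _sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_stack(path: str | Path, img: MultibandImage) -> None:
    """Write a stack as multi-page TIFF plus JSON sidecar (lossless float64)."""
    path = Path(path)
    pages = np.moveaxis(img.planes, -1, 0)  # (bands, h, w), ascending wavelength
    tifffile.imwrite(path, pages.astype(np.float64))
    sidecar = {
        "bands_nm": list(img.band_set.wavelengths_nm),
        "pixel_pitch_mm": img.pixel_pitch_mm,
        "is_transmittance": img.is_transmittance,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> MultibandImage:
    """Read a multi-page TIFF stack with its JSON sidecar.

    Raises :class:`FormatError` when the sidecar's band count does not
    match the number of TIFF pages.
    """
    path = Path(path)
    sidecar_p = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar_p.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_p}")
    meta = json.loads(sidecar_p.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None, ...]
    if len(meta["bands_nm"]) != pages.shape[0]:
        raise FormatError(
            f"sidecar lists {len(meta['bands_nm'])} bands for a "
            f"{pages.shape[0]}-page TIFF"
        )
    return MultibandImage(
        planes=np.moveaxis(pages, 0, -1),
        band_set=BandSet(tuple(meta["bands_nm"])),
        pixel_pitch_mm=float(meta["pixel_pitch_mm"]),
        is_transmittance=bool(meta.get("is_transmittance", False)),
    )


def write_mask(path: str | Path, result: SegmentationResult) -> None:
    """Write a label mask as an 8-bit PNG (pixel value = class index)."""
    path = Path(path)
    if len(result.class_names) > 255:
        raise FormatError("more than 255 classes cannot be stored in an 8-bit mask")
    iio.imwrite(path, result.label_mask.astype(np.uint8))
    meta = {
        "class_names": result.class_names,
        "pixel_pitch_mm": result.pixel_pitch_mm,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_mask(path: str | Path) -> SegmentationResult:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    mask = np.asarray(iio.imread(path)).astype(np.int32)
    return SegmentationResult(
        label_mask=mask,
        class_names=list(meta["class_names"]),
        pixel_pitch_mm=float(meta["pixel_pitch_mm"]),
    )


def cohort_to_frame(measurements: list[SampleMeasurement]) -> pd.DataFrame:
    """Tabulate a cohort; per-evaluator score columns are suffixed _e1/_e2,
    consolidated (fieldwise-minimum) columns are unsuffixed."""
    rows = []
    for m in measurements:
        row = {
            "sample_id": m.sample_id,
            "group": m.group,
            "svwc_length_mm": m.svwc_length_mm,
            "whitish_area_mm2": m.whitish_area_mm2,
            "diagnosis_success": int(m.diagnosis_success),
        }
        for suffix, scores in (("_e1", m.scores_e1), ("_e2", m.scores_e2), ("", m.scores)):
            if scores is not None:
                for f in _SCORE_FIELDS:
                    row[f"{f}{suffix}"] = getattr(scores, f)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(path: str | Path, measurements: list[SampleMeasurement]) -> None:
    cohort_to_frame(measurements).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[SampleMeasurement]:
    """Read a measurement CSV back into :class:`SampleMeasurement` objects.

    Raises :class:`SchemaError` naming any missing required column, or the
    1-based data row of the first malformed value.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort CSV missing column(s): {', '.join(missing)}")

    has_scores = all(
        f"{f}{s}" in frame.columns for f in _SCORE_FIELDS for s in ("_e1", "_e2")
    )
    measurements = []
    for i, row in frame.iterrows():
        try:
            kwargs = {}
            if has_scores:
                for suffix, key in (("_e1", "scores_e1"), ("_e2", "scores_e2")):
                    kwargs[key] = PathologyScores(
                        **{f: int(row[f"{f}{suffix}"]) for f in _SCORE_FIELDS}
                    )
            measurements.append(
                SampleMeasurement(
                    sample_id=str(row["sample_id"]),
                    group=str(row["group"]),
                    svwc_length_mm=float(row["svwc_length_mm"]),
                    whitish_area_mm2=float(row["whitish_area_mm2"]),
                    diagnosis_success=bool(int(row["diagnosis_success"])),
                    **kwargs,
                )
            )
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"malformed cohort row {i + 1}: {exc}") from exc
    return measurements


def write_report(path: str | Path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def render_report_text(report: dict) -> str:
    """Human-readable rendering of a cohort report."""
    lines = [f"Cohort report (n = {report.get('n_samples', '?')})"]
    for group, d in report.get("by_group", {}).items():
        L, A = d["svwc_length_mm"], d["whitish_area_mm2"]
        lines.append(
            f"  {group:12s} n={d['n']:3d}  "
            f"length {L['median']:.1f} mm (IQR {L['iqr'][0]:.1f}-{L['iqr'][1]:.1f})  "
            f"area {A['median']:.1f} mm2 (IQR {A['iqr'][0]:.1f}-{A['iqr'][1]:.1f})"
        )
    for name, rho in report.get("spearman", {}).items():
        lines.append(f"  Spearman {name}: rho = {rho:.2f}")
    roc = report.get("roc_area")
    if roc:
        lines.append(
            f"  ROC (area vs diagnosis): AUC = {roc['auc']:.2f}, "
            f"Youden cutoff >= {roc['youden_cutoff_mm2']:.1f} mm2 "
            f"(J = {roc['youden_j']:.2f})"
        )
    for key, s in report.get("sensitivity", {}).items():
        lines.append(
            f"  success rate at {key}: {s['numerator']}/{s['denominator']} "
            f"({s['pct']:g}%)"
        )
    return "\n".join(lines) + "\n"
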