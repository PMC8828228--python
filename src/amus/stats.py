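"""Evaluation statistics for measurement cohorts.

ROC analysis with the Youden-index operating cutoff, Spearman rank
correlation, Mann-Whitney U, Fisher's exact test on 2x2 tables, Cohen's
kappa with a large-sample confidence interval, and the report helpers
(printed percentages with half-up rounding, sensitivity at a cutoff).

Conventions: a sample is test-positive when its score is greater than or
equal to the threshold; all p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, DomainError
from .measure import SampleMeasurement


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """Threshold sweep over the observed score values.

    ``sensitivity[i]`` / ``specificity[i]`` use the rule "score >=
    thresholds[i] is positive".  ``auc`` is the trapezoidal area under the
    (FPR, TPR) curve; ``youden_cutoff`` maximises J = sensitivity +
    specificity - 1, ties resolving to the smallest threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float


def roc_with_youden(scores, labels) -> RocResult:
    """ROC curve, AUC and Youden-optimal cutoff for a binary outcome.

    Raises :class:`DegenerateInputError` unless both outcome classes are
    present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DomainError("scores and labels must be equal-length 1-D")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both outcome classes must be present")

    thresholds = np.unique(scores)  # ascending
    # positive test: score >= t
    tp = np.array([(scores[labels] >= t).sum() for t in thresholds], dtype=float)
    tn = np.array([(scores[~labels] < t).sum() for t in thresholds], dtype=float)
    sens = tp / n_pos
    spec = tn / n_neg

    # curve endpoints: t -> -inf gives (FPR, TPR) = (1, 1); t -> +inf gives (0, 0)
    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])
    tpr = np.concatenate([[1.0], sens, [0.0]])
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))

    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first max = smallest threshold on ties
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_cutoff=float(thresholds[best]),
        youden_j=float(j[best]),
    )


def auc_mwu_identity_check(scores, labels, tol: float = 1e-9) -> bool:
    """Cross-validate the ROC AUC against the rank-sum identity.

    The trapezoidal AUC equals the tie-adjusted Mann-Whitney statistic of
    the positive group divided by ``n_pos * n_neg``; returns whether the two
    agree to ``tol``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    auc = roc_with_youden(scores, labels).auc
    u, _ = mann_whitney_u(scores[labels], scores[~labels])
    n1, n0 = labels.sum(), (~labels).sum()
    return abs(auc - u / (n1 * n0)) <= tol


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise DomainError("need two equal-length 1-D vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (statistic of ``x``) with a two-sided p-value.

    Uses the exact permutation distribution when the pooled sample has at
    most 12 observations and no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DomainError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns success/failure."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DomainError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise DomainError("table total must be positive")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    tables (same margins) no more probable than the observed one."""
    arr = table.as_array
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DegenerateInputError("table has an empty margin")
    return float(sps.fisher_exact(arr, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

@dataclass
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float


def cohen_kappa(ratings1, ratings2, categories=None) -> KappaResult:
    """Unweighted Cohen's kappa with a 95% large-sample confidence interval.

    ``kappa = (po - pe) / (1 - pe)`` from the two raters' joint category
    proportions.  The standard error uses the Fleiss-Cohen-Everitt
    large-sample variance of kappa under the alternative; the interval is
    ``kappa +- 1.96 * se`` clipped to [-1, 1].

    Raises :class:`DegenerateInputError` when ``pe == 1`` (both raters
    constant and identical), where kappa is undefined.
    """
    r1 = np.asarray(ratings1)
    r2 = np.asarray(ratings2)
    if r1.shape != r2.shape or r1.ndim != 1 or len(r1) < 2:
        raise DomainError("need two equal-length rating vectors with n >= 2")
    cats = list(categories) if categories is not None else sorted(set(r1) | set(r2))
    index = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    n = len(r1)
    p = np.zeros((k, k))
    for a, b in zip(r1, r2):
        p[index[a], index[b]] += 1.0
    p /= n

    po = float(np.trace(p))
    pi, pj = p.sum(axis=1), p.sum(axis=0)
    pe = float(pi @ pj)
    if pe == 1.0:
        raise DegenerateInputError("kappa undefined: expected agreement is 1")
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt large-sample variance
    diag = np.diag(p)
    term1 = float(np.sum(diag * ((1 - pe) - (pi + pj) * (1 - po)) ** 2))
    off = p.copy()
    np.fill_diagonal(off, 0.0)
    term2 = float((1 - po) ** 2 * np.sum(off * (pj[None, :] + pi[:, None]) ** 2))
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    return KappaResult(
        kappa=float(kappa),
        se=se,
        ci_low=float(max(-1.0, kappa - 1.96 * se)),
        ci_high=float(min(1.0, kappa + 1.96 * se)),
    )


# ---------------------------------------------------------------------------
# Report helpers
# ---------------------------------------------------------------------------

def proportion_pct(numerator: int, denominator: int, decimals: int = 0) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``decimals``.

    Half-up (commercial) rounding matches how clinical tables print
    percentages: 93/120 prints as 78, not banker's-rounded 78 vs 77.5 -> 78.
    """
    if denominator <= 0:
        raise DomainError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise DomainError("numerator must be between 0 and denominator")
    q = Decimal(1).scaleb(-decimals)
    pct = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(q, ROUND_HALF_UP)
    return float(pct)


@dataclass
class SensitivityResult:
    fraction: float
    numerator: int
    denominator: int


def sensitivity_at_cutoff(
    measurements: list[SampleMeasurement], field: str, cutoff: float
) -> SensitivityResult:
    """Diagnostic success rate among samples meeting ``field >= cutoff``.

    ``field`` is ``"svwc_length_mm"`` or ``"whitish_area_mm2"``.
    """
    if field not in ("svwc_length_mm", "whitish_area_mm2"):
        raise DomainError(f"unknown measurement field {field!r}")
    if not measurements:
        raise DomainError("measurement list is empty")
    meeting = [m for m in measurements if getattr(m, field) >= cutoff]
    if not meeting:
        raise DegenerateInputError(f"no sample meets {field} >= {cutoff}")
    num = sum(m.diagnosis_success for m in meeting)
    return SensitivityResult(
        fraction=num / len(meeting), numerator=int(num), denominator=len(meeting)
    )


def _median_iqr(values: np.ndarray) -> dict:
    return {
        "median": float(np.median(values)),
        "iqr": [float(np.percentile(values, 25)), float(np.percentile(values, 75))],
    }


def cohort_report(
    measurements: list[SampleMeasurement],
    extra_area_cutoffs: tuple[float, ...] = (),
    decimals: int = 1,
) -> dict:
    """Summary report of a measurement cohort.

    Medians with IQR by group, length-area and score correlations, the
    area ROC with its Youden cutoff, and success-rate tables at the
    standard operating cutoffs (length >= 11 mm, area >= 8 mm^2) plus any
    user-supplied area cutoffs.
    """
    lengths = np.array([m.svwc_length_mm for m in measurements])
    areas = np.array([m.whitish_area_mm2 for m in measurements])
    success = np.array([m.diagnosis_success for m in measurements], dtype=bool)

    report: dict = {"n_samples": len(measurements)}
    for group in ("isolation", "no_isolation", None):
        sel = np.array(
            [group is None or m.group == group for m in measurements], dtype=bool
        )
        key = group or "all"
        if sel.any():
            report.setdefault("by_group", {})[key] = {
                "n": int(sel.sum()),
                "svwc_length_mm": _median_iqr(lengths[sel]),
                "whitish_area_mm2": _median_iqr(areas[sel]),
            }

    report["spearman"] = {"length_vs_area": spearman_rho(lengths, areas)}
    if all(m.scores is not None for m in measurements):
        adequacy = np.array([m.scores.adequacy for m in measurements], dtype=float)
        if np.ptp(adequacy) > 0:
            report["spearman"]["length_vs_adequacy"] = spearman_rho(lengths, adequacy)
            report["spearman"]["area_vs_adequacy"] = spearman_rho(areas, adequacy)

    if success.any() and not success.all():
        roc = roc_with_youden(areas, success)
        report["roc_area"] = {
            "auc": roc.auc,
            "youden_cutoff_mm2": roc.youden_cutoff,
            "youden_j": roc.youden_j,
        }

    report["sensitivity"] = {}
    for field, cutoff in (
        ("svwc_length_mm", 11.0),
        ("whitish_area_mm2", 8.0),
        *(("whitish_area_mm2", c) for c in extra_area_cutoffs),
    ):
        try:
            s = sensitivity_at_cutoff(measurements, field, cutoff)
        except DegenerateInputError:
            continue
        report["sensitivity"][f"{field}>={cutoff:g}"] = {
            "numerator": s.numerator,
            "denominator": s.denominator,
            "pct": proportion_pct(s.numerator, s.denominator, decimals),
        }
    return report
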