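"""Pathology score data model and two-rater consolidation.

Each specimen is scored by two evaluators on three ordinal scales:

* adequacy (0-5): 0 = no material up to 5 = sufficient, high-quality
  material for histologic interpretation;
* tumor cell content (0-5): binned percentage of tumor nuclei among all
  nuclei (0% -> 0, 1-19% -> 1, 20-39% -> 2, 40-59% -> 3, 60-79% -> 4,
  >=80% -> 5);
* blood contamination (1-3): 1 = significant, 2 = moderate, 3 = minimal.

When the two evaluators disagree, the lower score is adopted (fieldwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .errors import DomainError

_RANGES = {"adequacy": (0, 5), "tumor_content": (0, 5), "blood_contamination": (1, 3)}


@dataclass(frozen=True)
class PathologyScores:
    adequacy: int
    tumor_content: int
    blood_contamination: int

    def __post_init__(self) -> None:
        violations = validate_scores(self)
        if violations:
            raise DomainError("; ".join(violations))


def validate_scores(s) -> list[str]:
    """Return a list of out-of-range field descriptions (empty if ok).

    Accepts any object with the three score attributes; never mutates.
    """
    violations = []
    for name, (lo, hi) in _RANGES.items():
        value = getattr(s, name)
        if not isinstance(value, int) or isinstance(value, bool):
            violations.append(f"{name} must be an integer, got {value!r}")
        elif not lo <= value <= hi:
            violations.append(f"{name}={value} outside [{lo}, {hi}]")
    return violations


def tumor_content_score(tumor_nucleus_pct: float) -> int:
    """Bin a tumor-nucleus percentage (0-100) into the 0-5 ordinal score.

    Exactly 0% scores 0; any positive percentage below 20% scores 1 (any
    tumor present scores at least 1); thereafter 20-point bins with the top
    bin open (>=80% -> 5).
    """
    pct = float(tumor_nucleus_pct)
    if math.isnan(pct) or not 0.0 <= pct <= 100.0:
        raise DomainError(f"percentage {pct!r} outside [0, 100]")
    if pct == 0.0:
        return 0
    if pct < 20.0:
        return 1
    return min(5, 1 + int(pct // 20))


def consolidate_two_raters(s1: PathologyScores, s2: PathologyScores) -> PathologyScores:
    """Fieldwise minimum of two evaluators' scores (lower score adopted)."""
    return PathologyScores(
        **{f.name: min(getattr(s1, f.name), getattr(s2, f.name)) for f in fields(PathologyScores)}
    )
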