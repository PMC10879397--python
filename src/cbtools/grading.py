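"""WHO follicular-lymphoma grading from per-HPF centroblast counts.

Grade I: 0-5 CBs per high-power field; grade II: 6-15; grade III: above
15.  A slide is graded by the arithmetic mean count over its HPFs
(conventionally 10).  Fractional means are compared to the thresholds
directly, without rounding.

Note: one 512x512 patch at 0.12 um/px covers ~61.4 um square, far smaller
than a conventional HPF.  How many patches constitute one counting unit is
a deliberate configuration choice (default: one patch = one unit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["GradeReport", "who_grade", "grade_slide", "tabulate_grades"]

GRADE_I = "I"
GRADE_II = "II"
GRADE_III = "III"

#: labels accepted by :func:`tabulate_grades`
KNOWN_CASE_LABELS = ("1", "2", "3", "3a", "3b")


@dataclass(frozen=True)
class GradeReport:
    hpf_counts: tuple[float, ...]
    mean_count: float
    grade: str


def who_grade(count: float) -> str:
    """Map a CB count (possibly a fractional mean) to a WHO grade."""
    if count < 0:
        raise ValueError("CB count must be non-negative")
    if count <= 5:
        return GRADE_I
    if count <= 15:
        return GRADE_II
    return GRADE_III


def grade_slide(
    hpf_counts: Sequence[float], expected_n: int = 10
) -> GradeReport:
    """Grade a slide from its per-HPF CB counts.

    Warns (does not fail) when the number of fields differs from
    ``expected_n``; raises on an empty sequence or negative counts.
    """
    counts = tuple(float(c) for c in hpf_counts)
    if not counts:
        raise ValueError("need at least one HPF count")
    if any(c < 0 for c in counts):
        raise ValueError("CB counts must be non-negative")
    if len(counts) != expected_n:
        warnings.warn(
            f"grading over {len(counts)} HPFs (convention is {expected_n})",
            stacklevel=2,
        )
    mean = sum(counts) / len(counts)
    return GradeReport(hpf_counts=counts, mean_count=mean, grade=who_grade(mean))


def tabulate_grades(
    case_grades: Sequence[str] | Mapping[str, int],
) -> pd.DataFrame:
    """Tabulate a cohort's case grades with one-decimal percentages.

    Accepts a sequence of per-case labels from ``{"1","2","3","3a","3b"}``
    (or a mapping label -> count) and returns a table with a row per label
    plus the grouped rows ``grades 1-2`` and ``grade 3 group``.
    """
    if isinstance(case_grades, Mapping):
        counts = {str(k): int(v) for k, v in case_grades.items()}
    else:
        counts = {}
        for g in case_grades:
            counts[str(g)] = counts.get(str(g), 0) + 1
    unknown = sorted(set(counts) - set(KNOWN_CASE_LABELS))
    if unknown:
        raise ValueError(f"unknown grade labels: {unknown}")
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no cases to tabulate")

    rows = {}
    for label in KNOWN_CASE_LABELS:
        c = counts.get(label, 0)
        rows[label] = {"count": c, "percent": round(100.0 * c / n, 1)}
    low = counts.get("1", 0) + counts.get("2", 0)
    high = counts.get("3", 0) + counts.get("3a", 0) + counts.get("3b", 0)
    rows["grades 1-2"] = {"count": low, "percent": round(100.0 * low / n, 1)}
    rows["grade 3 group"] = {"count": high, "percent": round(100.0 * high / n, 1)}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["count"] = table["count"].astype(int)
    return table
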