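"""The 6-point cardiovascular risk scale over Agatston scores.

Ordinal categories 0..5 correspond to Agatston intervals 0, 1-10, 11-100,
101-400, 401-1000 and > 1000. Agatston totals are non-negative reals, so the
integer interval labels are embedded as half-open real intervals [1, 11),
[11, 101), [101, 401), [401, 1001), [1001, inf); scores below 1 are category
0, consistent with the CAC-positive cut-off (total >= 1).
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np

__all__ = ["RiskCategory", "CATEGORY_LABELS", "categorize", "categorize_cohort"]

CATEGORY_LABELS = ("0", "1-10", "11-100", "101-400", "401-1000", ">1000")
_EDGES = np.array([1.0, 11.0, 101.0, 401.0, 1001.0])


class RiskCategory(NamedTuple):
    ordinal: int
    label: str


def categorize(score: float) -> int:
    """Ordinal risk category (0..5) of an Agatston score."""
    if score < 0:
        raise ValueError(f"Agatston score must be non-negative, got {score}")
    return int(np.searchsorted(_EDGES, score, side="right"))


def risk_category(score: float) -> RiskCategory:
    """Category with its Agatston interval label."""
    c = categorize(score)
    return RiskCategory(c, CATEGORY_LABELS[c])


def categorize_cohort(scores: Iterable[float]) -> np.ndarray:
    """Per-category subject counts (length 6) of a list of Agatston totals."""
    counts = np.zeros(6, dtype=int)
    for s in scores:
        counts[categorize(s)] += 1
    return counts
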