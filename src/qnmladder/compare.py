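"""Response categorization and model-to-model agreement scoring.

Tallies over the simulation ensemble are reduced to four categories by a
majority rule: a direction (or neutrality) wins outright with more than
60% of runs; otherwise the response is *mixed*, optionally with a *lean*
when one direction drew more than 30% (but under 60%) of runs and beat
the other.  Pairs of categories are scored on a ±1 / ±0.5 / 0 point
scheme, and whole models are compared by the percentage of elements with
identical category labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qnm import ResponseTally

__all__ = [
    "ResponseCategory",
    "AgreementScore",
    "categorize",
    "categorize_tally",
    "score_pair",
    "model_agreement",
]

MAJORITY = 0.6
LEAN = 0.3

POSITIVE = "positive"
NEGATIVE = "negative"
NEUTRAL = "neutral"
MIXED = "mixed"
LABELS = (POSITIVE, NEGATIVE, NEUTRAL, MIXED)
LEANS = (POSITIVE, NEGATIVE, "none")


@dataclass(frozen=True)
class ResponseCategory:
    label: str
    lean: str = "none"  # meaningful only when label == "mixed"
    n_pos: int = 0
    n_neg: int = 0
    n_neutral: int = 0

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.lean not in LEANS:
            raise ValueError(f"unknown lean {self.lean!r}")

    @property
    def directional(self) -> bool:
        return self.label in (POSITIVE, NEGATIVE)

    @property
    def direction(self) -> int:
        if self.label == POSITIVE:
            return 1
        if self.label == NEGATIVE:
            return -1
        return 0

    @property
    def lean_direction(self) -> int:
        if self.label != MIXED:
            return 0
        if self.lean == POSITIVE:
            return 1
        if self.lean == NEGATIVE:
            return -1
        return 0


@dataclass(frozen=True)
class AgreementScore:
    elements: tuple[str, ...]
    points: np.ndarray  # per element, in {−1, −0.5, 0, +0.5, +1}
    total: float
    percent: float  # 0–100, identical-label fraction
    percent_with_leans: float  # lean matching the other model's direction also counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"element": self.elements, "points": self.points})


# ---------------------------------------------------------------------------


def categorize(
    n_pos: int, n_neg: int, n_neutral: int, n_sims: int = 1000
) -> ResponseCategory:
    """Majority-rule category for one element's outcome counts.

    Thresholds scale with ``n_sims``: direction/neutral labels need a
    strict majority above ``0.6·n_sims``; a lean needs strictly between
    ``0.3·n_sims`` and ``0.6·n_sims`` runs and more than the opposite
    direction.  Exactly 60% is mixed.
    """
    if n_pos + n_neg + n_neutral != n_sims:
        raise ValueError(
            f"counts ({n_pos}, {n_neg}, {n_neutral}) do not sum to n_sims={n_sims}"
        )
    hi = MAJORITY * n_sims
    lo = LEAN * n_sims
    if n_pos > hi:
        label, lean = POSITIVE, "none"
    elif n_neg > hi:
        label, lean = NEGATIVE, "none"
    elif n_neutral > hi:
        label, lean = NEUTRAL, "none"
    else:
        label = MIXED
        if lo < n_pos < hi and n_pos > n_neg:
            lean = POSITIVE
        elif lo < n_neg < hi and n_neg > n_pos:
            lean = NEGATIVE
        else:
            lean = "none"
    return ResponseCategory(
        label=label, lean=lean, n_pos=n_pos, n_neg=n_neg, n_neutral=n_neutral
    )


def categorize_tally(tally: ResponseTally) -> dict[str, ResponseCategory]:
    """Per-element categories for a whole tally."""
    return {
        e: categorize(
            int(tally.positive[i]),
            int(tally.negative[i]),
            int(tally.neutral[i]),
            tally.n_sims,
        )
        for i, e in enumerate(tally.elements)
    }


def score_pair(a: ResponseCategory, b: ResponseCategory) -> float:
    """Point value for one element compared across two models.

    +1 for matching directions, −1 for opposing directions, ±0.5 when
    exactly one side is mixed-with-lean against a directional result
    (sign by lean agreement), 0 for everything else (neutrals, leanless
    mixed, mixed vs mixed).
    """
    if a.directional and b.directional:
        return 1.0 if a.direction == b.direction else -1.0
    if a.label == MIXED and b.directional and a.lean_direction != 0:
        return 0.5 if a.lean_direction == b.direction else -0.5
    if b.label == MIXED and a.directional and b.lean_direction != 0:
        return 0.5 if b.lean_direction == a.direction else -0.5
    return 0.0


def model_agreement(
    cats_a: dict[str, ResponseCategory], cats_b: dict[str, ResponseCategory]
) -> AgreementScore:
    """Element-wise points plus percentage of elements with a common response."""
    if set(cats_a) != set(cats_b):
        raise ValueError(
            "element sets differ: "
            f"{sorted(set(cats_a) ^ set(cats_b))} not shared"
        )
    elements = tuple(cats_a)
    points = np.array([score_pair(cats_a[e], cats_b[e]) for e in elements])
    same = sum(1 for e in elements if cats_a[e].label == cats_b[e].label)

    def common_with_lean(x: ResponseCategory, y: ResponseCategory) -> bool:
        if x.label == y.label:
            return True
        if x.label == MIXED and y.directional:
            return x.lean_direction == y.direction
        if y.label == MIXED and x.directional:
            return y.lean_direction == x.direction
        return False

    same_lean = sum(1 for e in elements if common_with_lean(cats_a[e], cats_b[e]))
    n = len(elements)
    return AgreementScore(
        elements=elements,
        points=points,
        total=float(points.sum()),
        percent=100.0 * same / n if n else float("nan"),
        percent_with_leans=100.0 * same_lean / n if n else float("nan"),
    )
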