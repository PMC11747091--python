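"""Risk stratification by mean IEL score and IEL-adjusted composite grades.

Slides are split into low/high IEL risk at the cohort mean of the chosen
score (the mean rather than the median, because transformation events are a
minority of cases and a 50-50 split is not required). The composite grades
nudge a pathologist grade by the IEL label: the "plus" variant upgrades
low-grade cases whose IEL score is high, the "minus" variant downgrades
high-grade cases whose IEL score is low; on the three-level WHO ladder
(mild < moderate < severe) the move is exactly one step, clamped at the
ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RiskLabel",
    "CompositeGrade",
    "mean_threshold_stratify",
    "composite_grade",
    "consensus_features",
    "WHO_LADDER",
]

logger = logging.getLogger(__name__)

WHO_LADDER = ("mild", "moderate", "severe")
SCORE_NAMES = ("iel_c", "iel_pc", "iel_i", "iel_pi")


@dataclass(frozen=True)
class RiskLabel:
    """Low/high IEL-risk call for one slide against a cohort threshold."""

    slide_id: str
    score_name: str
    threshold: float
    label: str  # "low" | "high"


@dataclass(frozen=True)
class CompositeGrade:
    """A pathologist grade after one-step IEL adjustment."""

    base: str  # "binary" | "who"
    direction: str  # "plus" | "minus"
    value: str


def mean_threshold_stratify(
    scores: Sequence[tuple[str, float]],
    score_name: str = "iel_c",
    threshold: float | None = None,
) -> list[RiskLabel]:
    """Label each slide low/high risk against the (in-sample) mean score.

    ``label = high`` iff score is strictly greater than the threshold; ties
    go to low. The threshold defaults to the arithmetic mean over the
    supplied slides; pass ``threshold`` to apply an externally fixed cutoff
    (deployment on a new cohort). Invariant to slide ordering.
    """
    if score_name not in SCORE_NAMES:
        raise ValueError(f"unknown score name {score_name!r}")
    values = np.asarray([s for _, s in scores], dtype=float)
    if threshold is None:
        if len(values) < 2:
            raise ValueError("need >= 2 scores to compute a cohort threshold")
        if not np.all(np.isfinite(values)):
            raise ValueError("scores must be finite")
        threshold = float(values.mean())
    if np.all(values == threshold):
        logger.info("all scores equal the threshold %.6g; labelling all low", threshold)
    return [
        RiskLabel(slide_id, score_name, threshold, "high" if v > threshold else "low")
        for (slide_id, _), v in zip(scores, values)
    ]


def composite_grade(
    base_grade: str,
    iel_label: RiskLabel | str,
    base: str = "binary",
    direction: str = "plus",
) -> CompositeGrade:
    """Adjust a grade one step by the IEL risk label.

    binary/plus: a low-risk case with a high IEL label becomes high-risk;
    binary/minus: a high-risk case with a low IEL label becomes low-risk;
    the WHO variants move one step on mild < moderate < severe, clamped.
    "plus" never downgrades and "minus" never upgrades.
    """
    label = iel_label.label if isinstance(iel_label, RiskLabel) else iel_label
    if label not in ("low", "high"):
        raise ValueError(f"invalid IEL risk label {label!r}")
    if direction not in ("plus", "minus"):
        raise ValueError(f"invalid direction {direction!r}")
    if base == "binary":
        if base_grade not in ("low", "high"):
            raise ValueError(f"invalid binary grade {base_grade!r}")
        value = base_grade
        if direction == "plus" and base_grade == "low" and label == "high":
            value = "high"
        elif direction == "minus" and base_grade == "high" and label == "low":
            value = "low"
    elif base == "who":
        if base_grade not in WHO_LADDER:
            raise ValueError(f"invalid WHO grade {base_grade!r}")
        idx = WHO_LADDER.index(base_grade)
        if direction == "plus" and label == "high":
            idx = min(idx + 1, len(WHO_LADDER) - 1)
        elif direction == "minus" and label == "low":
            idx = max(idx - 1, 0)
        value = WHO_LADDER[idx]
    else:
        raise ValueError(f"invalid base grading system {base!r}")
    return CompositeGrade(base=base, direction=direction, value=value)


def consensus_features(votes: Iterable[int]) -> int:
    """2-of-3 majority consensus for one pathologist-rated binary feature."""
    votes = list(votes)
    if len(votes) != 3:
        raise ValueError(f"need exactly 3 rater votes, got {len(votes)}")
    if any(v not in (0, 1) for v in votes):
        raise ValueError(f"votes must be binary, got {votes}")
    return int(sum(votes) >= 2)
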