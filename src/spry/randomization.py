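"""Stratified sqrt(3):1:1:1 allocation and response-adaptive weight updates.

The platform randomizes to placebo and three daily metformin doses
(500/1000/1500 mg) in ratio sqrt(3):1:1:1 — the square-root-of-k rule that
maximizes the efficiency of k treatment-vs-control comparisons — stratified
by enrollment clinic, age category, and the planned pre-operative exposure
window (short 7-28 / medium 29-90 / long >90 days).  Because sqrt(3) is
irrational, permuted blocks use the rational approximation 7:4:4:4 (block
size 19; |7/19 - sqrt(3)/(sqrt(3)+3)| < 0.003), with simple weighted draws
available as an option.

At each interim, arms meeting the futility/inferiority drop rule lose all
weight; surviving treatment arms are re-weighted proportional to a power of
their posterior probability of being the best dose, and placebo is held at
sqrt(3) times the mean active-arm weight to preserve comparator
information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import DOSES, Patient, duration_stratum_for_lead_time
from .errors import DesignError, EligibilityError

__all__ = [
    "ARMS",
    "Assignment",
    "AllocationWeights",
    "allocation_probabilities",
    "block_composition",
    "Randomizer",
    "update_weights",
]

#: Randomized arms, placebo first.
ARMS: tuple = ("placebo",) + DOSES


@dataclass(frozen=True)
class Assignment:
    patient_id: str
    arm: object  # "placebo" or dose in mg
    duration_stratum: str
    strata_key: tuple
    block_id: int | None = None


@dataclass(frozen=True)
class AllocationWeights:
    """Nonnegative allocation weights over (placebo, 500, 1000, 1500)."""

    weights: tuple[float, float, float, float] = (math.sqrt(3.0), 1.0, 1.0, 1.0)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4,):
            raise DesignError("weights must have one entry per arm (4)")
        if np.any(w < 0):
            raise DesignError("weights must be nonnegative")

    @property
    def active_arms(self) -> tuple:
        return tuple(a for a, w in zip(ARMS, self.weights) if w > 0)


def allocation_probabilities(weights: AllocationWeights) -> np.ndarray:
    """Normalized allocation probabilities; dropped arms get exactly 0.

    At the default weights the placebo probability is
    sqrt(3)/(sqrt(3)+3) = 0.36602540...
    """
    w = np.asarray(weights.weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise DesignError("all allocation weights are zero")
    return w / total


def block_composition(weights: AllocationWeights, block_size: int = 19) -> np.ndarray:
    """Integer arm counts for one permuted block (largest-remainder rule).

    The default weights yield 7:4:4:4 in a block of 19.  Arms with zero
    weight receive zero slots.
    """
    probs = allocation_probabilities(weights)
    quota = probs * block_size
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = block_size - counts.sum()
    # break remainder ties toward lower arm index for determinism
    order = np.argsort(-(remainder + 1e-12 * np.arange(len(ARMS), 0, -1)))
    for i in order[:short]:
        counts[i] += 1
    counts[probs == 0] = 0
    return counts


class Randomizer:
    """Stratified permuted-block (or weighted) randomization with state.

    One instance carries per-stratum open blocks; changing the weights via
    :meth:`set_weights` discards open blocks so the new ratio takes effect
    immediately.  ``method`` is ``"blocks"`` (default) or ``"weighted"``.
    """

    def __init__(
        self,
        weights: AllocationWeights | None = None,
        *,
        method: str = "blocks",
        block_size: int = 19,
        rng: np.random.Generator | None = None,
    ):
        if method not in ("blocks", "weighted"):
            raise DesignError(f"unknown randomization method {method!r}")
        self.weights = weights or AllocationWeights()
        self.method = method
        self.block_size = block_size
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self._blocks: dict[tuple, list] = {}
        self._block_counter = 0

    def set_weights(self, weights: AllocationWeights) -> None:
        self.weights = weights
        self._blocks.clear()

    def _next_from_block(self, key: tuple):
        queue = self._blocks.get(key)
        if not queue:
            counts = block_composition(self.weights, self.block_size)
            block = [a for a, c in zip(ARMS, counts) for _ in range(int(c))]
            self.rng.shuffle(block)
            self._block_counter += 1
            queue = [(arm, self._block_counter) for arm in block]
            self._blocks[key] = queue
        return queue.pop(0)

    def assign(self, patient: Patient) -> Assignment:
        """Randomize one eligible patient within their stratum.

        Raises ``EligibilityError`` for ineligible patients or lead times
        below the 7-day minimum exposure window.
        """
        if not patient.eligible:
            raise EligibilityError(
                f"patient {patient.patient_id} ineligible: age {patient.age} < 60 "
                f"and CCI {patient.cci} <= 2"
            )
        duration = duration_stratum_for_lead_time(patient.planned_lead_time_days)
        key = (patient.clinic_id, patient.age_category, duration)
        if self.method == "blocks":
            arm, block_id = self._next_from_block(key)
        else:
            probs = allocation_probabilities(self.weights)
            arm = ARMS[int(self.rng.choice(len(ARMS), p=probs))]
            block_id = None
        return Assignment(
            patient_id=patient.patient_id,
            arm=arm,
            duration_stratum=duration,
            strata_key=key,
            block_id=block_id,
        )


def update_weights(
    current: AllocationWeights,
    p_best: Mapping[int, float],
    dropped: Sequence[int] = (),
    *,
    exponent: float = 0.5,
) -> AllocationWeights | None:
    """Response-adaptive weight update at an interim.

    ``p_best`` maps each still-active dose to its posterior probability of
    being the best dose; doses listed in ``dropped`` (futile/inferior, or
    previously dropped) get weight 0 and are never reassigned.  Active-dose
    weights are proportional to ``p_best ** exponent``; placebo is held at
    sqrt(3) times the mean active-dose weight.

    Returns ``None`` when no treatment arm remains active — a
    platform-conclusion signal (the trial stops), not an error.
    """
    if exponent < 0:
        raise DesignError("exponent must be nonnegative")
    dropped = set(dropped)
    # arms already at zero weight stay dropped
    for arm, w in zip(ARMS[1:], current.weights[1:]):
        if w == 0:
            dropped.add(arm)
    active = [d for d in DOSES if d not in dropped]
    if not active:
        return None
    missing = [d for d in active if d not in p_best]
    if missing:
        raise DesignError(f"p_best missing for active arms {missing}")
    dose_w = {d: float(p_best[d]) ** exponent for d in active}
    mean_active = sum(dose_w.values()) / len(dose_w)
    placebo_w = math.sqrt(3.0) * mean_active
    weights = tuple(
        [placebo_w] + [dose_w.get(d, 0.0) if d not in dropped else 0.0 for d in DOSES]
    )
    return AllocationWeights(weights=weights)
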