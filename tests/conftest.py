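"""Shared fixtures: simulated datasets drawn from the calibrated generator."""

import numpy as np
import pytest

from spry.cohort import (
    DURATIONS,
    STRATA,
    CohortConfig,
    EffectScenario,
    sample_hfd,
)

STRATUM_MIX = (0.29, 0.38, 0.13, 0.20)
DURATION_MIX = (0.61, 0.28, 0.11)


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig()


def simulate_outcome_table(
    scenario: EffectScenario,
    n_per_arm: dict,
    seed: int,
    config: CohortConfig | None = None,
):
    """Draw a tidy (hfd90, arm, duration, stratum) table, vectorized per cell.

    ``n_per_arm`` maps "placebo" or a dose to a patient count; strata and
    durations follow the trial mixes.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    total = sum(n_per_arm.values())
    arms = np.concatenate(
        [np.full(n, str(a), dtype=object) for a, n in n_per_arm.items()]
    )
    arms = np.array([a if a == "placebo" else int(a) for a in arms], dtype=object)
    strata = rng.choice(STRATA, size=total, p=STRATUM_MIX)
    durs = rng.choice(DURATIONS, size=total, p=DURATION_MIX)
    y = np.empty(total, dtype=int)
    for s in STRATA:
        for u in DURATIONS:
            for a in n_per_arm:
                a_val = a if a == "placebo" else int(a)
                mask = (strata == s) & (durs == u) & (arms == a_val)
                k = int(mask.sum())
                if k:
                    y[mask] = sample_hfd(cfg, s, a_val, u, scenario, rng, size=k)
    return y, arms, durs, strata
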