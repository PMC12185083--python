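"""Bayesian proportional-odds model: recovery, centring, engines, decisions."""

import numpy as np
import pytest
from scipy.special import expit

from spry.cohort import DURATIONS, CohortConfig, EffectScenario
from spry.errors import ConvergenceError, DegenerateDataError
from spry.ordinal import (
    DecisionThresholds,
    HierarchicalOrdinalModel,
    PriorConfig,
    classify_status,
    sensitivity_duration_model,
)

from conftest import simulate_outcome_table


def _fit(scenario, n_per_arm, seed, *, structure="cells", **fit_kw):
    y, arms, durs, strata = simulate_outcome_table(scenario, n_per_arm, seed)
    model = HierarchicalOrdinalModel(y, arms, durs, strata, structure=structure)
    return model.fit(seed=seed, **fit_kw)


class TestParameterRecovery:
    def test_true_por_covered_by_credible_interval(self):
        """The generating por 0.74 falls inside the 95% CrI in >=88% of 50
        replicates at 2000 patients per arm (nominal coverage 95%)."""
        true_por = 0.74
        scenario = EffectScenario.uniform_effect(dose=1000, por=true_por)
        covered = 0
        for rep in range(50):
            res = _fit(scenario, {"placebo": 2000, 1000: 2000}, 300 + rep, draws=2000)
            s = res.dose_summaries()[1000]
            covered += s.cri_low <= true_por <= s.cri_high
        assert covered >= 44

    def test_null_centring(self):
        """Under no effect the posterior median odds ratio sits near 1."""
        res = _fit(
            EffectScenario.null(),
            {"placebo": 5000, 500: 5000, 1000: 5000, 1500: 5000},
            seed=77,
            draws=2000,
        )
        for s in res.dose_summaries().values():
            assert abs(s.mpOR - 1.0) < 0.1
            # p_superior is ~uniform under the exact null; only its
            # location-scale sanity is checkable on one replicate
            assert 0.0 <= s.p_superior <= 1.0


class TestTwoCategoryEquivalence:
    def test_reduces_to_logistic_regression(self):
        """With two outcome categories the model is Bayesian logistic
        regression; its estimate matches the ML logistic fit."""
        import statsmodels.api as sm

        scenario = EffectScenario.uniform_effect(dose=1000, por=0.7)
        y, arms, durs, strata = simulate_outcome_table(
            scenario, {"placebo": 3000, 1000: 3000}, seed=5
        )
        strata = np.full_like(strata, "general")
        grid = [(-1, 87), (88, 90)]
        model = HierarchicalOrdinalModel(y, arms, durs, strata, grid=grid)
        res = model.fit(draws=4000, seed=5)
        post_log_or = np.log(res.dose_summaries()[1000].mpOR)
        # reference: ML logistic regression on the same dichotomy
        ybin = (y >= 88).astype(int)
        treated = (arms != "placebo").astype(float)
        mle = sm.Logit(ybin, sm.add_constant(treated)).fit(disp=False)
        # model parameterizes odds of *fewer* HFD: sign flips
        assert abs(post_log_or - (-float(mle.params[1]))) < 0.03


class TestInvariants:
    def test_cumulative_probabilities_monotone_in_every_draw(self):
        res = _fit(
            EffectScenario.null(), {"placebo": 800, 500: 800}, seed=9, draws=1000
        )
        assert res.cumulative_monotone()
        post = res.model._post
        for draw in res.sample[:100]:
            gamma = post.cutpoints(draw)
            assert np.all(np.diff(gamma) > 0)
            cum = expit(gamma)
            assert np.all(np.diff(cum) > 0)

    def test_orientation_reciprocity_with_ml_ordinal_fit(self):
        """The Bayesian mpOR (>1 = fewer HFD) and the frequentist ordinal
        OR (>1 = more HFD) are reciprocal on the same data."""
        import pandas as pd

        from spry.frequentist import POOLED, ordinal_or_more_hfd

        scenario = EffectScenario.uniform_effect(dose=1000, por=0.8)
        y, arms, durs, strata = simulate_outcome_table(
            scenario, {"placebo": 2000, 1000: 2000}, seed=21
        )
        strata = np.full_like(strata, "general")
        res = HierarchicalOrdinalModel(y, arms, durs, strata).fit(draws=4000, seed=21)
        mpor = res.dose_summaries()[1000].mpOR
        df = pd.DataFrame({"hfd90": y, "arm": arms, "duration": durs})
        (freq,) = ordinal_or_more_hfd(df, POOLED)
        assert abs(np.log(mpor * freq.estimate)) < 0.05

    def test_borrowing_shrinks_cells_together(self):
        """A tight hierarchy prior pulls the nine cell estimates toward a
        common additive structure; a loose one lets them separate."""
        scenario = EffectScenario(
            effect_type="dose_specific",
            por_by_arm={(500, "short"): 0.6, (1000, "medium"): 1.4, (1500, "long"): 0.8},
        )
        counts = {"placebo": 1500, 500: 1000, 1000: 1000, 1500: 1000}
        y, arms, durs, strata = simulate_outcome_table(scenario, counts, seed=31)
        spreads = {}
        for scale in (0.02, 2.0):
            model = HierarchicalOrdinalModel(
                y, arms, durs, strata, prior=PriorConfig(tau_scale=scale)
            )
            res = model.fit(draws=1000, seed=31)
            informed = res.model.cell_n > 0
            cells = np.log(
                [s.mpOR for (c, s) in zip(range(9), res.cell_summaries().values())]
            )[informed]
            spreads[scale] = np.std(cells)
        assert spreads[0.02] < spreads[2.0]


class TestTypeIError:
    def test_final_analysis_false_positive_rate(self):
        """Under the null, each dose's P(superior) exceeds 0.975 in at most
        2.5% of final analyses (plus 3 Monte-Carlo SEs)."""
        reps = 60
        crossings = {500: 0, 1000: 0, 1500: 0}
        counts = {"placebo": 916, 500: 528, 1000: 528, 1500: 528}
        for rep in range(reps):
            res = _fit(EffectScenario.null(), counts, 500 + rep, draws=2000)
            for d, s in res.dose_summaries().items():
                crossings[d] += s.p_superior > 0.975
        bound = 0.025 + 3 * np.sqrt(0.025 * 0.975 / reps)
        for d, k in crossings.items():
            assert k / reps <= bound, (d, k)


class TestDurationSensitivity:
    def test_medium_restricted_effect_ranks_first(self):
        """With a medium-duration-only benefit, the medium contrast has the
        smallest mpOR among durations in >=80% of replicates."""
        import pandas as pd

        scenario = EffectScenario(
            effect_type="duration_restricted",
            por_by_arm={(d, "medium"): 0.74 for d in (500, 1000, 1500)},
        )
        wins = 0
        reps = 50
        for rep in range(reps):
            rng = np.random.default_rng(900 + rep)
            counts = {"placebo": 1000, 500: 1000, 1000: 1000, 1500: 1000}
            y, arms, durs, strata = simulate_outcome_table(scenario, counts, 900 + rep)
            df = pd.DataFrame(
                {"hfd90": y, "arm": arms, "duration": durs, "stratum": strata}
            )
            summ = sensitivity_duration_model(df, seed=rep, draws=1000)
            ors = {u: summ[u].mpOR for u in DURATIONS}
            wins += min(ors, key=ors.get) == "medium"
        assert wins >= 0.8 * reps

    def test_missing_duration_is_prior_dominated(self):
        scenario = EffectScenario.null()
        y, arms, durs, strata = simulate_outcome_table(
            scenario, {"placebo": 600, 1000: 600}, seed=3
        )
        durs = np.full_like(durs, "short")
        import pandas as pd

        df = pd.DataFrame({"hfd90": y, "arm": arms, "duration": durs, "stratum": strata})
        summ = sensitivity_duration_model(df, seed=3, draws=500)
        assert not summ["short"].prior_dominated
        assert summ["medium"].prior_dominated and summ["long"].prior_dominated


class TestDecisionRules:
    thr = DecisionThresholds()

    @pytest.mark.parametrize(
        "p_sup, p_eq, expected",
        [
            (0.98, 0.1, "superior"),
            (0.975, 0.1, "continue"),        # strict inequality at the bound
            (0.5, 0.95, "equivalent"),
            (0.004, 0.0, "inferior"),
            (0.03, 0.0, "futile"),
            (0.5, 0.5, "continue"),
        ],
    )
    def test_classification(self, p_sup, p_eq, expected):
        assert classify_status(p_sup, p_eq, self.thr) == expected

    def test_decide_on_fitted_results(self):
        res = _fit(
            EffectScenario.uniform_effect(dose=1000, por=0.5),
            {"placebo": 2000, 1000: 2000},
            seed=55,
            draws=1000,
        )
        assert res.decide()[1000] == "superior"


class TestDegenerateData:
    def test_single_arm_rejected(self):
        y = np.array([88, 90, 85, 80])
        arms = np.array(["placebo"] * 4, dtype=object)
        with pytest.raises(DegenerateDataError):
            HierarchicalOrdinalModel(y, arms)

    def test_constant_outcome_rejected(self):
        y = np.array([90] * 10)
        arms = np.array(["placebo"] * 5 + [500] * 5, dtype=object)
        durs = np.array(["short"] * 10, dtype=object)
        with pytest.raises(DegenerateDataError):
            HierarchicalOrdinalModel(y, arms, durs)

    def test_disjoint_supports_rejected(self):
        y = np.array([1, 2, 3, 4, 5] * 4 + [85, 86, 87, 88, 90] * 4)
        arms = np.array(["placebo"] * 20 + [500] * 20, dtype=object)
        durs = np.array(["short"] * 40, dtype=object)
        with pytest.raises(DegenerateDataError, match="overlap"):
            HierarchicalOrdinalModel(y, arms, durs)


class TestMCMCEngine:
    def test_agrees_with_laplace_and_converges(self):
        scenario = EffectScenario.uniform_effect(dose=1000, por=0.74)
        y, arms, durs, strata = simulate_outcome_table(
            scenario, {"placebo": 600, 1000: 600}, seed=42
        )
        model = HierarchicalOrdinalModel(y, arms, durs, strata)
        lap = model.fit(draws=2000, seed=2)
        mc = model.fit(method="mcmc", draws=2000, seed=2, warmup=200)
        assert mc.rhat <= 1.05
        assert mc.ess > 50
        d_lap, d_mc = lap.dose_summaries()[1000], mc.dose_summaries()[1000]
        assert abs(np.log(d_lap.mpOR) - np.log(d_mc.mpOR)) < 0.1

    def test_failed_diagnostics_raise_with_results_attached(self):
        scenario = EffectScenario.null()
        y, arms, durs, strata = simulate_outcome_table(
            scenario, {"placebo": 200, 500: 200}, seed=8
        )
        model = HierarchicalOrdinalModel(y, arms, durs, strata)
        with pytest.raises(ConvergenceError) as err:
            model.fit(method="mcmc", draws=400, seed=8, warmup=50, rhat_limit=0.9999)
        assert err.value.results is not None
        assert err.value.results.sample.shape[0] > 0
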