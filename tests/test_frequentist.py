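"""Frequentist suite: logistic ORs, Cox/KM, subgroups, contrast sets."""

import itertools

import numpy as np
import pandas as pd
import pytest

from spry.errors import DataIntegrityError
from spry.frequentist import (
    BY_DOSE,
    BY_DURATION,
    LOWDOSE_SHORT_VS_REST,
    POOLED,
    fit_binary_endpoint,
    fit_linear_endpoint,
    fit_time_to_event,
    km_curve,
    subgroup_suite,
)


def binary_frame(events_treated, n_treated, events_placebo, n_placebo):
    rows = []
    for i in range(n_treated):
        rows.append({"arm": 1000, "duration": "short", "reoperation_90": i < events_treated})
    for i in range(n_placebo):
        rows.append({"arm": "placebo", "duration": "short", "reoperation_90": i < events_placebo})
    return pd.DataFrame(rows)


class TestBinaryEndpoint:
    def test_or_equals_cross_product_ratio(self):
        """Logistic OR on a 2x2 table equals ad/bc to 1e-9."""
        df = binary_frame(28, 196, 15, 106)
        (est,) = fit_binary_endpoint(df, "reoperation_90", POOLED)
        oracle = (28 * (106 - 15)) / ((196 - 28) * 15)
        assert abs(est.estimate - oracle) < 1e-9

    @pytest.mark.parametrize(
        "a,n1,c,n0",
        [(10, 50, 4, 40), (1, 30, 7, 60), (25, 80, 25, 80), (3, 10, 2, 9)],
    )
    def test_cross_product_exhaustive_small_tables(self, a, n1, c, n0):
        df = binary_frame(a, n1, c, n0)
        (est,) = fit_binary_endpoint(df, "reoperation_90", POOLED)
        oracle = (a * (n0 - c)) / ((n1 - a) * c)
        assert abs(est.estimate - oracle) < 1e-9

    def test_equal_rates_balanced_gives_unit_or(self):
        df = binary_frame(12, 60, 12, 60)
        (est,) = fit_binary_endpoint(df, "reoperation_90", POOLED)
        assert abs(est.estimate - 1.0) < 1e-9

    def test_zero_cell_continuity_correction(self):
        df = binary_frame(0, 50, 5, 50)
        (est,) = fit_binary_endpoint(df, "reoperation_90", POOLED)
        assert est.continuity_corrected
        assert np.isfinite(est.estimate) and est.estimate > 0

    def test_no_events_at_all_rejected(self):
        df = binary_frame(0, 20, 0, 20)
        with pytest.raises(DataIntegrityError):
            fit_binary_endpoint(df, "reoperation_90", POOLED)

    def test_consistency_against_generator_truth(self):
        """A known odds ratio of 1.45 is recovered within +/-0.05 at n=100k."""
        rng = np.random.default_rng(17)
        n = 100_000
        p0 = 0.0918
        odds1 = 1.45 * p0 / (1 - p0)
        p1 = odds1 / (1 + odds1)
        df = pd.DataFrame(
            {
                "arm": ["placebo"] * n + [1000] * n,
                "duration": "short",
                "readmission_90": np.concatenate(
                    [rng.random(n) < p0, rng.random(n) < p1]
                ),
            }
        )
        (est,) = fit_binary_endpoint(df, "readmission_90", POOLED)
        assert abs(est.estimate - 1.45) < 0.05

    def test_one_sided_p_agrees_with_ci_exclusion(self):
        """p < 0.025 in the benefit direction iff the 95% CI excludes 1
        favorably (Wald duality)."""
        rng = np.random.default_rng(23)
        for _ in range(40):
            n = 400
            p0, p1 = 0.2, rng.uniform(0.05, 0.35)
            df = pd.DataFrame(
                {
                    "arm": ["placebo"] * n + [500] * n,
                    "duration": "short",
                    "morbidity_90": np.concatenate(
                        [rng.random(n) < p0, rng.random(n) < p1]
                    ),
                }
            )
            try:
                (est,) = fit_binary_endpoint(df, "morbidity_90", POOLED)
            except DataIntegrityError:
                continue
            favorable = est.ci_high < 1.0  # benefit = fewer events
            assert (est.one_sided_p < 0.025) == favorable


class TestContrastSets:
    def _frame(self):
        rows = []
        for arm, dur in itertools.product(["placebo", 500, 1000, 1500],
                                          ["short", "medium", "long"]):
            for i in range(5):
                rows.append({"arm": arm, "duration": dur, "reoperation_90": i == 0})
        return pd.DataFrame(rows)

    def test_groups_partition_cohort(self):
        df = self._frame()
        for contrast in (POOLED, BY_DOSE, BY_DURATION, LOWDOSE_SHORT_VS_REST):
            groups = contrast.groups(df)
            assert len(groups) == len(df)
            assert groups.notna().all()
            assert contrast.reference in set(groups)

    def test_lowdose_short_isolated(self):
        df = self._frame()
        g = LOWDOSE_SHORT_VS_REST.groups(df)
        assert (g == "lowdose_short").sum() == 5
        assert (g == "placebo").sum() == 15
        assert (g == "other_treatment").sum() == len(df) - 20

    def test_by_dose_levels(self):
        ests = fit_binary_endpoint(self._frame(), "reoperation_90", BY_DOSE)
        assert {e.level for e in ests} == {"500 mg", "1000 mg", "1500 mg"}


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        """times {2,4,4,7,90}, events {1,1,0,1,0}: S = 0.8, 0.6, 0.3."""
        curve = km_curve([2, 4, 4, 7, 90], [1, 1, 0, 1, 0])
        s = dict(zip(curve["time"], curve["survival"]))
        assert abs(s[2.0] - 0.8) < 1e-12
        assert abs(s[4.0] - 0.6) < 1e-12
        assert abs(s[7.0] - 0.3) < 1e-12

    def test_matches_brute_force_on_all_small_patterns(self):
        """Every event/censor pattern on <=6 patients equals the
        hand-computed product-limit estimator."""
        times = [1, 2, 2, 3, 5, 8]
        for n in range(1, 7):
            tt = times[:n]
            for pattern in itertools.product([0, 1], repeat=n):
                curve = km_curve(tt, list(pattern))
                surv = dict(zip(curve["time"], curve["survival"]))
                # brute force product-limit
                s = 1.0
                for t in sorted(set(tt)):
                    at_risk = sum(1 for x in tt if x >= t)
                    deaths = sum(
                        1 for x, e in zip(tt, pattern) if x == t and e == 1
                    )
                    if at_risk > 0:
                        s *= 1 - deaths / at_risk
                    assert abs(surv[float(t)] - s) < 1e-12


def tte_frame(n0, n1, hr, rng, withdrawn=0):
    """Exponential event times with administrative censoring at day 90."""
    lam0 = 0.002
    t0 = rng.exponential(1 / lam0, size=n0)
    t1 = rng.exponential(1 / (lam0 * hr), size=n1)
    rows = []
    for arm, times in (("placebo", t0), (1000, t1)):
        for t in times:
            event = t <= 90
            rows.append(
                {
                    "arm": arm,
                    "duration": "short",
                    "reoperation_90": event,
                    "reoperation_time": min(t, 90.0),
                    "censor_day": 90.0,
                    "excluded_from_tte": False,
                }
            )
    df = pd.DataFrame(rows)
    if withdrawn:
        df.loc[df.index[:withdrawn], "excluded_from_tte"] = True
    return df


class TestCox:
    def test_label_swap_symmetry(self):
        """Two identical groups give HR = 1 within 1e-6."""
        rng = np.random.default_rng(3)
        base = tte_frame(200, 0, 1.0, rng)
        mirrored = base.copy()
        mirrored["arm"] = 1000
        df = pd.concat([base, mirrored], ignore_index=True)
        ests, _ = fit_time_to_event(df, "reoperation_90", POOLED)
        assert abs(ests[0].estimate - 1.0) < 1e-6

    def test_recovers_generator_hazard_ratio(self):
        rng = np.random.default_rng(5)
        df = tte_frame(50_000, 50_000, 1.37, rng)
        ests, _ = fit_time_to_event(df, "reoperation_90", POOLED)
        assert abs(ests[0].estimate - 1.37) < 0.05

    def test_withdrawn_excluded(self):
        rng = np.random.default_rng(6)
        df = tte_frame(300, 300, 1.0, rng, withdrawn=50)
        ests, curves = fit_time_to_event(df, "reoperation_90", POOLED)
        assert ests[0].n == len(df) - 50

    def test_no_events_in_group_flagged(self):
        rng = np.random.default_rng(7)
        df = tte_frame(100, 100, 1.0, rng)
        df.loc[df["arm"] != "placebo", "reoperation_90"] = False
        ests, _ = fit_time_to_event(df, "reoperation_90", POOLED)
        assert np.isnan(ests[0].estimate)
        assert "no events" in ests[0].note

    def test_km_curves_returned_per_group(self):
        rng = np.random.default_rng(8)
        _, curves = fit_time_to_event(tte_frame(100, 100, 1.5, rng),
                                      "reoperation_90", POOLED)
        assert set(curves) == {"placebo", "metformin"}
        for c in curves.values():
            assert np.all(np.diff(c["survival"]) <= 1e-12)


class TestLinear:
    def test_beta_equals_group_mean_difference(self):
        df = pd.DataFrame(
            {
                "arm": ["placebo"] * 4 + [500] * 4,
                "duration": "short",
                "index_los_days": [2, 4, 6, 8, 1, 3, 5, 7],
            }
        )
        (est,) = fit_linear_endpoint(df, "index_los_days", POOLED)
        assert abs(est.estimate - (-1.0)) < 1e-9
        assert est.measure == "beta"


class TestSubgroups:
    def _cohort(self, rng, benefit_below_median=False, n=2000):
        age = rng.integers(60, 80, size=n)
        arm = np.where(rng.random(n) < 0.5, "placebo", "1000").astype(object)
        arm = np.array([a if a == "placebo" else 1000 for a in arm], dtype=object)
        med = np.median(age)
        p = np.full(n, 0.2)
        treated = arm != "placebo"
        if benefit_below_median:
            p = np.where(treated & (age < med), 0.08, p)
        events = rng.random(n) < p
        return pd.DataFrame(
            {
                "age": age,
                "sex": rng.choice(["female", "male"], size=n),
                "arm": arm,
                "duration": "short",
                "morbidity_90": events,
            }
        )

    def test_age_split_at_cohort_median(self):
        rng = np.random.default_rng(11)
        df = self._cohort(rng)
        med = df["age"].median()
        out = subgroup_suite(df, "age_median_split", "morbidity_90")
        assert set(out) == {f"<{med:g}", f">={med:g}"}
        for ests in out.values():
            assert all(e.exploratory for e in ests)

    def test_constant_factor_degenerates_to_main_analysis(self):
        rng = np.random.default_rng(12)
        df = self._cohort(rng)
        df["sex"] = "female"
        out = subgroup_suite(df, "sex", "morbidity_90")
        assert list(out) == ["female"]
        (est,) = out["female"]
        (main,) = fit_binary_endpoint(df, "morbidity_90", POOLED)
        assert abs(est.estimate - main.estimate) < 1e-12

    def test_detects_age_restricted_benefit(self):
        """A below-median-only benefit yields a smaller below-median OR in
        >=90% of replicates."""
        wins = 0
        reps = 50
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            df = self._cohort(rng, benefit_below_median=True)
            out = subgroup_suite(df, "age_median_split", "morbidity_90")
            med = df["age"].median()
            below = out[f"<{med:g}"][0].estimate
            above = out[f">={med:g}"][0].estimate
            wins += below < above
        assert wins >= 0.9 * reps
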