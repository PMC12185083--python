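"""Frequentist secondary, sensitivity, and subgroup analyses.

Univariable logistic regression (odds ratios) for the 90-day binary
endpoints, Cox proportional hazards (Efron ties) with Kaplan-Meier curves
for their time-to-event versions, ordinary least squares for continuous
endpoints, and a cumulative-logit fit of HFD-90 as the frequentist
sensitivity analysis of the primary endpoint.

Conventions: 95% Wald confidence intervals; significance at a one-sided
p < 0.025 in the prespecified benefit direction (fewer events for
harm-type endpoints, more hospital-free days for the ordinal endpoint);
zero cells handled with the Haldane-Anscombe 0.5 correction and flagged.
Withdrawn patients are excluded from time-to-event analyses.  Subgroup
analyses are exploratory and carry no multiplicity adjustment; the output
flags them as such.

Orientation note: the frequentist ordinal fit reports the odds of *more*
hospital-free days (OR > 1 = benefit), the reciprocal of the Bayesian
model's convention (mpOR > 1 = worse); on the same data the two estimates
multiply to ~1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .errors import ConfigError, DataIntegrityError

__all__ = [
    "ContrastSet",
    "EffectEstimate",
    "POOLED",
    "BY_DOSE",
    "BY_DURATION",
    "LOWDOSE_SHORT_VS_REST",
    "fit_binary_endpoint",
    "fit_linear_endpoint",
    "fit_time_to_event",
    "ordinal_or_more_hfd",
    "subgroup_suite",
    "km_curve",
]

#: Endpoints where "benefit" means fewer events (harm-type outcomes).
HARM_ENDPOINTS = frozenset(
    {"reoperation_90", "readmission_90", "morbidity_90", "mortality_90"}
)


@dataclass(frozen=True)
class ContrastSet:
    """A named rule partitioning the analysis cohort into comparison groups.

    ``grouper`` maps a row (with columns ``arm`` and ``duration``) to a
    group label; ``reference`` names the comparator group.  Every patient
    must map to exactly one group.
    """

    name: str
    grouper: Callable[[pd.Series], str]
    reference: str

    def groups(self, df: pd.DataFrame) -> pd.Series:
        g = df.apply(self.grouper, axis=1)
        if self.reference not in set(g):
            raise DataIntegrityError(
                f"contrast {self.name!r}: reference group {self.reference!r} empty"
            )
        return g


POOLED = ContrastSet(
    "pooled_metformin_vs_placebo",
    lambda r: "placebo" if r["arm"] == "placebo" else "metformin",
    "placebo",
)
BY_DOSE = ContrastSet(
    "by_dose",
    lambda r: "placebo" if r["arm"] == "placebo" else f"{r['arm']} mg",
    "placebo",
)
BY_DURATION = ContrastSet(
    "by_duration",
    lambda r: "placebo" if r["arm"] == "placebo" else str(r["duration"]),
    "placebo",
)
LOWDOSE_SHORT_VS_REST = ContrastSet(
    "lowdose_short_vs_rest",
    lambda r: (
        "placebo"
        if r["arm"] == "placebo"
        else (
            "lowdose_short"
            if (r["arm"] == 500 and r["duration"] == "short")
            else "other_treatment"
        )
    ),
    "placebo",
)


@dataclass(frozen=True)
class EffectEstimate:
    """One contrast-level effect with Wald CI and one-sided p."""

    contrast: str
    level: str
    endpoint: str
    measure: str              # "OR" | "HR" | "beta"
    estimate: float
    ci_low: float
    ci_high: float
    one_sided_p: float
    n: int
    events: int
    benefit_direction: str    # "less" (fewer events better) or "greater"
    continuity_corrected: bool = False
    exploratory: bool = False
    note: str = ""

    @property
    def significant(self) -> bool:
        """One-sided p < 0.025, the trial's frequentist significance rule."""
        return self.one_sided_p < 0.025


def _one_sided_p(log_est: float, se: float, benefit: str) -> float:
    """One-sided p for H1 'treatment is beneficial'."""
    if se <= 0 or not np.isfinite(se):
        return float("nan")
    z = -log_est / se if benefit == "less" else log_est / se
    return float(stats.norm.sf(z))


def _benefit_direction(endpoint: str) -> str:
    return "less" if endpoint in HARM_ENDPOINTS else "greater"


def fit_binary_endpoint(
    df: pd.DataFrame,
    endpoint: str,
    contrast: ContrastSet = POOLED,
    *,
    exploratory: bool = False,
) -> list[EffectEstimate]:
    """Univariable logistic regression of a binary endpoint on group.

    One estimate per non-reference group versus the reference.  Groups in
    which the endpoint is constant get the Haldane-Anscombe 0.5 correction
    (flagged) instead of a crash.
    """
    y = df[endpoint].astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == y.size:
        raise DataIntegrityError(f"endpoint {endpoint} has no events or no non-events")
    groups = contrast.groups(df)
    benefit = _benefit_direction(endpoint)
    out = []
    ref_mask = (groups == contrast.reference).to_numpy()
    for level in sorted(set(groups) - {contrast.reference}, key=str):
        mask = (groups == level).to_numpy()
        a = int(y[mask].sum())          # events, treated
        b = int(mask.sum() - a)
        c = int(y[ref_mask].sum())      # events, reference
        d = int(ref_mask.sum() - c)
        corrected = 0 in (a, b, c, d)
        if corrected:
            a2, b2, c2, d2 = (v + 0.5 for v in (a, b, c, d))
            log_or = np.log(a2 * d2 / (b2 * c2))
            se = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
        else:
            sub = mask | ref_mask
            X = sm.add_constant(mask[sub].astype(float))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y[sub], X).fit(disp=False)
            log_or = float(fit.params[1])
            se = float(fit.bse[1])
        ci = 1.959963984540054 * se
        out.append(
            EffectEstimate(
                contrast=contrast.name,
                level=str(level),
                endpoint=endpoint,
                measure="OR",
                estimate=float(np.exp(log_or)),
                ci_low=float(np.exp(log_or - ci)),
                ci_high=float(np.exp(log_or + ci)),
                one_sided_p=_one_sided_p(log_or, se, benefit),
                n=int(mask.sum() + ref_mask.sum()),
                events=a + c,
                benefit_direction=benefit,
                continuity_corrected=corrected,
                exploratory=exploratory,
            )
        )
    return out


def fit_linear_endpoint(
    df: pd.DataFrame,
    endpoint: str,
    contrast: ContrastSet = POOLED,
    *,
    exploratory: bool = False,
) -> list[EffectEstimate]:
    """Univariable OLS (identity link) for continuous endpoints.

    Benefit direction: a larger value is better for hospital-free-day type
    endpoints, worse for length-of-stay type endpoints (``index_los_days``).
    """
    groups = contrast.groups(df)
    y = df[endpoint].astype(float).to_numpy()
    benefit = "less" if endpoint == "index_los_days" else "greater"
    out = []
    ref_mask = (groups == contrast.reference).to_numpy()
    for level in sorted(set(groups) - {contrast.reference}, key=str):
        mask = (groups == level).to_numpy()
        sub = mask | ref_mask
        X = sm.add_constant(mask[sub].astype(float))
        fit = sm.OLS(y[sub], X).fit()
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        ci = 1.959963984540054 * se
        out.append(
            EffectEstimate(
                contrast=contrast.name,
                level=str(level),
                endpoint=endpoint,
                measure="beta",
                estimate=beta,
                ci_low=beta - ci,
                ci_high=beta + ci,
                one_sided_p=_one_sided_p(beta, se, benefit),
                n=int(sub.sum()),
                events=0,
                benefit_direction=benefit,
                exploratory=exploratory,
            )
        )
    return out


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier survivor table (time, at-risk, survival)."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tbl = kmf.event_table
    surv = kmf.survival_function_
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "at_risk": tbl["at_risk"].reindex(surv.index).to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
        }
    )


def fit_time_to_event(
    df: pd.DataFrame,
    endpoint: str,
    contrast: ContrastSet = POOLED,
    *,
    exploratory: bool = False,
) -> tuple[list[EffectEstimate], dict[str, pd.DataFrame]]:
    """Cox proportional-hazards HR (Efron ties) plus per-group KM curves.

    ``endpoint`` names a binary column with a matching ``<stem>_time``
    column (e.g., ``reoperation_90`` / ``reoperation_time``).  Event-free
    patients are administratively censored at their ``censor_day`` (day 90,
    or death).  Rows flagged ``excluded_from_tte`` (withdrawals) are
    dropped.  Groups with no events are flagged and excluded from the Cox
    fit rather than crashing.
    """
    stem = endpoint.replace("_90", "")
    time_col = f"{stem}_time"
    if time_col not in df:
        raise ConfigError(f"missing time column {time_col!r} for {endpoint}")
    excluded = (
        df["excluded_from_tte"].astype(bool)
        if "excluded_from_tte" in df
        else pd.Series(False, index=df.index)
    )
    work = df.loc[~excluded].copy()
    event = work[endpoint].astype(bool)
    censor = (
        work["censor_day"].astype(float)
        if "censor_day" in work
        else pd.Series(90.0, index=work.index)
    )
    time = np.where(event, work[time_col].astype(float), censor)
    time = np.maximum(time, 0.5)  # day-0 events tie with entry; keep positive
    groups = contrast.groups(work)
    benefit = _benefit_direction(endpoint)
    curves = {
        str(level): km_curve(time[(groups == level).to_numpy()],
                             event[(groups == level).to_numpy()])
        for level in sorted(set(groups), key=str)
    }
    out = []
    ref_mask = (groups == contrast.reference).to_numpy()
    for level in sorted(set(groups) - {contrast.reference}, key=str):
        mask = (groups == level).to_numpy()
        n_ev = int(event[mask].sum() + event[ref_mask].sum())
        if event[mask].sum() == 0 or event[ref_mask].sum() == 0:
            out.append(
                EffectEstimate(
                    contrast=contrast.name,
                    level=str(level),
                    endpoint=endpoint,
                    measure="HR",
                    estimate=float("nan"),
                    ci_low=float("nan"),
                    ci_high=float("nan"),
                    one_sided_p=float("nan"),
                    n=int(mask.sum() + ref_mask.sum()),
                    events=n_ev,
                    benefit_direction=benefit,
                    exploratory=exploratory,
                    note="no events in one group; HR undefined",
                )
            )
            continue
        sub = mask | ref_mask
        cdf = pd.DataFrame(
            {"time": time[sub], "event": event[sub].astype(int),
             "treated": mask[sub].astype(float)}
        )
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(cdf, duration_col="time", event_col="event")
        log_hr = float(cph.params_["treated"])
        se = float(cph.standard_errors_["treated"])
        ci = 1.959963984540054 * se
        out.append(
            EffectEstimate(
                contrast=contrast.name,
                level=str(level),
                endpoint=endpoint,
                measure="HR",
                estimate=float(np.exp(log_hr)),
                ci_low=float(np.exp(log_hr - ci)),
                ci_high=float(np.exp(log_hr + ci)),
                one_sided_p=_one_sided_p(log_hr, se, benefit),
                n=int(sub.sum()),
                events=n_ev,
                benefit_direction=benefit,
                exploratory=exploratory,
            )
        )
    return out, curves


def ordinal_or_more_hfd(df: pd.DataFrame, contrast: ContrastSet = POOLED) -> list[EffectEstimate]:
    """Frequentist proportional-odds fit of HFD-90 (OR > 1 = more HFD, better).

    The maximum-likelihood cumulative-logit counterpart of the Bayesian
    primary model, used for the prespecified frequentist sensitivity
    analyses.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    groups = contrast.groups(df)
    y = df["hfd90"].astype(int)
    out = []
    ref_mask = (groups == contrast.reference).to_numpy()
    for level in sorted(set(groups) - {contrast.reference}, key=str):
        mask = (groups == level).to_numpy()
        sub = mask | ref_mask
        ysub = pd.Series(pd.Categorical(y[sub], ordered=True))
        X = mask[sub].astype(float)[:, None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = OrderedModel(ysub, X, distr="logit").fit(disp=False, method="bfgs")
        beta = float(np.asarray(fit.params)[0])
        se = float(np.asarray(fit.bse)[0])
        ci = 1.959963984540054 * se
        out.append(
            EffectEstimate(
                contrast=contrast.name,
                level=str(level),
                endpoint="hfd90",
                measure="OR",
                estimate=float(np.exp(beta)),
                ci_low=float(np.exp(beta - ci)),
                ci_high=float(np.exp(beta + ci)),
                one_sided_p=_one_sided_p(beta, se, "greater"),
                n=int(sub.sum()),
                events=0,
                benefit_direction="greater",
            )
        )
    return out


_SUBGROUP_FACTORS = ("age_median_split", "sex", "frailty", "stratum", "operative_stress")


def subgroup_suite(
    df: pd.DataFrame,
    factor: str,
    endpoint: str,
    *,
    engine: str = "binary",
) -> dict[str, list[EffectEstimate]]:
    """Pooled metformin-vs-placebo estimates within each level of a factor.

    ``factor`` is one of age_median_split / sex / frailty / stratum /
    operative_stress; the age split point is the analysis cohort's own
    median.  Exploratory: no multiplicity adjustment (estimates are flagged
    ``exploratory=True``).  Empty or degenerate levels are skipped with a
    warning.
    """
    if factor not in _SUBGROUP_FACTORS:
        raise ConfigError(f"unknown subgroup factor {factor!r}")
    col = {
        "age_median_split": "age",
        "sex": "sex",
        "frailty": "frailty_category",
        "stratum": "stratum",
        "operative_stress": "operative_stress",
    }[factor]
    if col not in df:
        raise ConfigError(f"cohort table lacks column {col!r}")
    if factor == "age_median_split":
        med = float(df["age"].median())
        levels = pd.Series(
            np.where(df["age"] < med, f"<{med:g}", f">={med:g}"), index=df.index
        )
    else:
        levels = df[col].astype(str)
    out: dict[str, list[EffectEstimate]] = {}
    for level in sorted(set(levels), key=str):
        sub = df.loc[(levels == level).to_numpy()]
        if sub.empty or sub["arm"].nunique() < 2:
            warnings.warn(f"subgroup {factor}={level}: too few groups, skipped")
            continue
        try:
            if engine == "binary":
                ests = fit_binary_endpoint(sub, endpoint, POOLED, exploratory=True)
            elif engine == "ordinal":
                ests = [
                    e.__class__(**{**e.__dict__, "exploratory": True})
                    for e in ordinal_or_more_hfd(sub, POOLED)
                ]
            else:
                raise ConfigError(f"unknown subgroup engine {engine!r}")
        except DataIntegrityError as exc:
            warnings.warn(f"subgroup {factor}={level}: {exc}; skipped")
            continue
        out[str(level)] = ests
    return out


def estimates_frame(estimates) -> pd.DataFrame:
    """Tidy results table for a list (or dict of lists) of estimates."""
    if isinstance(estimates, Mapping):
        rows = [
            {**e.__dict__, "subgroup_level": k}
            for k, lst in estimates.items()
            for e in lst
        ]
    else:
        rows = [e.__dict__ for e in estimates]
    return pd.DataFrame(rows)
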