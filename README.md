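# spry

Simulation and analysis toolkit for a randomized, embedded, multifactorial
**adaptive platform trial** in perioperative medicine: older adults
scheduled for major elective surgery are randomized √3:1:1:1 to placebo or
three daily doses of a study drug, stratified by clinic, age category, and
planned pre-operative exposure duration (short 7–28 d / medium 29–90 d /
long >90 d), and followed for 90 postoperative days.

The primary endpoint is **HFD-90, 90-day hospital-free days** — an ordinal
composite on {−1, 0, 1, …, 90}: −1 for death within 90 days, 0 for
patients alive but hospitalized the whole period, otherwise the days alive
and out of hospital. The primary analysis is a **hierarchical Bayesian
proportional-odds model**

```
logit P(Y ≤ k) = γ_k + λ_stratum + θ(dose, duration)
θ(d,u) = μ + α_d + β_u + ε_du,   α_d ~ N(0, τ_α²),  β_u ~ N(0, τ_β²),
ε_du ~ N(0, τ_ε²),   τ ~ Half-Normal(0.5)
```

whose hierarchy *borrows* information across the 3 × 3 dose-by-duration
grid. `exp(θ)` is the median posterior proportional odds ratio (mpOR)
toward **fewer** hospital-free days — mpOR > 1 is worse — and a dose is
declared superior when its one-sided posterior probability of benefit
exceeds 0.975. Interim analyses at every 500th enrollment (cap 2500)
re-weight randomization toward better doses and drop futile ones.

Because the motivating trial's patient-level data are not public, the
package ships a **calibrated synthetic-patient generator** (null cohort:
median HFD-90 = 88, IQR 85–90; stratum mix 29/38/13/20; ~13.5%
reoperation, ~10% readmission, 18.4% nonadherence with 6.7% withdrawal)
that injects treatment effects as exact proportional-odds shifts, plus the
trial's frequentist secondary suite (logistic ORs, Cox HRs with
Kaplan-Meier curves, subgroup analyses) and a Monte-Carlo
operating-characteristics study of the whole adaptive design.

Intended users: trial statisticians and methods researchers who want a
tested, reproducible re-implementation of this design's machinery to study
its behavior under controlled truths.

## Worked example

```python
import numpy as np
from spry import (CohortConfig, EffectScenario, HierarchicalOrdinalModel,
                  Randomizer, generate_cohort, generate_course, compute_hfd90)

cfg = CohortConfig(n_patients=8000, seed=5)
rng = np.random.default_rng(5)
scenario = EffectScenario.uniform_effect(dose=1000, por=0.74)  # 1000 mg helps

patients = generate_cohort(cfg, rng)
randomizer = Randomizer(rng=rng)                 # √3:1:1:1 permuted blocks
rows = []
for p in patients:
    a = randomizer.assign(p)
    course = generate_course(p, a.arm, scenario, cfg, rng)
    if course.surgery_performed:
        rows.append((compute_hfd90(course).value, a.arm,
                     a.duration_stratum, p.surgical_stratum))

y, arm, dur, stratum = map(np.array, zip(*rows))
res = HierarchicalOrdinalModel(y, arm, dur, stratum).fit(seed=5)
print(res.summary())
print("decision:", res.decide())
```

prints (abridged):

```
Hierarchical proportional-odds model for HFD-90
engine: laplace   draws: 4000   max R-hat: 1.000   min ESS: 4000
n = 7467 (2758 placebo); 16 outcome categories
mpOR > 1 = higher odds of fewer hospital-free days (worse)
------------------------------------------------------------------------------
contrast                    mpOR    2.5%   97.5%   P(sup)  P(best)     n
metformin (pooled)         0.902   0.831   0.979    0.992        -  4709
500 mg                     0.994   0.891   1.109    0.540    0.000  1576
1000 mg                    0.709   0.635   0.795    1.000    1.000  1556
1500 mg                    1.038   0.930   1.158    0.252    0.000  1577
short                      0.896   0.822   0.975    0.994        -  2896
...
decision: {500: 'equivalent', 1000: 'superior', 1500: 'equivalent'}
```

The 1000 mg arm — the one the scenario made effective with true
proportional odds ratio 0.74 — is recovered (mpOR 0.709, 95% CrI
0.64–0.80) with posterior probability of benefit 1.000 (> 0.975, so
`decide()` classifies it "superior") and P(best) = 1.0, while the null
doses sit at ~1 and classify as equivalent under the default 1.25
margin.

Simulate the whole adaptive design:

```sh
spry simulate --scenario uniform-15 --replicates 200 --seed 7 --out oc.json
spry generate --n 1000 --seed 3 --out cohort.csv
spry analyze cohort.csv --model primary --out posterior.csv
```

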