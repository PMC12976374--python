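# pahburden

Probabilistic assessment of dietary exposure to polycyclic aromatic
hydrocarbons (PAHs) and the cancer burden attributable to it, built around
the data structure of a national total diet study (TDS): composite food
samples analysed for the four EU marker PAHs — benz[a]anthracene (BaA),
benzo[a]pyrene (BaP), benzo[b]fluoranthene (BbF) and chrysene (Ch), summed
as PAH4 — paired with a 24-hour-recall food consumption survey.  It is
written for food-safety risk assessors and biostatisticians who need a
tested, reproducible implementation of this exposure → risk → burden chain,
including a synthetic TDS generator so every stage can be exercised and
validated without access to confidential survey microdata.

## Model

**Exposure.**  Each Monte Carlo iteration resamples one person-day (one
respondent's 24-hour diet, amounts in g food per kg body weight) uniformly
from the survey, draws one composite sample per food consumed (one sample
index shared across the four analytes), and accumulates

&nbsp;&nbsp;&nbsp;&nbsp;*E* = 10⁻⁶ · Σ_foods  amount (g/kg bw) · [PAH4] (µg/kg)   [mg/kg bw/d],

where [PAH4] = [BaA] + [BaP] + [BbF] + [Ch].  Non-detects are left-censored
at the limit of detection (LOD, default 0.15 µg/kg) and substituted per
scenario: **optimistic** (lower bound, 0 µg/kg) or **pessimistic** (upper
bound, the LOD).  With common random numbers the two scenarios share all
draws, so the pessimistic run dominates the optimistic one at every
iteration.  100,000 iterations give a stable frequency distribution.

**Prevalence.**  The exposed-population share *p* is the higher-mean
cluster's fraction under two-means clustering of the simulated
distribution, solved *exactly* in 1-D by minimising the within-cluster sum
of squares over all sorted-order cut points (no initialisation
sensitivity); a Mann-Whitney U test confirms the clusters differ, with
Shapiro-Wilk and Levene as assumption checks.

**Risk and burden.**  From the median exposure *E*₅₀:

- lifetime cancer risk *R* = *E*₅₀ · SF_avg · *t*/*L*, with SF_avg an
  average slope factor ((mg/kg bw/d)⁻¹), *t* = 65 exposure years and
  *L* = 83 years life expectancy;
- excess-risk relative risk RR = 1 + *R*/(*T* − *R*) against the
  background lifetime cancer risk *T* = 0.25;
- Levin's population attributable fraction
  PAF = *p*(RR − 1) / (*p*(RR − 1) + 1);
- attributable burden = PAF × total all-cancer DALYs (a required input,
  e.g. 158,418 years for Singapore 2021).

The median exposure is also classified against a PAH4 minimal risk level
(MRL, default 4.84 × 10⁻⁴ mg/kg bw/d).

## Worked example

```python
from pahburden import (RiskParams, SimConfig, SynthConfig,
                       OPTIMISTIC, PESSIMISTIC, simulate, kmeans2, summarize,
                       burden_chain)
from pahburden.synthetic_tds import (generate_catalog, generate_concentrations,
                                     generate_survey)
import numpy as np

cfg = SynthConfig(seed=1)                     # 21 categories, 264 foods, 2,000 adults
catalog = generate_catalog(cfg)
records = generate_concentrations(catalog, cfg)
survey = generate_survey(catalog, cfg)

sim = SimConfig(iterations=100_000, seed=1)   # common random numbers by default
pes = simulate(survey, records, PESSIMISTIC, sim)
opt = simulate(survey, records, OPTIMISTIC, sim)
print(f"dominance: {np.mean(pes.values >= opt.values):.1%}")

s = summarize(pes)
clusters = kmeans2(pes.values)
res = burden_chain(s.median, clusters.prevalence,
                   RiskParams(total_cancer_dalys=158_418.0))
print(f"median {res.exposure_median:.3e} mg/kg bw/d, "
      f"prevalence {res.prevalence:.1%}, risk {res.cancer_risk:.3e}, "
      f"PAF {res.paf:.3e}, {res.attributable_daly:.2f} DALYs, MRL {res.mrl_status}")
```

prints

```
dominance: 100.0%
median 4.050e-05 mg/kg bw/d, prevalence 18.4%, risk 8.088e-05, PAF 5.952e-05, 9.43 DALYs, MRL below
```

i.e. on this synthetic TDS the upper-bound scenario's median intake is
4.05 × 10⁻⁵ mg/kg bw/d, 18.4% of simulated person-days fall in the exposed
cluster, and the implied burden is ~9 DALY-years out of 158,418 — an
MRL-compliant, very small attributable burden.  The numbered scripts under
`analysis/` run the same chain end to end and leave their tables under
`results/`; the `pahburden` CLI (`synth`, `simulate`, `stats`, `cluster`,
`burden`, `cooking-test`, `run`) exposes each stage on CSV/YAML files.

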