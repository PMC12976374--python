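# Methods

## Scope and data model

The package implements an acute (person-day) probabilistic dietary exposure
assessment for PAH4 — the summed concentration of benz[a]anthracene,
benzo[a]pyrene, benzo[b]fluoranthene and chrysene — and the downstream
cancer-burden chain.  Its inputs mirror a total diet study: a laboratory
table of composite-sample × analyte concentrations with left-censored
non-detects, a 24-hour-recall consumption survey, and a food catalog with
category and cooking-method labels.  Units are canonical: concentrations
and LODs in µg/kg food, consumption in g food per kg body weight per day,
exposures in mg/kg bw/d.  The single 10⁻⁶ conversion is applied exactly
once, to each iteration's total — never per record — which also makes the
degenerate constant-input case bit-exact.

## Monte Carlo exposure model

Each iteration: (1) one person-day drawn uniformly with replacement from
the survey — the minimal-assumption reading of random person-day selection
under independence across respondents; (2) for each food in that diet, one
composite sample drawn uniformly (empirical resampling of the laboratory
data rather than a fitted parametric law; a parametric variant would be a
straightforward extension); the drawn sample index is shared across the
four analytes, preserving the within-sample correlation that exists
because all four were measured on the same composite; (3) non-detect
substitution by scenario — 0 µg/kg (optimistic lower bound) or the
record's own LOD (pessimistic upper bound; 0.15 µg/kg at the default LOD);
(4) summation and unit conversion.

Randomness policy: one root seed; person-day and sample draws come from
separately keyed substreams.  With `common_random_numbers` (default) the
substreams ignore the scenario label, so both scenarios see identical
draws and substitution is the only difference — giving pathwise dominance
(pessimistic ≥ optimistic at every iteration), which the tests assert at
100,000 iterations.  Without coupling, only median dominance is asserted.
Surveyed foods with no laboratory record contribute zero exposure (logged
per food): any other fill-in could inflate the optimistic lower bound.

Default iteration count is 100,000; at that size the median's two-seed
relative difference on the default synthetic data is well under the 2%
stability band the tests require (observed ≈ 0.4%).

## Non-detect scenarios

The two scenarios bracket the true exposure: if even the optimistic
estimate exceeded the MRL, true exposure would too; if even the
pessimistic one lies below it, there is little concern.  Records carry
their own LOD so the upper bound generalises to per-record detection
limits without code changes; the default 0.15 µg/kg applies to all
analytes.

## Distribution summary

Order statistics use linear interpolation (`numpy.percentile` default).
Kurtosis is the Pearson population-moment ratio m₄/m₂² (normal → 3, not
excess kurtosis): under this convention a value like 2.49 is correctly
read as "close to normal", which the excess convention would garble.
`proportion_positive` is the strictly-greater-than-zero fraction; it is
reported alongside the clustering prevalence because the two answer
different questions — under upper-bound substitution every iteration is
positive, so a "positive exposure" share below 100% can only be a
cluster share.  The burden chain consumes the clustering prevalence; both
are logged.

## Exposure prevalence by exact 1-D two-means

The two-means objective in one dimension is minimised exactly: sort the
values, evaluate the within-cluster sum of squares at every cut between
distinct consecutive values via prefix sums, take the argmin.  Any
converged Lloyd run can at best reach this optimum, and restricting cuts
to distinct-value boundaries is without loss because an optimal two-means
partition in 1-D is a threshold partition.  This removes the
initialisation sensitivity that iterative k-means exhibits on skewed,
outlier-heavy exposure distributions.  That sensitivity is real: in the
equivalence test, fully converged scikit-learn KMeans (20 starts,
tol 10⁻¹², 1000 iterations) lands in a strictly worse local optimum on a
small fraction of heavy-tailed samples, so the test asserts the exact
solver is never beaten on the shared objective and that partitions
coincide whenever Lloyd attains the optimum (the overwhelmingly common
case), rather than demanding label agreement with a sometimes-suboptimal
baseline.  `lloyd_kmeans2` is retained purely as that cross-check.

The exposed cluster is the higher-mean one; its share is the prevalence
*p*.  Prevalence is invariant to positive affine rescaling of exposures.
Cluster separation is verified by a two-sided Mann-Whitney U test
(tie-corrected, asymptotic for large products of sample sizes);
Shapiro-Wilk (subsampling inputs above n = 5000, logged) and Levene
checks are reported as warnings only — they gate nothing, since they
verify rather than license the nonparametric comparison.

## Risk and burden chain

Lifetime cancer risk R = E₅₀ · SF_avg · t / L with t = L − 18 = 65 adult
years at risk and L = 83 years life expectancy.  The four oral slope
factors (BaA 10⁻¹, BaP 10¹, BbF 10⁻¹, Ch 10⁻³ (mg/kg bw/d)⁻¹) collapse to
SF_avg by arithmetic mean (2.55025) by default, with a `fixed` override.
The override matters: a single effective slope factor of ≈ 0.300
back-solved from the optimistic exposure–risk pair (1.97 × 10⁻⁴ →
4.63 × 10⁻⁵) also reproduces the pessimistic pair (2.20 × 10⁻² →
5.17 × 10⁻³) to three significant figures, so the consistency tests and
the acceptance script use that back-solved value; the averaging rule that
produces it from the four listed factors is not derivable from the inputs,
hence both routes are exposed rather than hard-coding either.

Relative risk uses the excess-risk reading RR = 1 + R/(T − R) with
T = 0.25 background lifetime cancer risk.  The plain ratio R/(T − R) is
exposed as `literal_relative_risk` but is below 1 for any realistic
dietary risk (R ≪ T/2), which would drive Levin's attributable fraction
negative; the excess-risk form sends RR → 1 as R → 0 and reproduces the
published attributable fractions (1.64 × 10⁻⁵ and 6.44 × 10⁻³) from their
stated prevalences.  PAF is Levin's formula; attributable DALYs are
PAF × total all-cancer DALYs.  The DALY total is a *required* parameter:
published figures pair a PAF of 6.44 × 10⁻³ with 92.5 attributable DALYs,
implying a total near 14,400, while the cited all-cancer total is 158,418
(of which 92.5 is 0.06%); since the two cannot be reconciled from the
available inputs, the package computes the plain product from whatever
total the caller supplies and refuses to embed either constant.

The MRL comparison is strict: an exposure exactly at 4.84 × 10⁻⁴ mg/kg
bw/d is "below".  The MRL's derivation (TEF scaling from a BaP reference)
is upstream of this package; it is a configuration constant.

## Synthetic TDS generator

The generator reproduces the *design* of the study — 21 food categories
over 264 foods, two composite samples per food, 2,000 adult respondents —
and the statistical features the pipeline's behaviour depends on, chosen
once as realistic for PAH occurrence data: a 30% detection rate (PAH
non-detect rates in national TDS tables are commonly 60–80%), detected
concentrations lognormal(µ = 0, σ = 1.2) µg/kg (median 1 µg/kg, heavy
right tail — the source of the leptokurtic exposure distributions), LOD
0.15 µg/kg, Poisson(8) distinct foods per person-day (floored at one),
amounts lognormal(0.5, 0.9) g/kg bw (median ≈ 1.6 g/kg bw, a few hundred
grams for a typical adult), ages uniform on [18, 83].  Body weight is
folded into the g/kg-bw amounts, as in the survey encoding; it is never
used separately.  Cooking methods cycle through a fixed six-label
vocabulary, independent of concentration — so the cooking-method
Kruskal-Wallis test on synthetic data probes the machinery, not a real
effect.

What the generator does *not* emulate: category-specific concentration
profiles, correlation between diet composition and contamination,
age/ethnicity stratification, seasonal effects, and any real-data medians
or kurtoses.  Passing tests therefore demonstrate correctness of the
computational chain and its statistical behaviour under known conditions,
not agreement with any population's measured exposure.

A separate two-component normal mixture fixture (`generate_bimodal_sample`,
separation constraint low + 4σ < high, truncation at zero by clipping —
inactive under the constraint with a positive low mean) provides ground
truth labels for validating the clustering stage: exact two-means recovers
a 30% high-component weight within binomial sampling error at n = 10,000.

## Numerical and policy choices

- Exposure accumulation is vectorised (flat event arrays, `bincount`);
  100,000 iterations over the default survey take well under a second.
- Two-means ties: cuts are only placed between distinct sorted values;
  the threshold is the midpoint of the boundary pair.
- Kruskal-Wallis on an all-tied pooled sample returns H = 0, p = 1
  (no evidence of difference) rather than an error.
- Validation is total and row-addressed: every malformed CSV row raises
  with its row number and field.  CSV round-trips are exact (`repr`
  serialisation of floats).
- Seeds: every stochastic component takes an explicit seed; generators and
  the simulator derive labelled substreams from it, so end-to-end runs are
  bit-reproducible and scenario coupling is explicit.

## Problem sizes used in the test suite

Unit and property tests run on reduced designs (36–48 foods, 120–150
respondents, 2,000–20,000 iterations); the end-to-end statistical checks
(scenario dominance, median stability) run at the full design — 264 foods,
2,000 respondents, 100,000 iterations — which the vectorised engine makes
cheap.  Simulation-based calibration checks (Levene type-I error at 1,000
replicates, Kruskal-Wallis power at 500 replicates of n = 30 per group)
use binomial-error acceptance bands.

## Known limitations

- Acute exposure only: person-days are resampled independently, so the
  model says nothing about habitual (chronic) intake of individuals.
- The exposed/unexposed dichotomy inherits k-means' behaviour on skewed
  data; on a unimodal right-skewed distribution the "exposed" cluster is a
  tail split, and its share should be read as a model quantity, not a
  biological prevalence.
- The chain treats PAH4 as a single agent with one slope factor; no
  per-congener or per-cancer-site attribution is attempted.
- Non-detect handling is bounding substitution, not a censored-likelihood
  estimator; the two scenarios bracket rather than estimate the truth.
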