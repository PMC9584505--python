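# Methods

## The model

`qcindex` turns a stratified burden-of-disease panel — incidence,
prevalence, deaths, DALYs, YLLs and YLDs per (location, year, sex,
age-group) stratum — into a composite Quality of Care Index (QCI) on a
0–100 scale, then derives gender- and age-disparity summaries from it.

The premise is epidemiological: holding incidence fixed, better care keeps
patients alive longer. Four ratio indices encode this:

| index       | definition            | direction            |
|-------------|-----------------------|----------------------|
| `prev_inc`  | prevalence / incidence| higher = better care |
| `mir`       | deaths / incidence    | higher = worse care  |
| `daly_prev` | DALYs / prevalence    | higher = worse care  |
| `yll_yld`   | YLLs / YLDs           | higher = worse care  |

Each is a ratio of two quantities measured on the same stratum population,
so it is identical whether computed from counts or from rates — the
package exposes both and tests the invariance.

The QCI is the first principal component of these four indices over a
fitting pool of strata, with three deliberate choices where the
construction is underdetermined:

1. **Correlation, not covariance.** The indices live on incommensurate
   scales (`yll_yld` can be an order of magnitude above `mir`), so each
   feature is z-scored before the eigendecomposition. Covariance-PCA would
   let the widest-ranged index dominate the component.
2. **Orientation.** The leading eigenvector is defined only up to sign.
   We first negate the three "worse-care" indices so that larger = better
   on every column, then fix the eigenvector sign so the loading sum is
   positive (tie-break: first nonzero loading positive). This makes
   "higher score = better care" a testable contract rather than a
   convention, and lets tests assert that lowering a stratum's
   mortality-to-incidence ratio can never lower its score.
3. **0–100 scale = min–max over the fitting pool.** The raw projection is
   rescaled so the pool's minimum maps to 0 and its maximum to 100;
   strata scored outside the pool's range are clipped. Percentile anchors
   (`lower_q`/`upper_q`) are available when outliers should not own the
   endpoints; the default is the true min–max (0, 1).

Zero-variance features are dropped before the PCA and recorded on the
fitted model. Strata with a missing index (zero denominator or absent
measure) are excluded from fitting and scored as missing — imputation
would manufacture quality signal. All fitted state (means, SDs, loadings,
score anchors, pool size, dropped features) round-trips through a
human-readable `model.yaml`.

Two fitting pools are supported: `location-year-sex` on age-standardized
rates (the headline, cross-population comparable view) and
`location-year-sex-age` on the five-year bands (for age-gradient
analyses). One global fit per pool; pool composition is logged.

## Age-standardization

Direct standardization: the age-standardized rate is the weighted mean of
band-specific rates under fixed standard-population weights, normalized to
sum to 1. The shipped `world_standard_weights()` table is a synthetic
stand-in built from the WHO World Standard population proportions
restricted to the 15–85+ analysis bands; any weights CSV
(`age_group,weight`) can be supplied instead. Standardization is linear in
rates and leaves an age-constant panel unchanged (tested).

## Disparity metrics

* **GDR** (gender disparity ratio) = female QCI / male QCI per
  (location, year, age-group); 1 means gender-equal care. Missing when
  either score is missing or the male score is zero.
* **Net change** = value(year_to) − value(year_from) per group.
* **Rounding**: ratios and differences are chained on unrounded values and
  rounded half-up only in the reported column (2 places for GDR, 1 for
  QCI). This reproduces published-table arithmetic such as
  0.86 − 0.68 = 0.18 without double-rounding drift.
* **Rankings** sort by QCI descending with ties broken by location label
  ascending (documented, deterministic).
* **Age gradient**: band-level scores are summarized into coarse bins
  (15–49, 50–74, 75+) as standard-population-weighted means of the member
  bands, weights renormalized within each bin.
* **External validation** is a Pearson correlation between QCI and a
  reference index (e.g. a healthcare access and quality index) over shared
  (location, year) keys.

## The synthetic cohort generator

The generator exists so the whole pipeline is verifiable without any real
extract: every stratum carries a latent care quality `q ∈ [0, 1]` and the
six measures are derived from it consistently (see `qcindex/simulate.py`
for the exact maps). Key properties, all asserted in tests:

* DALY = YLL + YLD holds bitwise in every stratum and both metrics;
* with noise off, each of the four indices is strictly monotone in `q`
  stratum-wise, in the direction the orientation step assumes;
* with defaults (20 locations × 1990–2019 × 2 sexes × 15 bands, 5%
  lognormal noise on incidence), the fitted QCI recovers `q` with Spearman
  ρ ≈ 0.94 over all 18 000 strata, and ρ ≈ 1.0 at the age-standardized
  location-year-sex level.

Default parameters and what they emulate: a three-fold male/female
incidence ratio typical of bladder cancer; baseline incidence rising
steeply with age (~0.2 to ~110 per 100 000); case fatality mapped from
`q` between `mir_max = 0.9` and `mir_min = 0.1`; steady-state prevalence
= incidence × survival duration, with duration between 2 and 12 years;
disability weight 0.05; residual life expectancy falling from 65 to 5
years across bands; latent quality with a per-location base level spread
over [0.15, 0.85], a +0.003/year trend, a 0.05 male−female gap (so GDR <
1 emerges), and a 0.15 decline from the youngest to the oldest band.

Choices worth flagging. The steady-state prevalence model replaces a
cohort simulation — it is enough to induce the intended monotonicities and
keeps the generator analytic. Noise enters through incidence only and
propagates downstream, which keeps the DALY identity exact; a consequence
is that the ratio indices are noise-free functions of (q, age), so the
residual recovery error comes from the age-varying life-expectancy term in
`yll_yld` and `daly_prev`, not from the noise level. What the generator
does *not* emulate: registry undercounting, measure-specific estimation
error, uncertainty intervals, cause-specific epidemiology. Passing
recovery tests therefore show the construction is internally sound, not
that any real-world score is correct.

## Numerical and degenerate-input policy

* PCA via a full SVD on the z-scored pool (sample SD, ddof = 1);
  explained variance ratio = top eigenvalue / number of kept features.
  Tests require agreement with a dense eigendecomposition of the
  correlation matrix to 1e−8.
* Zero variance detection at relative tolerance 1e−12; an all-constant
  pool is an error ("zero total variance"), as is a pool of fewer than two
  complete strata.
* Zero denominators: default policy flags the index as missing with a
  recorded reason (`zero_incidence`, `zero_prevalence`, `zero_yld`,
  `absent_measure`); an `epsilon` policy (add ε to the denominator) is
  available but not default, because it distorts the `yll_yld` tail.
* Reductions run in fixed order on sorted strata; rerunning a pipeline
  config yields byte-identical numeric artifacts (tested).

## Problem sizes

Tests and the acceptance script run the generator at its default size
(18 000 strata, ~216 000 panel rows) for recovery checks and smaller
panels (5–6 locations, 5–10 years) for unit and pipeline tests; the PCA
oracle comparison uses 102 random pools of n ∈ {10, 100, 1000}. These
sizes make every check exact or tightly converged while keeping the whole
suite in seconds.

## Known limitations

* Real-data headline scores depend on the exact fitting pool; two
  different pools give differently anchored 0–100 scales. The fitted
  model.yaml records everything needed to score new strata on a frozen
  scale.
* Min–max anchoring is sensitive to single extreme strata; use percentile
  anchors on noisy panels.
* "both"-sex rows are consumed as data, never synthesized from the two
  sexes (rates cannot be summed without population weights).
* The mixed-effects external-validation model is out of scope; only the
  Pearson correlation against a reference index is provided.
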