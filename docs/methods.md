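# Methods notes

## Scope and data model

The package operates on three plain-text tables: a long composition table
(`sample_id, site_id, year, month, round, taxon_id, rra`), per-taxon
metadata (`taxon_id, family, crop_flag`), and monthly site climate
(`site_id, year, month, t_mean, p_sum`) with site coordinates.  RRA values
of one sample lie on the simplex.  Climate is monthly, so the two sampling
rounds of a month share one climate record by construction — niche
observations are therefore clustered within site × month, which the KDE
treats as independent weighted observations (a deliberate simplification;
see limitations).

## Preparation

Sub-1% entries are removed per sample and the survivors renormalised to
sum 1 by default.  Renormalisation preserves ratios among surviving taxa and
keeps per-sample risk partitions on the simplex; it can be disabled
(`renormalise=False`) since either reading of the filter is defensible.
Prevalence counting (strictly more than 5 distinct sites, at least 10
distinct samples, i.e. ≥6 / ≥10) is applied *after* the 1% filter, matching
the order of the preparation chain.  Taxa failing the filter, or rejected as
degenerate during profiling, are excluded from every downstream numerator
and denominator rather than renormalised away; samples emptied by the 1%
filter are dropped with a warning.

## Niche estimation

* Kernel: Gaussian, one axis at a time (no bivariate temperature ×
  precipitation density — each axis is thresholded independently).
* Weights: the taxon's RRA per sample, normalised to sum 1.  An unweighted
  mode exists as a diagnostic flag.
* Bandwidth: Silverman's rule `0.9·min(σ̂, IQR/1.34)·n_eff^(−1/5)` with the
  weighted standard deviation, weighted IQR and Kish effective sample size
  `(Σw)²/Σw²`; Scott's rule and a fixed bandwidth (axis units) are
  selectable.  Weighted-KDE bandwidth selection has no canonical rule; the
  ESS plug-in is the standard pragmatic choice.
* Grid: 512 points spanning the observation range padded by 3 bandwidths.
  Precipitation support is truncated at 0 (no reflection) and the density
  renormalised — the simplest positive-support correction, which slightly
  redistributes mass toward the interior for taxa observed near 0 mm.
* Thresholds: the 1/5/10/90/95/99 percentiles of the trapezoid-integrated
  CDF, inverse-interpolated linearly.  Weighted empirical quantiles are kept
  in the package (`weighted_quantile`) as the brute-force oracle the KDE
  path is tested against at small bandwidth.
* Degenerate taxa (fewer than 2 distinct climate values) are rejected with a
  logged warning rather than given zero-width niches.

## Risk classification

Classification uses pure threshold comparisons, so values beyond the fitted
grid behave as clamped CDF values (far above the grid ⇒ critical on
temperature; far below ⇒ critical on precipitation).  Boundary conventions:
a value exactly at q90 (temperature) or q10 (precipitation) is still *low*;
strict inequalities move classes up.  The combined class is the ordinal
maximum of the axes — the minimal ordinal extension of "at risk on either
axis".  Perturbed precipitation is clamped at 0 mm (negative rainfall is
meaningless).  Latitude bands are integer-degree floors.

## Resistance, resilience, replacement search

Resistance and resilience are taxon *counts*, not RRA-weighted.  The
replacement search processes a sample's at-risk taxa greedily in descending
focal RRA (ties lexicographic); each takes its geographically nearest
qualifying candidate (ties lexicographic), where qualification means: same
family, not the focal taxon, not already used in the sample, and at least
one low/low-classified occurrence within the search radius *evaluated at the
candidate's own location* under the same scenario.  Evaluating candidates
where they occurred (rather than re-projecting them onto the focal site's
climate) follows from reading the radius criterion as "occurred within
500 km".  Greedy matching can in principle fall short of the maximum
bipartite matching; the acceptance suite checks it equals the brute-force
optimum in ≥95% of small cases, and a reference (slow, pandas) search is
kept and tested identical to the optimised path.  A sample with no at-risk
taxa reports resilience 1.0 with a `zero_risk` flag by default ("one"
convention, keeping resilience total for density plots); the "exclude"
convention reports NaN instead.

## Synthetic data

The generator emulates the *design* of a continental pollen survey, not
foraging behaviour: site latitudes uniform on 35–65° N (longitudes
−10–30° E, a European extent so the 500 km radius is meaningful), monthly
temperature = 36 − 0.45·lat + 8·cos(2π(month−7)/12) + N(0, 1.5) °C and
precipitation = −10 + 1.3·lat + N(0, 15) mm clipped at 0 — realistic
May–August magnitudes with the dominant latitude/season structure and no
spatial autocorrelation beyond the latitude trend.  Taxa have Gaussian
suitability kernels (σ_T = 3 °C, σ_P = 25 mm, centres uniform over the
realised climate envelope), lognormal base propensities, and 30 family
labels; 10% are crops whose propensity is ×10 in May (a mass-flowering
pulse).  Realised compositions are Dirichlet draws centred on normalised
suitability with total concentration 50 — enough noise to be realistic while
keeping niche recovery feasible at ~2480 samples (310 sites × 4 months × 2
rounds, the study-like default scale).  All randomness flows from one root
seed split into per-stage child streams.

What passing tests on this fixture do **not** show: robustness to spatially
autocorrelated climate, non-Gaussian or multimodal real niches, phenology
beyond the single crop pulse, or read-level taxonomic error.

## Numerical and size choices

* Determinism: every table is written with `%.10g` formatting; the run
  manifest stores SHA-256 digests per table and a combined content hash, and
  re-running a config+seed reproduces the hashes byte for byte.
* The full default run (121 scenarios, replacement search included) takes
  ~20 s on one CPU; the per-scenario search precomputes the site distance
  matrix and each taxon's nearest low/low occurrence per site, leaving a
  small greedy loop per sample.
* Test problem sizes are set from error budgets, not speed: e.g. the niche
  parameter-recovery check uses 50 000 draws per synthetic taxon because the
  KDE mode's sampling SD shrinks only as n^(−1/5), and smaller n would test
  Monte-Carlo noise rather than estimator correctness.

## Known limitations

* Realised niches are availability-confounded: a taxon foraged only where a
  climate occurs looks narrow even if physiologically tolerant.  This is
  inherent to the exceedance framing.
* Scenarios are uniform offsets, not downscaled climate projections; no
  extreme-event structure.
* Replacement candidates count equally regardless of nutritional quality or
  abundance, and one qualifying occurrence suffices — resilience is an upper
  bound under the stated criteria.
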