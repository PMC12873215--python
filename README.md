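# pollenrisk

Climate-exceedance risk analysis for pollinator food resources, built around
pollen-metabarcoding composition data.

## The problem

Honey bees (*Apis mellifera*) forage on whatever flowers the local landscape
offers; DNA metabarcoding of trapped pollen turns each site-and-date sample
into a compositional vector of relative read abundances (RRA) over plant
taxa.  Pairing those abundances with the monthly climate each sample was
collected under yields, per taxon, an empirical picture of the climatic
conditions it was actually foraged in — its *realised climatic niche*.  The
question this package answers: under uniform warming and/or drying offsets
applied to the observed climate, how much of the pollen diet ends up outside
the climatic conditions its source plants were ever observed under, and can
losses plausibly be compensated from the regional species pool?

It is aimed at community ecologists and pollination researchers working with
taxon × sample relative-abundance tables plus per-site monthly climate
(CRU-TS-style mean temperature and accumulated precipitation).

## The method

1. **Preparation** — RRA tables are noise-filtered (taxa < 1% of a sample are
   dropped, the rest renormalised) and only taxa observed at more than 5
   distinct sites and in at least 10 samples are profiled.
2. **Niche profiles** — for taxon *s* and climate axis *x* (temperature or
   precipitation), every sample *i* containing the taxon contributes its
   climate value x_i with weight w_i = RRA_si.  The niche density is the
   weighted Gaussian KDE

   f̂_s(x) = Σ_i w_i·K_h(x − x_i) / Σ_i w_i,

   with bandwidth h from Silverman's rule at the effective sample size
   n_eff = (Σw)²/Σw², and percentile thresholds q_p taken from the
   trapezoid-integrated CDF (p = 1, 5, 10, 90, 95, 99).  Precipitation has
   no negative support: the grid is truncated at 0 and renormalised.
3. **Exceedance risk** — a scenario is an offset (ΔT, ΔP) from the 11 × 11
   grid (0…+5 °C × 0.5; 0…−50 mm × −5).  The perturbed temperature is
   classified against the niche's upper tail (low ≤ q90 < moderate ≤ q95 <
   high ≤ q99 < critical), perturbed precipitation — clamped at 0 mm —
   against the lower tail (low ≥ q10 > moderate ≥ q05 > high ≥ q01 >
   critical); the combined class is the ordinal maximum.  RRA mass is then
   aggregated per risk class by latitude band, month and crop/wild status.
4. **Resistance and resilience** — per sample and scenario, with S_risk taxa
   at least moderate on either axis and S_no-risk taxa low on both:

   Resistance = 1 − S_risk / (S_no-risk + S_risk)

   Resilience = S_replacement / S_risk,

   where a replacement for an at-risk taxon must occur within 500 km of the
   focal site, be classified low/low there under the same scenario, belong
   to the same plant family, and not already be used in the sample.

A seeded synthetic-data module emulates the whole study design (hundreds of
apiaries over 35–65° N, biweekly May–August rounds sharing monthly climate,
taxa with Gaussian climatic preferences, Dirichlet compositional noise, a
crop mass-flowering pulse) so the entire chain runs offline.

## Worked example

```python
import pollenrisk as pr
from pollenrisk.io_prep import filter_to_taxa

ds = pr.generate_dataset(pr.SyntheticConfig(n_sites=60, n_taxa=40, n_families=10, seed=42))
filtered, _ = pr.apply_rra_filter(ds.compositions)           # 1% noise floor
retained, report = pr.prevalence_filter(filtered)            # >5 sites, >=10 samples
joined = pr.join_climate(filter_to_taxa(filtered, retained), ds.climate, ds.sites)
profiles, _ = pr.fit_niche_profiles(joined, sorted(retained))
records = pr.attach_thresholds(joined, profiles, ds.taxa)

surf = pr.resilience_surface(
    records, [pr.Scenario(0.0, 0.0), pr.Scenario(2.0, -20.0), pr.Scenario(5.0, -50.0)],
    ds.taxa, ds.sites,
)
print(f"retained taxa: {len(retained)}/{len(report)}")
for (dt, dp), g in surf.groupby(["delta_t", "delta_p"]):
    print(f"dT=+{dt:.1f} degC, dP={dp:+.0f} mm: "
          f"mean resistance {g.resistance.mean():.3f}, mean resilience {g.resilience.mean():.3f}")
```

prints

```
retained taxa: 40/40
dT=+0.0 degC, dP=+0 mm: mean resistance 0.771, mean resilience 0.968
dT=+2.0 degC, dP=-20 mm: mean resistance 0.357, mean resilience 0.873
dT=+5.0 degC, dP=-50 mm: mean resistance 0.019, mean resilience 0.203
```

Unperturbed, most taxa sit inside their own fitted niches (resistance 0.77)
and nearly every at-risk taxon has a nearby same-family replacement.
Moderate combined warming and drying already pushes most of the diet past
its thresholds, and under the severe corner of the grid almost everything is
at risk while replacement candidates have largely run out — the joint
collapse of resistance *and* resilience is the method's central readout.

The same stages are available from a shell:

```sh
pollenrisk simulate --n-sites 60 --n-taxa 40 --seed 42 --outdir run/
pollenrisk run-all --seed 42 --outdir run/
```

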