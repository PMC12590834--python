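# sitefidelity

Multi-scale site-fidelity analysis for GPS-collared ungulates: from hourly
telemetry and daily foodscape rasters to dynamic Brownian bridge home
ranges, Colwell constancy metrics, distance-based fidelity, and
model-averaged mixed-model plus survival inference.

## The scientific problem

Many ungulates return to the same summer ranges year after year. Whether
that *site fidelity* pays off should depend on how predictable the
landscape is: returning to a known place is only informative when the
place behaves the same way it did last time. This package implements a
complete analysis chain for testing, in a bighorn-sheep-like study
system, (i) whether fidelity tracks the predictability and quality of
forage within home ranges versus prior reproductive success
("win-stay, lose-switch"), and (ii) whether fidelity improves autumn
body condition or neonate survival.

Because the motivating field data are not publicly deposited, the
package ships a first-class synthetic study system (`sitefidelity.synthetic`)
that emulates the data structures — multi-year females with 1-h GPS
fixes over a summer season, 250-m daily suitable-biomass rasters,
neonate survival histories, paired spring/autumn percent ingesta-free
body fat (IFBFat) — with every generating parameter a known ground truth.

## The analysis chain

1. **Track processing** (`tracks`): season truncation (grassland
   Apr 1–Sep 1, alpine Jun 1–Sep 1), removal of fixes terminating steps
   above the 95th percentile of an animal-season's step lengths, binning
   into annual / 30-day / 14-day intervals anchored at the season start,
   and a ≥50% monitoring-coverage inclusion rule per interval.
2. **Home ranges** (`dbbmm`): dynamic Brownian bridge movement model
   with moving window 7 fixes / margin 3 / 20 m location error. The
   bridge between fixes a, b places the animal at fractional time α at an
   isotropic Gaussian with variance
   `T·α(1−α)·σ²ₘ + (1−α)²δₐ² + α²δᵦ²`; σ²ₘ is re-estimated along the
   track by BIC-selected breakpoint models on a leave-one-out likelihood.
   The home range is the 99% isopleth of the utilization distribution,
   with area in km².
3. **Foodscape metrics** (`foodscape`): suitable biomass min–max scaled
   to [0, 1] globally; Colwell's constancy `C = 1 − H/ln(n)` with
   `H = −Σ Pᵢ ln Pᵢ` over n = 100 even bins. Temporal constancy is
   per-pixel over days, averaged across home-range pixels; spatial
   constancy is per-day over home-range pixels, averaged across days;
   mean scaled biomass is the quality metric.
4. **Site fidelity** (`fidelity`): mean minimum Euclidean distance
   between each focal-interval fix and the previous interval's fixes —
   restricted to a ±W day-of-year window at the annual scale, with a
   5–100-day (step 5) sensitivity analysis and an explicit asymptote
   rule for choosing W.
5. **Recruitment** (`recruitment`): previous-timestep success labels —
   offspring alive to 120 days (annual), ≥15 of the previous 30 days, or
   ≥7 of the previous 14 days ("neonate at heel").
6. **Inference** (`inference`): linear mixed models of ln(distance) on
   standardized covariates with a random intercept for animal
   (annual) or animal-year (finer scales), fitted by ML; hypothesis-driven
   candidate sub-model sets screened for collinearity (|r| > 0.6 splits a
   sub-model); AICc model averaging over the 95% confidence set with
   unconditional SEs; condition models for autumn IFBFat and spring→autumn
   fat accrual; Andersen–Gill Cox proportional hazards of neonate
   mortality with a mother-level cluster-robust variance, or a
   Mann–Whitney comparison when mortalities are too few.

## Worked example

Fit the candidate model sets to an analysis table with known effects
(spatial constancy 0.3, temporal constancy 0.2, biomass −0.2, recruit
0.4, home-range size −0.3 on the log-distance scale):

```python
from sitefidelity import FidelityModelSet
from sitefidelity.synthetic import make_analysis_table

table = make_analysis_table(
    n_rows=300,
    betas={"spatial_C": 0.3, "temporal_C": 0.2, "mean_biomass": -0.2,
           "recruit": 0.4, "hr_area_km2": -0.3},
    seed=42,
)
result = FidelityModelSet(table, scale="annual").fit()
print(result.summary())
```

```
AICc model comparison
========================================================================
                 model           set  k   logLik    AICc  delta_AICc  weight  in_confidence_set
comb.pred+qual+recruit      combined  8 -436.884 890.263       0.000   0.994               True
         het.pred+qual heterogeneity  7 -443.124 900.632      10.369   0.006              False
     comb.pred+recruit      combined  7 -447.653 909.690      19.427   0.000              False
     comb.qual+recruit      combined  6 -453.395 919.077      28.813   0.000              False
    het.predictability heterogeneity  6 -454.781 921.848      31.585   0.000              False
           het.quality heterogeneity  5 -458.518 927.241      36.977   0.000              False
          succ.recruit       success  5 -468.159 946.522      56.259   0.000              False

Model-averaged coefficients (95% confidence set)
========================================================================
        term   beta    se  ci_low  ci_high  significant  n_models
 hr_area_km2 -0.348 0.058  -0.461   -0.235         True         1
mean_biomass -0.287 0.061  -0.406   -0.168         True         1
     recruit  0.433 0.121   0.196    0.671         True         1
   spatial_C  0.305 0.061   0.186    0.424         True         1
  temporal_C  0.173 0.057   0.062    0.284         True         1
```

The full additive model carries essentially all Akaike weight, and every
model-averaged 95% CI covers its generating value: positive
constancy/recruit coefficients mean *larger* distances (lower fidelity),
negative biomass and home-range-size coefficients mean higher fidelity in
better, smaller ranges.

The whole chain — simulate → preprocess → home ranges → constancy →
fidelity → recruitment → models — runs from one seed with

```bash
sitefidelity run-all --out out/ --seed 7
```

or module by module (`simulate`, `preprocess`, `homerange`, `constancy`,
`fidelity`, `models`); see `sitefidelity --help`.

## Documentation

`docs/methods.md` documents the models, their assumptions, the synthetic
study system's defaults and limitations, and the numerical choices made
where the original workflow delegated them to software defaults.
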