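# soilgam

Statistical analysis of soil-incubation experiments that link microbial
diversity to soil organic carbon (SOC) mineralisation. The package is
aimed at soil ecologists and biogeochemists who run ¹³C-labelled residue
incubations and want to know *which* soil properties — texture, SOC,
C:N, pH, microbial biomass, or bacterial/fungal diversity indexes —
best predict the observed CO₂ fluxes.

It implements, as a tested and reusable pipeline:

1. **Isotope partitioning.** Amended microcosms respire a two-source
   mix of native soil C and ¹³C-enriched residue C. With endmember
   abundances A¹³ₛ (soil) and A¹³ᵣ (residue) and the measured abundance
   A¹³ₜ of respired CO₂, mass balance

   ```
   Rs + Rr = Rt
   Rs·A¹³s + Rr·A¹³r = Rt·A¹³t
   ```

   gives the soil-derived flux Rs and residue-derived flux Rr. The
   priming effect is the ratio PE = Rs,amended / Rs,control, kept as a
   ratio so ln(PE) is defined.

2. **Diversity indexes.** Richness, Shannon H′ = −Σ pᵢ ln pᵢ, evenness
   J′ = H′/ln S and inverse Simpson 1/D = 1/Σ pᵢ² per sample from OTU
   count tables.

3. **Additive-model covariate selection.** For each mineralisation
   kinetic (Rs,control, Rs,amended, Rr, PE) the response is the log
   interval rate, modelled as

   ```
   E(y) = α + f₁(x₁) + … + f_p(x_p) + time
   ```

   with `time` a random factor (ridge-penalized per-date intercepts)
   and each fⱼ drawn from a menu: identity (I), orthogonal polynomial
   of degree 2/3 (poly2/poly3), or a penalized cubic regression spline
   (s), optionally interacting with land use. Covariates are selected
   stepwise by minimizing the leave-one-soil-out cross-validated mean
   squared error of prediction, MSEP = (1/N) Σ (y_itu − ŷ₋ᵢ,tu)², with
   a variance-inflation-factor prescreen (VIF ≤ 4) against collinearity.

4. **Assessment.** Explained deviance (%Dev), RPIQ = IQR(y)/√MSEP,
   BIC, per-term F tests, relative importance of each model component
   by sequential variance partitioning of the linear predictor, and a
   two-way mixed ANOVA (land use fixed, time random) with Tukey HSD
   groupings for the raw kinetics.

A seeded synthetic-data generator reproduces the experiment's structure
(20 soils split cropland/grassland, 2 treatments × 3 replicates ×
8 sampling dates, intercorrelated diversity covariates, double-pool
decay kinetics, lognormal rate noise, exact two-endmember ¹³C mixing)
with ground-truth accessors for recovery tests.

## Worked example

```python
from soilgam import GAMConfig, RunConfig, run_pipeline
from soilgam.selection import SelectionConfig

config = RunConfig(
    simulate=True, seed=3, outdir="run",
    selection=SelectionConfig(
        candidates=("bacterial_j", "soc", "ph", "fungal_invd"),
        forms=("I", "s"), interaction_mode="never", gam=GAMConfig(k=5),
    ),
)
results = run_pipeline(config)
```

prints (see `examples/05_full_pipeline.py`):

```
rs_control  %Dev  91.6  RPIQ  4.81  MSEP  0.0255  terms: Time, Bacterial J', SOC
rs_amended  %Dev  94.5  RPIQ  5.36  MSEP  0.0241  terms: Time, Bacterial J', SOC, Fungal 1/D, pH
rr          %Dev  98.5  RPIQ 14.45  MSEP  0.0231  terms: Time
pe          %Dev  79.2  RPIQ  2.90  MSEP  0.0481  terms: Time, SOC, Fungal 1/D, pH, Bacterial J'
```

Every model contains Time; residue mineralisation (`rr`) is explained
almost entirely by incubation time, while the priming effect (`pe`) is
the hardest kinetic to predict (lowest RPIQ) — the generator injects a
bacterial-evenness effect on control-soil respiration, and the search
recovers it. `examples/` contains one short script per capability
(partitioning, diversity, model fitting, selection, full pipeline).

The same stages are available from a shell:

```sh
soilgam simulate --seed 1 --outdir data
soilgam partition --sites data/sites.csv --respiration data/respiration.csv \
    --endmembers data/endmembers.csv --out responses.csv
soilgam run --config run.yaml
```

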