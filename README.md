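# mycoforest

Plot-level forest carbon accounting and statistical inference on the role
of **ectomycorrhizal (EcM) tree dominance** in tree, soil and whole-forest
carbon stocks — the analysis pipeline used for large grid-based forest
inventories in high-latitude temperate forests, built as a tested,
reusable Python library with a synthetic-inventory generator so every step
can be validated against known ground truth.

It is written for ecosystem ecologists and forest biometricians who have
stem-level inventory tables (species, DBH, height per 30 m x 30 m plot),
soil-layer measurements, species attributes (mycorrhizal strategy, leaf
traits, seral status) and, optionally, a guild-annotated soil fungal OTU
table.

## What it computes

- **Carbon stocks** (Mg C/ha): tree carbon from a shared allometry
  ln(kg) = c0 + c1·ln(DBH²·h) with the 0.5 biomass-to-carbon factor; soil
  organic carbon density per depth layer, SOCD = Σ (1−V_i)·B_i·C_i·T_i/10;
  forest carbon = tree + soil.
- **Mycorrhizal dominance**: EcMD = share of EcM basal area in total
  EcM+AM basal area, dual-type species split 50/50; AMD = 1 − EcMD.
- **Community structure**: species richness, Rao's quadratic entropy
  Q = Σ p_i p_j d_ij over eight leaf traits (Gower distance, basal-area
  weights), and a climate score (PCA axis 1 of temperature and
  precipitation seasonality — high = harsh, strongly seasonal climate).
- **Successional ordination**: Importance Values IV = (rel. density +
  rel. cover + rel. frequency)/3, Climax Adaptation Values
  CAV = (10·S_climax + S_pioneer)/(S_climax + S_pioneer) on the 1–10
  pioneer-to-climax scale, the per-plot compositional index Σ IV·CAV, and
  an early/middle/late tertile staging.
- **Inference**: boundary transform y' = (y(N−1)+0.5)/N for dominance
  proportions; linear mixed models of ln stocks with EcMD' x richness /
  stage / climate interactions and an ecoregion random intercept; simple
  slopes per moderator level; VIFs; random-forest driver screening; an
  ecoregion-stratified 50% subsampling stability check; and a from-scratch
  **piecewise SEM** with Shipley's d-separation basis set and Fisher's
  C = −2 Σ ln p (chi-square, 2k df).
- **Fungal summaries**: guild relative abundances and Shannon diversity
  for all/EcM/saprotrophic fungi, regressed on EcM tree dominance.

See `docs/methods.md` for the models, assumptions and design choices.

## Worked example

```python
from mycoforest import (SimConfig, simulate_dataset, compute_plot_metrics,
                        build_model_frame, fit_mixed_model, interaction_slopes)

ds, truth = simulate_dataset(SimConfig(seed=1, plots_per_ecoregion=100))
metrics = compute_plot_metrics(ds)          # 1000 plots x 14 columns
fit = fit_mixed_model(build_model_frame(metrics, "tree_c"))
print(fit.params.loc[["ecmd_t", "ecmd_t:richness_z", "ecmd_t:climate_z"],
                     ["est", "se", "p"]].round(3))
```

prints

```
                     est     se      p
ecmd_t             0.406  0.055  0.000
ecmd_t:richness_z -0.171  0.033  0.000
ecmd_t:climate_z   0.197  0.032  0.000
```

The generator embedded a true EcMD effect of 0.4 on ln tree carbon with
interactions −0.15 (richness) and +0.15 (climate); the fitted model
recovers all three: EcM dominance raises tree carbon, most strongly in
species-poor stands and under harsh, strongly seasonal climate.
`interaction_slopes(fit, "richness")` turns the interaction into the three
moderator-level slopes (0.56 at low richness vs 0.20 at high, in this
run).

The `examples/` directory has one short script per capability:
inventory simulation, carbon/dominance metrics, succession staging,
moderated mixed models, piecewise SEM paths, and fungal guild shifts.
A thin CLI mirrors the pipeline stages:

```bash
mycoforest simulate --seed 1 --out data/
mycoforest metrics --data data/ --out plot_metrics.csv
mycoforest fit-lmm --metrics plot_metrics.csv --out fits/
```

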