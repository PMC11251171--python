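"""The mixed-effects core: EcM-dominance effect and its moderators.

Fits ln tree carbon on transformed EcM dominance, richness, stage, climate,
slope and altitude with an ecoregion random intercept and the three
EcMD x moderator interactions, then reports the simple EcMD slopes at low /
middle / high richness and climate, plus the ecoregion-stratified 50%
subsampling stability check.
"""

from mycoforest import (ModelSpec, SimConfig, build_model_frame,
                        compute_plot_metrics, ecoregion_subsample,
                        fit_mixed_model, interaction_slopes, simulate_dataset)

ds, truth = simulate_dataset(SimConfig(seed=1, plots_per_ecoregion=100))
metrics = compute_plot_metrics(ds)
frame = build_model_frame(metrics, "tree_c")
fit = fit_mixed_model(frame, ModelSpec(response="tree_c"))

print(f"method: {fit.method}; n = {fit.n}; "
      f"R2 marginal {fit.r2_marginal:.2f} / conditional {fit.r2_conditional:.2f}")
print(fit.params[["est", "se", "p", "std_est"]].round(3))
print(f"\ntrue effects: EcMD {truth.config.beta_ecm_tree}, "
      f"x climate {truth.config.beta_int_climate}, x richness {truth.config.beta_int_sr}")

for moderator in ("richness", "climate"):
    slopes = interaction_slopes(fit, moderator)
    print(f"\nEcMD slope by {moderator}:")
    print(slopes.round(3).to_string(index=False))
# With the negative EcMD x richness interaction, the low-richness slope is
# the steepest: dominance matters most in species-poor stands. The positive
# climate interaction makes the effect strongest under harsh seasonality.

summary = ecoregion_subsample(frame, fraction=0.5, n_replicates=50, seed=1)
print(f"\nEcMD sign consistency over {summary.n_replicates} half-samples: "
      f"{summary.sign_consistency['ecmd_t']:.2f}")
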