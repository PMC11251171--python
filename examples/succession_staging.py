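"""Successional ordination: importance values, CAVs and the compositional
index, with recovery of the generator's latent gradient.

Each plot gets a compositional index in [1, 10] (sum of IV x CAV) and an
early/middle/late stage from the ascending tertile cut; the Spearman
correlation with the latent succession score that actually drove community
assembly shows how well the ordination recovers the gradient.
"""

from scipy.stats import spearmanr

from mycoforest import SimConfig, simulate_dataset
from mycoforest.io import apply_stem_filter
from mycoforest.succession import run_succession

ds, truth = simulate_dataset(SimConfig(seed=1, plots_per_ecoregion=100))
res = run_succession(apply_stem_filter(ds.stems), ds.species)

print(res.stages["stage"].value_counts().to_string())
print("\nCAV range:", res.cav["cav"].min(), "-", res.cav["cav"].max())
print("designated pioneers at 1:", (res.cav["cav"] == 1.0).sum(),
      "| climax at 10:", (res.cav["cav"] == 10.0).sum())

comp = res.stages.set_index("plot_id")["comp_index"]
rho = spearmanr(comp.loc[truth.latent_succession.index],
                truth.latent_succession).statistic
print(f"\nSpearman(comp_index, latent succession) = {rho:.3f}")
# Around 0.85: the IV x CAV ordination orders plots essentially the same
# way as the hidden gradient that generated their communities.
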