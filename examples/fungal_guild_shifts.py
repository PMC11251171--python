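"""Soil fungal community vs tree dominance.

Generates a guild-annotated OTU table for a 110-plot subset (the scale at
which soil communities are typically sequenced), filters low-abundance
OTUs, summarizes guild shares and Shannon diversity, and regresses each
summary on EcM tree dominance.
"""

from mycoforest import (SimConfig, compute_plot_metrics, filter_low_abundance,
                        generate_fungal_table, guild_vs_dominance,
                        simulate_dataset, summarize_fungi)

ds, _ = simulate_dataset(SimConfig(seed=1))
metrics = compute_plot_metrics(ds)

subset = metrics.sample(110, random_state=1).set_index("plot_id")["ecmd"]
otu = generate_fungal_table(subset, seed=1)
kept = filter_low_abundance(otu, threshold=10)
print(f"OTUs: {len(otu)} generated, {len(kept)} kept after the <=10-read filter")
# at this sequencing depth every simulated OTU clears 10 total reads; the
# filter matters for real, shallower libraries

summary = summarize_fungi(kept)
fits = guild_vs_dominance(metrics, summary)
print(fits[["slope", "p", "r"]].round(4))
# Expected pattern: EcM fungal share rises with EcM tree dominance (r > 0)
# while the saprotroph share falls, and the two guilds' Shannon diversities
# move opposite to their abundances.
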