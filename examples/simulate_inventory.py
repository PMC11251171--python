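"""Generate a synthetic forest-inventory bundle and look at its structure.

Builds a 500-plot inventory (10 ecoregions x 50 plots) with the default
true effects, writes the four tables plus the ground-truth record, and
prints the headline numbers of the simulated landscape.
"""

from pathlib import Path

from mycoforest import SimConfig, simulate_dataset, write_tables

cfg = SimConfig(seed=1)
ds, truth = simulate_dataset(cfg)

out = Path("scratch/example_inventory")
write_tables(ds, out)
truth.to_json(out / "truth.json")

print(f"plots:   {len(ds.plots)} across {ds.plots['ecoregion_id'].nunique()} ecoregions")
print(f"stems:   {len(ds.stems)} (all DBH >= 3 cm: {(ds.stems['dbh'] >= 3).all()})")
print(f"species: {len(ds.species)} "
      f"({(ds.species['strategy'] == 'EcM').sum()} EcM, "
      f"{(ds.species['strategy'] == 'AM').sum()} AM, "
      f"{(ds.species['strategy'] == 'dual').sum()} dual, "
      f"{(ds.species['strategy'] == 'other').sum()} other)")
print(f"soil:    {len(ds.soil)} layer records (5 per plot)")
print(f"true EcMD effect on ln tree C: {truth.config.beta_ecm_tree}")
print(f"written to {out}/")
# The true effect sizes live in truth.json; downstream examples re-estimate
# them from the tables alone.
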