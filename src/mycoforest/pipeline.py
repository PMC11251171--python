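"""End-to-end assembly: dataset bundle -> per-plot metrics -> fitted models.

This is the glue the CLI, the examples and the acceptance checks share. The
per-plot metrics table carries: tree_c, soil_c, forest_c (Mg C/ha), ecmd,
amd, richness, raoq, climate_score, comp_index, stage, plus the plot
environment columns needed by the models.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import sem as sem_mod
from .io import Dataset, apply_stem_filter, apply_strategy_exclusion
from .inference import (ModelSpec, boundary_transform, build_model_frame,
                        fit_mixed_model)
from .metrics import (CARBON_FRACTION, climate_score, dominance_table,
                      impute_traits, rao_q, stem_basal_area, stem_biomass,
                      trait_distance)
from .soil import forest_carbon, socd_table
from .succession import run_succession

log = logging.getLogger("mycoforest")


def compute_plot_metrics(ds: Dataset, *, allometry=( -2.5, 0.95),
                         rao_weights: str = "basal_area",
                         trait_metric: str = "gower",
                         exclude_other_from_carbon: bool = False) -> pd.DataFrame:
    """Derive the full per-plot metrics table from a validated bundle.

    ``rao_weights`` is "basal_area" (consistent with the dominance metric)
    or "stems"; ``exclude_other_from_carbon`` extends the other-strategy
    exclusion from the dominance ratio to tree carbon and richness.
    """
    stems = apply_stem_filter(ds.stems)
    dom_stems = apply_strategy_exclusion(stems, ds.species)
    carbon_stems = dom_stems if exclude_other_from_carbon else stems

    plot_ids = ds.plots["plot_id"]
    area = ds.plots.set_index("plot_id")["area_ha"]

    biomass = stem_biomass(carbon_stems["dbh"].to_numpy(),
                           carbon_stems["height"].to_numpy(), allometry)
    tree_c = (pd.Series(biomass, index=carbon_stems["plot_id"]).groupby(level=0).sum()
              * CARBON_FRACTION / 1000.0)
    tree_c = (tree_c / area).reindex(plot_ids)
    empty = tree_c.isna()
    if empty.any():
        log.warning("compute_plot_metrics: %d empty plot(s), tree carbon 0", int(empty.sum()))
        tree_c = tree_c.fillna(0.0)

    dom = dominance_table(dom_stems, ds.species).reindex(plot_ids)
    richness = carbon_stems.groupby("plot_id")["species_id"].nunique().reindex(plot_ids)

    # Rao's quadratic entropy from imputed traits
    trait_mat = impute_traits(ds.species)
    D = trait_distance(trait_mat, metric=trait_metric)
    w_col = carbon_stems.copy()
    w_col["_w"] = (stem_basal_area(w_col["dbh"].to_numpy())
                   if rao_weights == "basal_area" else 1.0)
    weights = w_col.groupby(["plot_id", "species_id"])["_w"].sum()
    raoq = {}
    Dv = D.to_numpy()
    pos = {s: i for i, s in enumerate(D.index)}
    for pid, grp in weights.groupby(level=0):
        p = grp.to_numpy()
        p = p / p.sum()
        idx = [pos[s] for s in grp.index.get_level_values(1)]
        raoq[pid] = float(p @ Dv[np.ix_(idx, idx)] @ p)
    raoq = pd.Series(raoq).reindex(plot_ids)

    clim, clim_var = climate_score(ds.plots["temp_seasonality"].to_numpy(),
                                   ds.plots["precip_seasonality"].to_numpy())
    log.info("climate PCA axis 1 explains %.1f%% of TS/PS variance", 100 * clim_var)

    soil_c = socd_table(ds.soil).reindex(plot_ids)
    n_missing_soil = int(soil_c.isna().sum())
    if n_missing_soil:
        log.info("%d plot(s) lack soil layers; soil/forest carbon missing", n_missing_soil)

    suc = run_succession(carbon_stems, ds.species)
    stages = suc.stages.set_index("plot_id").reindex(plot_ids)

    out = pd.DataFrame({
        "plot_id": plot_ids.to_numpy(),
        "ecoregion_id": ds.plots["ecoregion_id"].to_numpy(),
        "slope": ds.plots["slope"].to_numpy(),
        "altitude": ds.plots["altitude"].to_numpy(),
        "tree_c": tree_c.to_numpy(),
        "soil_c": soil_c.to_numpy(),
        "forest_c": forest_carbon(tree_c.to_numpy(), soil_c.to_numpy()),
        "ecmd": dom["ecmd"].to_numpy(),
        "amd": dom["amd"].to_numpy(),
        "richness": richness.to_numpy(),
        "raoq": raoq.to_numpy(),
        "climate_score": clim,
        "comp_index": stages["comp_index"].to_numpy(),
        "stage": stages["stage"].to_numpy(),
    })
    return out


def fit_carbon_models(metrics: pd.DataFrame,
                      responses=("tree_c", "soil_c", "forest_c")):
    """Fit the mixed model for each carbon response; returns {response: FitResult}."""
    fits = {}
    for resp in responses:
        frame = build_model_frame(metrics, resp)
        fits[resp] = fit_mixed_model(frame, ModelSpec(response=resp))
    return fits


def sem_data(metrics: pd.DataFrame, response: str = "tree_c") -> pd.DataFrame:
    """Node table for the piecewise SEM.

    Succession enters as the numeric compositional index, richness and the
    carbon stock on the natural-log scale, EcM dominance boundary-
    transformed; all node columns are z-scored so path coefficients live on
    comparable scales.
    """
    df = metrics[np.isfinite(metrics[response]) & (metrics[response] > 0)
                 & metrics["ecmd"].notna()].copy()
    nodes = pd.DataFrame({
        "climate": df["climate_score"],
        "succession": df["comp_index"],
        "richness": np.log(df["richness"].astype(float)),
        "ecmd": boundary_transform(df["ecmd"].to_numpy(), len(df)),
        "fd": df["raoq"],
        "carbon": np.log(df[response]),
        "ecoregion_id": df["ecoregion_id"],
    })
    return nodes


def fit_sem(metrics: pd.DataFrame, response: str = "tree_c",
            dag=None) -> sem_mod.PathModel:
    dag = dag if dag is not None else sem_mod.default_dag()
    return sem_mod.fit_paths(dag, sem_data(metrics, response))
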