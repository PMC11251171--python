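"""Synthetic forest-inventory generator with known ground truth.

Emulates the structure the analysis assumes: 30 m x 30 m plots of nine
subplots across ten ecoregions, stems with DBH >= 3 cm, an EcM/AM/dual/other
species pool with eight leaf traits, five soil depth layers, and climate
seasonality. The generating equations place a configurable true effect of
boundary-transformed EcM basal-area dominance on ln tree and ln soil carbon,
with configurable interactions with the (z-scored) climate score and species
richness, ecoregion random intercepts, and Gaussian residual noise.

The trick that makes parameter recovery exact is that the generator first
draws realistic communities, then *rescales* stem heights and soil organic-C
contents so that each plot's realized carbon stocks hit the linear-model
targets computed from the realized (not latent) predictor values - the same
quantities the metrics module later recomputes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SOIL_LAYER_BOUNDS, TRAIT_NAMES, SimConfig
from .errors import ConfigurationError
from .inference import boundary_transform
from .io import Dataset
from .metrics import climate_score, dominance_table, stem_biomass

log = logging.getLogger("mycoforest")


def generate_species_pool(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Species-attributes table: strategy, seral status, eight leaf traits.

    Strategies are drawn per the frac_* proportions (remainder AM). Traits
    are log-normal with strategy-correlated means: EcM species draw lower
    leaf N and higher leaf dry-matter content on average, the conservative
    leaf economics of EcM-associated trees. Pioneers are enriched among
    high-SLA (light-demanding) draws, climax species among low-SLA ones.
    A configurable fraction of trait cells is blanked to exercise imputation.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_species
    p_rest = 1.0 - config.frac_ecm - config.frac_dual - config.frac_other
    strategy = rng.choice(
        ["EcM", "dual", "other", "AM"], size=n,
        p=[config.frac_ecm, config.frac_dual, config.frac_other, p_rest])
    is_ecm_like = np.isin(strategy, ["EcM"]) * 1.0 + np.isin(strategy, ["dual"]) * 0.5

    # log-scale trait means; EcM shifts: lower Nmass, higher LDMC
    traits = pd.DataFrame(index=np.arange(n))
    traits["Cmass"] = rng.lognormal(np.log(470), 0.08, n)
    traits["Nmass"] = rng.lognormal(np.log(21) - 0.15 * is_ecm_like, 0.25, n)
    traits["Pmass"] = rng.lognormal(np.log(1.6), 0.30, n)
    traits["Kmass"] = rng.lognormal(np.log(8.0), 0.30, n)
    traits["LA"] = rng.lognormal(np.log(2000), 0.80, n)
    traits["SLA"] = rng.lognormal(np.log(15), 0.35, n)
    traits["LMA"] = 1.0 / traits["SLA"] * np.exp(rng.normal(0, 0.05, n))
    traits["LDMC"] = rng.lognormal(np.log(380) + 0.10 * is_ecm_like, 0.15, n)

    sla_z = (np.log(traits["SLA"]) - np.log(traits["SLA"]).mean()) / np.log(traits["SLA"]).std()
    seral = np.full(n, "neither", dtype=object)
    n_pio = int(round(config.frac_pioneer * n))
    n_cli = int(round(config.frac_climax * n))
    if n_pio + n_cli > 0 and n_pio + n_cli <= n:
        w_pio = np.exp(1.5 * sla_z)
        pio_idx = rng.choice(n, size=n_pio, replace=False, p=w_pio / w_pio.sum())
        seral[pio_idx] = "pioneer"
        rest = np.setdiff1d(np.arange(n), pio_idx)
        w_cli = np.exp(-1.5 * sla_z[rest])
        cli_idx = rng.choice(rest, size=n_cli, replace=False, p=w_cli / w_cli.sum())
        seral[cli_idx] = "climax"

    # blank a fraction of trait cells, but never a whole column
    if config.trait_missing_frac > 0:
        mask = rng.random((n, len(TRAIT_NAMES))) < config.trait_missing_frac
        keep_rows = rng.integers(0, n, len(TRAIT_NAMES))
        mask[keep_rows, np.arange(len(TRAIT_NAMES))] = False
        vals = traits[TRAIT_NAMES].to_numpy()
        vals[mask] = np.nan
        traits[TRAIT_NAMES] = vals

    out = pd.DataFrame({
        "species_id": [f"S{i + 1:04d}" for i in range(n)],
        "strategy": strategy,
        "seral_status": seral,
    })
    return pd.concat([out, traits[TRAIT_NAMES].round(4)], axis=1)


@dataclass
class TruthRecord:
    """Everything needed for recovery tests: the realized generating
    coefficients, per-ecoregion intercepts, and per-plot latent scores."""

    config: SimConfig
    u_tree: dict[str, float]
    u_soil: dict[str, float]
    latent_succession: pd.Series
    expected_ln_tree_c: pd.Series
    expected_ln_soil_c: pd.Series
    ecmd: pd.Series
    climate_z: pd.Series

    def to_json(self, path: str | Path) -> None:
        from dataclasses import asdict
        cfg = asdict(self.config)
        cfg["allometry_coeffs"] = list(cfg["allometry_coeffs"])
        payload = {
            "config": cfg,
            "u_tree": self.u_tree,
            "u_soil": self.u_soil,
            "latent_succession": self.latent_succession.to_dict(),
            "expected_ln_tree_c": self.expected_ln_tree_c.to_dict(),
            "expected_ln_soil_c": self.expected_ln_soil_c.to_dict(),
            "ecmd": self.ecmd.to_dict(),
            "climate_z": self.climate_z.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_inventory(config: SimConfig, species: pd.DataFrame,
                       rng: np.random.Generator | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Plots, stems and soil layers whose carbon stocks embed the true effects.

    Returns (plots, stems, soil_layers, truth). See the module docstring for
    the generating model; the latent succession score shifts community
    composition from pioneer- to climax-dominated via an exponential
    (log-linear) weighting, and a per-plot EcM tilt spreads basal-area
    dominance over (0, 1).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_plots = config.n_plots
    plot_ids = [f"P{i + 1:05d}" for i in range(n_plots)]
    eco_ids = [f"E{e + 1:02d}" for e in range(config.n_ecoregions)]
    ecoregion = np.repeat(eco_ids, config.plots_per_ecoregion)

    # plot environment
    slope = rng.uniform(0, 35, n_plots)
    altitude = np.clip(rng.normal(600, 200, n_plots), 50, None)
    climate_lat = rng.standard_normal(n_plots)
    a = config.climate_loading
    b = np.sqrt(max(1.0 - a * a, 0.0))
    ts = 100 + 15 * (a * climate_lat + b * rng.standard_normal(n_plots))
    ps = 80 + 20 * (a * climate_lat + b * rng.standard_normal(n_plots))
    latent = rng.standard_normal(n_plots)  # succession gradient
    tilt = rng.normal(0, config.ecm_tilt_sd, n_plots)

    strat = species["strategy"].to_numpy()
    ecm_w = np.where(strat == "EcM", 1.0, np.where(strat == "dual", 0.5, 0.0))
    # continuous successional affinity: designated species sit at the
    # endpoints, the rest spread between them (species sort continuously
    # along succession, which is what the CAV interpolation estimates)
    seral_dir = np.where(species["seral_status"] == "climax", 1.0,
                         np.where(species["seral_status"] == "pioneer", -1.0,
                                  rng.uniform(-0.7, 0.7, len(species))))
    base_ab = rng.lognormal(0.0, 1.0, config.n_species)
    p_base = base_ab / base_ab.sum()

    stem_frames = []
    n_species = config.n_species
    kmin = min(config.pool_min, n_species)
    kmax = min(config.pool_max, n_species)
    for i in range(n_plots):
        k = int(rng.integers(kmin, kmax + 1))
        cand = rng.choice(n_species, size=k, replace=False, p=p_base)
        w = (base_ab[cand]
             * np.exp(tilt[i] * ecm_w[cand])
             * np.exp(config.succession_strength * latent[i] * seral_dir[cand]))
        n_stems = config.min_stems_per_plot + rng.poisson(
            max(config.mean_stems_per_plot - config.min_stems_per_plot, 0.0))
        draws = rng.choice(cand, size=n_stems, p=w / w.sum())
        dbh = 3.0 + rng.lognormal(1.8, 0.7, n_stems)
        height = 1.6 * dbh ** 0.66 * np.exp(rng.normal(0, 0.12, n_stems))
        stem_frames.append(pd.DataFrame({
            "plot_id": plot_ids[i],
            "subplot": rng.integers(1, 10, n_stems),
            "species_idx": draws,
            "dbh": dbh,
            "height": height,
        }))
    stems = pd.concat(stem_frames, ignore_index=True)
    stems["species_id"] = species["species_id"].to_numpy()[stems["species_idx"]]

    # realized predictors, exactly as the metrics module will compute them
    dom = dominance_table(stems, species).reindex(plot_ids)
    ecmd = dom["ecmd"].fillna(0.5).to_numpy()  # all-'other' plots: no EcMD signal
    ecmd_t = boundary_transform(ecmd, n_plots)
    richness = stems.groupby("plot_id")["species_id"].nunique().reindex(plot_ids).to_numpy()
    clim_scores, _ = climate_score(ts, ps)
    climate_z = _zscore(clim_scores)
    rich_z = _zscore(richness.astype(float))
    slope_z = _zscore(slope)
    alt_z = _zscore(altitude)
    stage_code = np.digitize(latent, np.quantile(latent, [1 / 3, 2 / 3]))
    stage_eff = np.choose(stage_code, [0.0, config.beta_stage_mid, config.beta_stage_late])

    u_tree = rng.normal(0, config.sigma_ecoregion, config.n_ecoregions)
    u_soil = rng.normal(0, config.sigma_ecoregion, config.n_ecoregions)
    eco_idx = np.repeat(np.arange(config.n_ecoregions), config.plots_per_ecoregion)

    shared = (config.beta_richness * rich_z + config.beta_climate * climate_z
              + stage_eff + config.beta_slope * slope_z
              + config.beta_altitude * alt_z
              + config.beta_int_climate * ecmd_t * climate_z
              + config.beta_int_sr * ecmd_t * rich_z)
    ln_tree = (config.intercept_tree + config.beta_ecm_tree * ecmd_t + shared
               + u_tree[eco_idx] + rng.normal(0, config.sigma_resid, n_plots))
    ln_soil = (config.intercept_soil + config.beta_ecm_soil * ecmd_t + shared
               + u_soil[eco_idx] + rng.normal(0, config.sigma_resid, n_plots))

    # rescale heights so each plot's summed biomass hits its target exactly;
    # biomass scales as height^c1 under the shared allometric form
    c0, c1 = config.allometry_coeffs
    stems["_biomass"] = stem_biomass(stems["dbh"].to_numpy(), stems["height"].to_numpy(),
                                     config.allometry_coeffs)
    current = stems.groupby("plot_id")["_biomass"].sum().reindex(plot_ids).to_numpy()
    target_kg = np.exp(ln_tree) * config.plot_area_ha * 1000.0 / 0.5
    k_scale = (target_kg / current) ** (1.0 / c1)
    scale_map = pd.Series(k_scale, index=plot_ids)
    stems["height"] = stems["height"] * stems["plot_id"].map(scale_map).to_numpy()
    stems = stems.drop(columns=["species_idx", "_biomass"])
    stems["dbh"] = stems["dbh"].round(4)
    stems["height"] = stems["height"].round(4)

    # soil: draw a plausible five-layer profile, then rescale organic C so the
    # summed SOCD equals the target soil stock
    tops = np.array([t for t, _ in SOIL_LAYER_BOUNDS], dtype=float)
    bottoms = np.array([b for _, b in SOIL_LAYER_BOUNDS], dtype=float)
    thickness = bottoms - tops
    n_layers = len(SOIL_LAYER_BOUNDS)
    V = rng.uniform(0.0, 0.3, (n_plots, n_layers))
    B = np.array([1.0, 1.1, 1.25, 1.4, 1.5]) * np.exp(rng.normal(0, 0.05, (n_plots, n_layers)))
    C_base = np.array([35.0, 25.0, 18.0, 12.0, 6.0]) * np.exp(rng.normal(0, 0.15, (n_plots, n_layers)))
    socd0 = ((1 - V) * B * C_base * thickness / 10.0).sum(axis=1)
    C_scaled = C_base * (np.exp(ln_soil) / socd0)[:, None]
    soil = pd.DataFrame({
        "plot_id": np.repeat(plot_ids, n_layers),
        "layer_index": np.tile(np.arange(1, n_layers + 1), n_plots),
        "top_cm": np.tile(tops, n_plots),
        "bottom_cm": np.tile(bottoms, n_plots),
        "gravel_frac": V.ravel().round(4),
        "bulk_density": B.ravel().round(4),
        "organic_c": C_scaled.ravel().round(5),
        "thickness": np.tile(thickness, n_plots),
    })
    if config.frac_soil_missing > 0:
        n_missing = int(round(config.frac_soil_missing * n_plots))
        missing_plots = rng.choice(plot_ids, size=n_missing, replace=False)
        soil = soil[~soil["plot_id"].isin(missing_plots)].reset_index(drop=True)

    plots = pd.DataFrame({
        "plot_id": plot_ids,
        "ecoregion_id": ecoregion,
        "slope": slope.round(3),
        "altitude": altitude.round(2),
        "temp_seasonality": ts.round(4),
        "precip_seasonality": ps.round(4),
        "area_ha": config.plot_area_ha,
    })
    idx = pd.Index(plot_ids, name="plot_id")
    truth = TruthRecord(
        config=config,
        u_tree=dict(zip(eco_ids, u_tree.round(8))),
        u_soil=dict(zip(eco_ids, u_soil.round(8))),
        latent_succession=pd.Series(latent, index=idx, name="latent"),
        expected_ln_tree_c=pd.Series(ln_tree, index=idx, name="ln_tree_c"),
        expected_ln_soil_c=pd.Series(ln_soil, index=idx, name="ln_soil_c"),
        ecmd=pd.Series(ecmd, index=idx, name="ecmd"),
        climate_z=pd.Series(climate_z, index=idx, name="climate_z"),
    )
    return plots, stems, soil, truth


def simulate_dataset(config: SimConfig) -> tuple[Dataset, TruthRecord]:
    """One seeded generator drives species pool and inventory; no global state."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = generate_species_pool(config, rng)
    plots, stems, soil, truth = generate_inventory(config, species, rng)
    return Dataset(plots=plots, stems=stems, soil=soil, species=species), truth


def generate_fungal_table(ecmd: pd.Series, *, n_otus: int = 240,
                          reads_per_plot: int = 15000, effect: float = 1.8,
                          seed: int = 0) -> pd.DataFrame:
    """Synthetic guild-annotated OTU counts linked to EcM tree dominance.

    The EcM-fungal guild share rises (log-linearly) with plot EcM dominance
    and the saprotroph share falls; within the EcM guild the abundance
    distribution grows more uneven with dominance, so EcM Shannon diversity
    declines while the EcM share rises - the qualitative pattern the tree
    dominance is expected to leave in the soil community.
    """
    if n_otus < 3:
        raise ConfigurationError("need at least 3 OTUs (one per guild)")
    rng = np.random.default_rng(seed)
    n_ecm = int(0.4 * n_otus)
    n_sap = int(0.4 * n_otus)
    n_other = n_otus - n_ecm - n_sap
    guild = np.array(["EcM"] * n_ecm + ["SAP"] * n_sap + ["other"] * n_other)
    cols: dict = {
        "otu_id": [f"OTU{i + 1:04d}" for i in range(n_otus)],
        "guild": guild,
    }
    for plot_id, x in ecmd.items():
        w_guild = {"EcM": np.exp(-0.6 + effect * x), "SAP": np.exp(0.4 - effect * x),
                   "other": 0.6}
        sigma_ecm = 0.8 + 1.2 * x       # more dominance -> more uneven EcM guild
        sigma_sap = 0.8 + 1.2 * (1 - x)
        ab = np.empty(n_otus)
        ab[guild == "EcM"] = rng.lognormal(0, sigma_ecm, n_ecm) * w_guild["EcM"]
        ab[guild == "SAP"] = rng.lognormal(0, sigma_sap, n_sap) * w_guild["SAP"]
        ab[guild == "other"] = rng.lognormal(0, 1.0, n_other) * w_guild["other"]
        cols[plot_id] = rng.multinomial(reads_per_plot, ab / ab.sum())
    return pd.DataFrame(cols)
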