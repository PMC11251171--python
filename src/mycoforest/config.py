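"""Simulation configuration for the synthetic forest-inventory generator.

The generator emulates a grid-based inventory of high-latitude temperate
forest: 30 m x 30 m plots (0.09 ha) of nine 10 m x 10 m subplots, stems with
DBH >= 3 cm, a species pool with ectomycorrhizal (EcM) / arbuscular
mycorrhizal (AM) / dual / other strategies, five soil depth layers, and ten
ecoregions. True effect sizes of EcM basal-area dominance on ln carbon
stocks, and its interactions with climate seasonality and species richness,
are configurable so that downstream inference can be validated against known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError

SOIL_LAYER_BOUNDS = [(0, 10), (10, 20), (20, 30), (30, 50), (50, 100)]

TRAIT_NAMES = ["Cmass", "Nmass", "Pmass", "Kmass", "LA", "SLA", "LMA", "LDMC"]


@dataclass
class SimConfig:
    """Ground-truth parameters for one synthetic dataset.

    Effect sizes are on the natural-log scale of the carbon stocks (Mg C/ha);
    the EcM dominance predictor is the boundary-transformed basal-area
    proportion, and interaction moderators (climate score, species richness)
    are z-scored within the dataset, matching the convention of the
    inference module.
    """

    # design
    n_ecoregions: int = 10
    plots_per_ecoregion: int = 50
    n_species: int = 240
    plot_area_ha: float = 0.09

    # species pool composition
    frac_ecm: float = 0.40
    frac_dual: float = 0.05
    frac_other: float = 0.0125
    frac_pioneer: float = 0.15
    frac_climax: float = 0.15
    trait_missing_frac: float = 0.05

    # true effects (ln Mg C/ha per unit transformed EcM dominance)
    beta_ecm_tree: float = 0.4
    beta_ecm_soil: float = 0.3
    beta_int_climate: float = 0.15
    beta_int_sr: float = -0.15

    # nuisance structure shared by the tree- and soil-carbon equations
    beta_richness: float = 0.08
    beta_climate: float = -0.10
    beta_stage_mid: float = 0.08
    beta_stage_late: float = 0.15
    beta_slope: float = -0.02
    beta_altitude: float = -0.05
    intercept_tree: float = 3.7   # ln(Mg C/ha); exp ~ 40 Mg C/ha
    intercept_soil: float = 4.4   # ln(Mg C/ha); exp ~ 80 Mg C/ha

    # variance components
    sigma_ecoregion: float = 0.3
    sigma_resid: float = 0.3

    # community structure
    mean_stems_per_plot: float = 40.0
    min_stems_per_plot: int = 5
    pool_min: int = 3
    pool_max: int = 25
    ecm_tilt_sd: float = 1.2
    succession_strength: float = 2.5
    climate_loading: float = 0.486  # sqrt(0.236): PCA axis 1 explains ~62% of TS/PS variance

    # allometry shared by generator and metrics: ln(kg) = c0 + c1*ln(dbh_cm^2 * h_m)
    allometry_coeffs: tuple[float, float] = (-2.5, 0.95)

    frac_soil_missing: float = 0.0
    seed: int = 0

    def validate(self) -> "SimConfig":
        fracs = {
            "frac_ecm": self.frac_ecm,
            "frac_dual": self.frac_dual,
            "frac_other": self.frac_other,
            "frac_pioneer": self.frac_pioneer,
            "frac_climax": self.frac_climax,
            "trait_missing_frac": self.trait_missing_frac,
            "frac_soil_missing": self.frac_soil_missing,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.frac_ecm + self.frac_dual + self.frac_other > 1.0 + 1e-12:
            raise ConfigurationError(
                "frac_ecm + frac_dual + frac_other must not exceed 1"
            )
        if self.frac_pioneer + self.frac_climax > 1.0 + 1e-12:
            raise ConfigurationError("frac_pioneer + frac_climax must not exceed 1")
        for name in ("sigma_ecoregion", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("n_ecoregions", "plots_per_ecoregion", "n_species"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.plot_area_ha <= 0:
            raise ConfigurationError("plot_area_ha must be > 0")
        if not 1 <= self.pool_min <= self.pool_max:
            raise ConfigurationError("need 1 <= pool_min <= pool_max")
        if self.min_stems_per_plot < 1:
            raise ConfigurationError("min_stems_per_plot must be >= 1")
        return self

    @property
    def n_plots(self) -> int:
        return self.n_ecoregions * self.plots_per_ecoregion

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["allometry_coeffs"] = list(self.allometry_coeffs)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "allometry_coeffs" in data:
            data = dict(data)
            data["allometry_coeffs"] = tuple(data["allometry_coeffs"])
        return cls(**data).validate()
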