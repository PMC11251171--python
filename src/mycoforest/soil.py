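"""Soil organic carbon density and forest-carbon aggregation.

Per depth layer, SOCD (Mg C/ha) = (1 - V) * B * C * T / 10 with V the gravel
(>2 mm) volume fraction, B the bulk density (g/cm^3), C the organic carbon
content (g/kg) and T the layer thickness (cm); a plot's soil carbon stock is
the sum over its available layers (shallow profiles sum fewer than five).
Forest carbon is tree carbon + soil carbon, and is missing whenever soil
carbon is missing - absence is never treated as zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DomainError

log = logging.getLogger("mycoforest")


def layer_socd(gravel_frac, bulk_density, organic_c, thickness) -> float:
    """Organic carbon density of one soil layer, Mg C/ha.

    Units: gravel fraction dimensionless in [0,1], bulk density g/cm^3,
    organic C g/kg, thickness cm; the /10 factor converts the product to
    Mg C/ha.
    """
    V = np.asarray(gravel_frac, dtype=float)
    B = np.asarray(bulk_density, dtype=float)
    C = np.asarray(organic_c, dtype=float)
    T = np.asarray(thickness, dtype=float)
    if np.any((V < 0) | (V > 1)):
        raise DomainError("gravel fraction must be in [0, 1]")
    if np.any(B <= 0):
        raise DomainError("bulk density must be > 0")
    if np.any(C < 0):
        raise DomainError("organic carbon content must be >= 0")
    if np.any(T <= 0):
        raise DomainError("layer thickness must be > 0")
    out = (1.0 - V) * B * C * T / 10.0
    return float(out) if out.ndim == 0 else out


def plot_socd(layers: pd.DataFrame, average_replicates: bool = True) -> float:
    """Soil organic carbon density of one plot, summed over its layers.

    Replicate rows for the same (plot, layer) are averaged before Eq.-style
    summation when ``average_replicates``. Returns NaN (missing, not zero)
    when no layers are present; callers must treat NaN as "excluded from
    soil/forest carbon analyses".
    """
    if len(layers) == 0:
        log.warning("plot_socd: no soil layers; soil carbon flagged missing")
        return float("nan")
    cols = ["gravel_frac", "bulk_density", "organic_c", "thickness"]
    if average_replicates and layers["layer_index"].duplicated().any():
        layers = layers.groupby("layer_index", as_index=False)[cols].mean()
    vals = layer_socd(
        layers["gravel_frac"].to_numpy(),
        layers["bulk_density"].to_numpy(),
        layers["organic_c"].to_numpy(),
        layers["thickness"].to_numpy(),
    )
    return float(np.atleast_1d(vals).sum())


def socd_table(soil: pd.DataFrame) -> pd.Series:
    """Vectorized per-plot SOCD for a multi-plot soil-layer table."""
    cols = ["gravel_frac", "bulk_density", "organic_c", "thickness"]
    agg = soil.groupby(["plot_id", "layer_index"], as_index=False)[cols].mean()
    per_layer = layer_socd(
        agg["gravel_frac"].to_numpy(),
        agg["bulk_density"].to_numpy(),
        agg["organic_c"].to_numpy(),
        agg["thickness"].to_numpy(),
    )
    out = pd.Series(np.atleast_1d(per_layer), index=agg["plot_id"]).groupby(level=0).sum()
    out.name = "soil_c"
    return out


def forest_carbon(tree_c, soil_c):
    """Forest carbon stock = tree carbon + soil carbon (Mg C/ha).

    Missing soil carbon propagates: the result is NaN, never a silent zero.
    """
    tree_c = np.asarray(tree_c, dtype=float)
    soil_c = np.asarray(soil_c, dtype=float)
    out = tree_c + soil_c
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        log.info("forest_carbon: %d plot(s) missing a component, flagged NaN", n_missing)
    return float(out) if out.ndim == 0 else out


def ln_stock(x):
    """Natural log of a carbon stock; non-positive values become NaN.

    Log-scale models exclude plots with non-positive stocks; the count of
    exclusions is logged rather than silently dropped.
    """
    x = np.asarray(x, dtype=float)
    bad = (x <= 0) & ~np.isnan(x)
    if bad.any():
        log.warning("ln_stock: %d non-positive stock(s) excluded from log scale", int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan)
    return float(out) if out.ndim == 0 else out
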