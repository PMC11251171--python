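"""Per-plot forest metrics.

Tree carbon from a shared allometric equation, basal-area mycorrhizal
dominance, species richness, trait imputation, Rao's quadratic entropy, and
the seasonality-based climate score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import TRAIT_NAMES
from .errors import DegenerateInputError, DomainError, ImputationError

log = logging.getLogger("mycoforest")

#: biomass -> carbon conversion coefficient
CARBON_FRACTION = 0.5

DEFAULT_ALLOMETRY = (-2.5, 0.95)


def stem_basal_area(dbh):
    """Basal area (m^2) of a stem from its DBH in cm: pi * (dbh/200)^2."""
    dbh = np.asarray(dbh, dtype=float)
    if np.any(dbh <= 0):
        raise DomainError("dbh must be strictly positive")
    return np.pi * (dbh / 200.0) ** 2


def stem_biomass(dbh, height, coeffs=DEFAULT_ALLOMETRY):
    """Whole-tree biomass (kg) from DBH (cm) and height (m).

    A single allometric form is used for all species to avoid artifacts from
    species-specific equations: ln(kg) = c0 + c1 * ln(dbh^2 * height).
    """
    dbh = np.asarray(dbh, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(dbh <= 0) or np.any(height <= 0):
        raise DomainError("dbh and height must be strictly positive")
    c0, c1 = coeffs
    return np.exp(c0 + c1 * np.log(dbh ** 2 * height))


def plot_tree_carbon(stems: pd.DataFrame, coeffs=DEFAULT_ALLOMETRY,
                     area_ha: float = 0.09) -> float:
    """Tree carbon stock of one plot in Mg C/ha.

    Sum of stem biomass (kg) times the 0.5 carbon fraction, converted to Mg
    and divided by plot area. An empty plot is defined as 0 with a warning.
    """
    if area_ha <= 0:
        raise DomainError("area_ha must be > 0")
    if len(stems) == 0:
        log.warning("plot_tree_carbon: empty plot, tree carbon set to 0")
        return 0.0
    biomass_kg = stem_biomass(stems["dbh"].to_numpy(), stems["height"].to_numpy(), coeffs)
    return float(biomass_kg.sum() * CARBON_FRACTION / 1000.0 / area_ha)


# strategy weight toward the EcM side of the dominance ratio;
# dual-type species split their basal area equally between EcM and AM
_ECM_WEIGHT = {"EcM": 1.0, "AM": 0.0, "dual": 0.5}


def mycorrhizal_dominance(stems: pd.DataFrame, species: pd.DataFrame) -> tuple[float, float]:
    """(EcMD, AMD): shares of total basal area held by EcM vs AM species.

    ``stems`` must already be restricted to EcM/AM/dual species (see
    :func:`mycoforest.io.apply_strategy_exclusion`). Dual species contribute
    half their basal area to each side, so EcMD + AMD == 1.
    """
    if len(stems) == 0:
        raise DomainError("dominance undefined: no EcM/AM/dual stems in plot")
    strat = stems["species_id"].map(species.set_index("species_id")["strategy"])
    if strat.isna().any():
        raise DomainError("dominance: stems reference unknown species")
    ba = stem_basal_area(stems["dbh"].to_numpy())
    w = strat.map(_ECM_WEIGHT).to_numpy(dtype=float)
    if np.any(np.isnan(w)):
        raise DomainError("dominance requires only EcM/AM/dual strategies")
    total = ba.sum()
    if total <= 0:
        raise DomainError("dominance undefined: zero total basal area")
    ecmd = float((ba * w).sum() / total)
    return ecmd, 1.0 - ecmd


def dominance_table(stems: pd.DataFrame, species: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-plot (ecmd, amd) over a multi-plot stem table.

    Plots whose EcM/AM/dual basal area is zero get NaN dominance.
    """
    strat = stems["species_id"].map(species.set_index("species_id")["strategy"])
    w = strat.map(_ECM_WEIGHT)
    keep = w.notna()
    sub = stems.loc[keep].copy()
    sub["_ba"] = stem_basal_area(sub["dbh"].to_numpy())
    sub["_ecm_ba"] = sub["_ba"] * w.loc[keep].to_numpy(dtype=float)
    grp = sub.groupby("plot_id")[["_ba", "_ecm_ba"]].sum()
    out = pd.DataFrame(index=stems["plot_id"].unique())
    out.index.name = "plot_id"
    out["ecmd"] = grp["_ecm_ba"] / grp["_ba"]
    out["amd"] = 1.0 - out["ecmd"]
    return out


def species_richness(stems: pd.DataFrame) -> int:
    """Number of distinct tree species recorded in the plot."""
    return int(stems["species_id"].nunique())


def impute_traits(species: pd.DataFrame, traits: list[str] = TRAIT_NAMES) -> pd.DataFrame:
    """Complete the species x trait matrix.

    Multiple rows per species are averaged first; any cell still missing is
    filled with the cross-species mean of that trait. Raises
    :class:`ImputationError` if a trait has no value for any species.
    """
    cols = [t for t in traits if t in species.columns]
    missing_cols = sorted(set(traits) - set(cols))
    if missing_cols:
        raise ImputationError(f"trait columns absent from table: {missing_cols}")
    mat = species.groupby("species_id")[cols].mean()
    empty = [t for t in cols if mat[t].isna().all()]
    if empty:
        raise ImputationError(f"no species carries a value for trait(s): {empty}")
    n_filled = int(mat.isna().to_numpy().sum())
    if n_filled:
        log.info("impute_traits: filled %d missing cells with trait means", n_filled)
    return mat.fillna(mat.mean())


def gower_distance(trait_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Gower distance between species over range-normalized traits.

    Traits are on heterogeneous scales (mg/g, mm^2, ...), so each absolute
    difference is divided by the trait's observed range before averaging.
    Zero-range traits contribute zero distance.
    """
    X = trait_matrix.to_numpy(dtype=float)
    rng = X.max(axis=0) - X.min(axis=0)
    rng[rng == 0] = np.inf  # constant trait: no discriminating power
    D = np.abs(X[:, None, :] - X[None, :, :]) / rng
    D = D.mean(axis=2)
    return pd.DataFrame(D, index=trait_matrix.index, columns=trait_matrix.index)


def euclidean_z_distance(trait_matrix: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance on z-scored traits (alternative to Gower)."""
    X = trait_matrix.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = np.inf
    Z = (X - X.mean(axis=0)) / sd
    diff = Z[:, None, :] - Z[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))
    return pd.DataFrame(D, index=trait_matrix.index, columns=trait_matrix.index)


def trait_distance(trait_matrix: pd.DataFrame, metric: str = "gower") -> pd.DataFrame:
    if metric == "gower":
        return gower_distance(trait_matrix)
    if metric == "euclidean":
        return euclidean_z_distance(trait_matrix)
    raise DomainError(f"unknown trait distance metric: {metric!r}")


def rao_q(abundances, distance: pd.DataFrame | np.ndarray) -> float:
    """Rao's quadratic entropy: Q = sum_ij p_i p_j d_ij.

    ``abundances`` must be a probability vector over the plot's species (the
    expected trait distance between two randomly drawn individuals). If it is
    a named Series and ``distance`` a DataFrame, the distance matrix is
    aligned to the abundance index.
    """
    if isinstance(abundances, pd.Series) and isinstance(distance, pd.DataFrame):
        D = distance.loc[abundances.index, abundances.index].to_numpy(dtype=float)
        p = abundances.to_numpy(dtype=float)
    else:
        p = np.asarray(abundances, dtype=float)
        D = np.asarray(distance, dtype=float)
    if abs(p.sum() - 1.0) > 1e-8:
        raise DomainError(f"abundances must sum to 1, got {p.sum():.10f}")
    return float(p @ D @ p)


def climate_score(ts, ps) -> tuple[np.ndarray, float]:
    """Axis-1 PCA score of standardized temperature/precipitation seasonality.

    Both variables are z-scored, so the PCA is on their 2x2 correlation
    matrix. The sign is fixed so the TS loading is positive: a higher score
    means stronger joint seasonality, i.e. a less favorable climate for
    growth. Returns (scores, fraction of variance on axis 1).
    """
    ts = np.asarray(ts, dtype=float)
    ps = np.asarray(ps, dtype=float)
    if ts.size < 2 or ts.size != ps.size:
        raise DegenerateInputError("need >= 2 paired TS/PS values")
    sd_t, sd_p = ts.std(ddof=0), ps.std(ddof=0)
    if sd_t == 0 or sd_p == 0:
        raise DegenerateInputError("zero variance in TS or PS")
    Z = np.column_stack([(ts - ts.mean()) / sd_t, (ps - ps.mean()) / sd_p])
    C = np.corrcoef(Z.T)
    eigval, eigvec = np.linalg.eigh(C)
    v1 = eigvec[:, -1]
    if v1[0] < 0:
        v1 = -v1
    scores = Z @ v1
    var_explained = float(eigval[-1] / eigval.sum())
    return scores, var_explained
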