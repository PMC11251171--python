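"""Successional ordination via the compositional index.

The procedure: (1) Importance Values (IV) per species per plot as the mean
of relative density, relative cover and relative frequency; (2) Climax
Adaptation Values (CAV) on a 1 (pioneer) to 10 (climax) scale - designated
pioneer/climax species are pinned at the endpoints, all other species are
interpolated from their Czekanowski similarity to the pioneer and climax
groups' plot-wise IV profiles; (3) a per-plot compositional index
sum(IV * CAV) in [1, 10]; (4) an ascending sort cut into equal-count
tertiles labelled early/middle/late.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, StagingError
from .metrics import stem_basal_area

log = logging.getLogger("mycoforest")

STAGES = ["early", "middle", "late"]
N_SUBPLOTS = 9


def importance_values(stems: pd.DataFrame, cover: pd.Series | None = None) -> pd.DataFrame:
    """Species Importance Values per plot.

    IV = (relative density + relative cover + relative frequency) / 3, each
    component normalized to sum to 1 over the plot's species. ``cover`` maps
    (plot_id, species_id) -> measured canopy cover; when absent the basal-
    area share is used as the cover proxy.

    Returns columns plot_id, species_id, rel_density, rel_cover,
    rel_frequency, iv.
    """
    if len(stems) == 0:
        return pd.DataFrame(columns=["plot_id", "species_id", "rel_density",
                                     "rel_cover", "rel_frequency", "iv"])
    df = stems[["plot_id", "species_id", "subplot"]].copy()
    df["_ba"] = stem_basal_area(stems["dbh"].to_numpy())

    counts = df.groupby(["plot_id", "species_id"]).agg(
        n=("_ba", "size"), ba=("_ba", "sum"),
        n_subplots=("subplot", "nunique")).reset_index()

    if cover is not None:
        counts["cover"] = [
            cover.get((p, s), 0.0) for p, s in zip(counts["plot_id"], counts["species_id"])
        ]
    else:
        counts["cover"] = counts["ba"]

    def _norm(col: pd.Series) -> pd.Series:
        tot = col.groupby(counts["plot_id"]).transform("sum")
        return col / tot

    counts["rel_density"] = _norm(counts["n"].astype(float))
    counts["rel_cover"] = _norm(counts["cover"].astype(float))
    # raw frequency = share of the 9 subplots occupied, then normalized
    # across species so the three components share the sum-to-one scale
    counts["rel_frequency"] = _norm(counts["n_subplots"] / N_SUBPLOTS)
    counts["iv"] = counts[["rel_density", "rel_cover", "rel_frequency"]].mean(axis=1)
    return counts[["plot_id", "species_id", "rel_density", "rel_cover",
                   "rel_frequency", "iv"]]


def iv_profile_matrix(iv_rows: pd.DataFrame) -> pd.DataFrame:
    """Plots x species matrix of IVs (zeros where a species is absent)."""
    return iv_rows.pivot_table(index="plot_id", columns="species_id",
                               values="iv", fill_value=0.0, aggfunc="sum")


def czekanowski(a: np.ndarray, b: np.ndarray) -> float:
    """Percentage (Czekanowski) similarity: 2*sum(min)/(sum a + sum b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.minimum(a, b).sum() / denom)


def group_similarity(profiles: pd.DataFrame, species_id, group: list) -> float:
    """Similarity of one species' plot-wise IV profile to a species group.

    The group profile is the per-plot sum of the member species' IVs. The
    focal species is not removed from the group if it belongs to it, so a
    species compared against its own one-member group scores 1.
    """
    if not group:
        raise ConfigurationError("species group must be non-empty")
    a = profiles[species_id].to_numpy()
    members = [g for g in group if g in profiles.columns]
    if not members:
        return 0.0
    b = profiles[members].sum(axis=1).to_numpy()
    return czekanowski(a, b)


def climax_adaptation_value(sim_climax: float, sim_pioneer: float) -> float:
    """Interpolated CAV = (10*sim_climax + sim_pioneer)/(sim_climax + sim_pioneer).

    Bounded in [1, 10]; the limits reproduce the designated endpoint values
    (similarity to one group only -> 1 or 10).
    """
    if sim_climax < 0 or sim_pioneer < 0:
        raise DomainError("similarities must be >= 0")
    denom = sim_climax + sim_pioneer
    if denom == 0:
        raise DomainError("both similarities are zero; CAV is unassignable")
    return (10.0 * sim_climax + sim_pioneer) / denom


#: CAV assigned, with a warning, to species with zero similarity to both groups
NEUTRAL_CAV = 5.5


def cav_table(iv_rows: pd.DataFrame, species: pd.DataFrame,
              neutral_fallback: bool = True) -> pd.DataFrame:
    """CAVs for every species appearing in the IV table.

    Designated pioneers get 1, designated climax species 10; the similarity
    interpolation applies only to the remaining species. Species similar to
    neither group get the neutral value 5.5 with a warning (or raise, with
    ``neutral_fallback=False``).
    """
    profiles = iv_profile_matrix(iv_rows)
    seral = species.set_index("species_id")["seral_status"]
    pioneers = [s for s in profiles.columns if seral.get(s) == "pioneer"]
    climaxes = [s for s in profiles.columns if seral.get(s) == "climax"]
    if not pioneers or not climaxes:
        raise ConfigurationError(
            "need at least one designated pioneer and one climax species"
        )
    rows = []
    n_neutral = 0
    for sp in profiles.columns:
        status = seral.get(sp, "neither")
        if status == "pioneer":
            sim_p, sim_c, cav = 1.0, 0.0, 1.0
        elif status == "climax":
            sim_p, sim_c, cav = 0.0, 1.0, 10.0
        else:
            sim_p = group_similarity(profiles, sp, pioneers)
            sim_c = group_similarity(profiles, sp, climaxes)
            if sim_p + sim_c == 0:
                if not neutral_fallback:
                    raise DomainError(f"CAV unassignable for species {sp}")
                n_neutral += 1
                cav = NEUTRAL_CAV
            else:
                cav = climax_adaptation_value(sim_c, sim_p)
        rows.append((sp, sim_c, sim_p, cav))
    if n_neutral:
        log.warning("cav_table: %d species similar to neither group "
                    "assigned neutral CAV %.1f", n_neutral, NEUTRAL_CAV)
    return pd.DataFrame(rows, columns=["species_id", "sim_climax", "sim_pioneer", "cav"])


def compositional_index(iv_rows: pd.DataFrame, cavs: pd.DataFrame) -> pd.Series:
    """Per-plot compositional index sum_s IV_s * CAV_s, in [1, 10]."""
    cav_map = cavs.set_index("species_id")["cav"]
    missing = set(iv_rows["species_id"]) - set(cav_map.index)
    if missing:
        raise DomainError(f"species lacking a CAV: {sorted(missing)[:10]}")
    contrib = iv_rows["iv"] * iv_rows["species_id"].map(cav_map)
    out = contrib.groupby(iv_rows["plot_id"]).sum()
    out.name = "comp_index"
    return out


def assign_stages(comp_indices: pd.Series) -> pd.DataFrame:
    """Cut plots into early/middle/late tertiles of the compositional index.

    Plots are sorted ascending (ties broken by plot_id for determinism) and
    split into three nearly equal groups; stage sizes differ by at most 1.
    """
    if len(comp_indices) < 3:
        raise StagingError("need >= 3 plots to assign successional stages")
    ordered = comp_indices.sort_index().sort_values(kind="mergesort")
    parts = np.array_split(np.arange(len(ordered)), 3)
    stage = np.empty(len(ordered), dtype=object)
    for label, idx in zip(STAGES, parts):
        stage[idx] = label
    out = pd.DataFrame({
        "plot_id": ordered.index,
        "comp_index": ordered.to_numpy(),
        "rank": np.arange(1, len(ordered) + 1),
        "stage": stage,
    })
    out = out.set_index("plot_id").loc[comp_indices.index]
    out.index.name = "plot_id"
    return out.reset_index()


@dataclass
class SuccessionResult:
    iv: pd.DataFrame
    cav: pd.DataFrame
    stages: pd.DataFrame  # plot_id, comp_index, rank, stage


def run_succession(stems: pd.DataFrame, species: pd.DataFrame,
                   cover: pd.Series | None = None) -> SuccessionResult:
    """Full chain: IVs -> CAVs -> compositional index -> stage assignment."""
    iv = importance_values(stems, cover=cover)
    cavs = cav_table(iv, species)
    comp = compositional_index(iv, cavs)
    stages = assign_stages(comp)
    return SuccessionResult(iv=iv, cav=cavs, stages=stages)
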