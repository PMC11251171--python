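"""Guild-annotated fungal OTU table summaries.

The table has OTUs in rows (otu_id, guild in {EcM, SAP, other}) and one
integer count column per plot. Summaries: guild relative abundances and
Shannon diversity (natural log) for all fungi, EcM fungi and saprotrophic
(SAP) fungi, plus OLS regressions of those summaries on EcM tree dominance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DegenerateInputError, DomainError, SchemaError
from .inference import fit_simple_regression

log = logging.getLogger("mycoforest")

GUILDS = ("EcM", "SAP", "other")
META_COLS = ("otu_id", "guild")


def _plot_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLS]


def validate_otu_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in META_COLS:
        if col not in table.columns:
            raise SchemaError(f"OTU table missing column {col!r}")
    if table["otu_id"].duplicated().any():
        raise SchemaError("duplicate otu_id rows in OTU table")
    counts = table[_plot_columns(table)]
    arr = counts.to_numpy()
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise DomainError("OTU counts must be non-negative integers")
    return table


def filter_low_abundance(table: pd.DataFrame, threshold: int = 10) -> pd.DataFrame:
    """Drop OTUs whose total count across all plots is <= threshold.

    The rule is strict: a total of exactly ``threshold`` is removed (the
    standard guard against PCR/sequencing artifacts).
    """
    validate_otu_table(table)
    totals = table[_plot_columns(table)].sum(axis=1)
    kept = table[totals > threshold]
    log.info("low-abundance filter (<= %d reads): removed %d of %d OTUs",
             threshold, len(table) - len(kept), len(table))
    return kept


def guild_relative_abundance(table: pd.DataFrame, plot_id: str, guild: str) -> float:
    """Share of a plot's reads belonging to one guild; NaN for empty plots."""
    if guild not in GUILDS:
        raise DomainError(f"unknown guild {guild!r}")
    if plot_id not in table.columns:
        raise SchemaError(f"plot {plot_id!r} not in OTU table")
    counts = table[plot_id].to_numpy(dtype=float)
    total = counts.sum()
    if total <= 0:
        log.warning("plot %s has zero reads; relative abundance is missing", plot_id)
        return float("nan")
    return float(counts[(table["guild"] == guild).to_numpy()].sum() / total)


def shannon_index(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i over positive-count OTUs."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        return float("nan")
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def summarize_fungi(table: pd.DataFrame) -> pd.DataFrame:
    """Per-plot guild shares and Shannon indices (all / EcM / SAP fungi)."""
    validate_otu_table(table)
    guild = table["guild"].to_numpy()
    rows = []
    for plot in _plot_columns(table):
        counts = table[plot].to_numpy(dtype=float)
        total = counts.sum()
        row = {"plot_id": plot}
        for g in ("EcM", "SAP", "other"):
            row[f"{g.lower()}_abundance"] = (
                counts[guild == g].sum() / total if total > 0 else np.nan
            )
        row["shannon_all"] = shannon_index(counts)
        row["shannon_ecm"] = shannon_index(counts[guild == "EcM"])
        row["shannon_sap"] = shannon_index(counts[guild == "SAP"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("plot_id")


def guild_vs_dominance(metrics: pd.DataFrame, summary: pd.DataFrame,
                       responses: tuple[str, ...] = ("ecm_abundance", "sap_abundance",
                                                     "shannon_ecm", "shannon_sap")) -> pd.DataFrame:
    """OLS of each fungal summary on EcM tree dominance.

    ``metrics`` must carry an ``ecmd`` column indexed (or keyed) by plot_id;
    only plots present in both tables enter each fit.
    """
    if "ecmd" in metrics.columns and "plot_id" in metrics.columns:
        ecmd = metrics.set_index("plot_id")["ecmd"]
    elif "ecmd" in metrics.columns:
        ecmd = metrics["ecmd"]
    else:
        raise SchemaError("metrics table lacks an 'ecmd' column")
    joined = summary.join(ecmd, how="inner")
    if len(joined) < 3:
        raise DegenerateInputError("need >= 3 plots with both EcMD and fungal data")
    rows = []
    for resp in responses:
        sub = joined[np.isfinite(joined[resp]) & np.isfinite(joined["ecmd"])]
        fit = fit_simple_regression(sub["ecmd"], sub[resp])
        r = sstats.pearsonr(sub["ecmd"], sub[resp])
        rows.append({"response": resp, "slope": fit.slope, "intercept": fit.intercept,
                     "p": fit.p_value, "r2": fit.r_squared, "r": float(r.statistic),
                     "n": len(sub)})
    return pd.DataFrame(rows).set_index("response")
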