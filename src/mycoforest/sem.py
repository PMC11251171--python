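"""Piecewise structural equation modelling.

Each endogenous node of a user-specified DAG is fitted with its own linear
(mixed) model - parents as fixed effects, ecoregion random intercept - and
the DAG's global fit is judged by testing the conditional-independence
claims its missing edges imply (Shipley's d-separation basis set) and
combining their p-values into Fisher's C = -2 * sum(ln p), chi-square with
2k degrees of freedom under the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DomainError, SpecificationError
from .inference import _mixed_or_ols

log = logging.getLogger("mycoforest")

#: default node set: climate seasonality score, succession (compositional
#: index), ln species richness, transformed EcM dominance, functional
#: diversity (Rao's Q), and one ln carbon stock
DEFAULT_NODES = ("climate", "succession", "richness", "ecmd", "fd", "carbon")

DEFAULT_EDGES = (
    ("climate", "ecmd"), ("richness", "ecmd"), ("succession", "ecmd"),
    ("climate", "fd"), ("succession", "fd"), ("richness", "fd"), ("ecmd", "fd"),
    ("ecmd", "carbon"), ("fd", "carbon"),
    ("climate", "carbon"), ("succession", "carbon"), ("richness", "carbon"),
)


def build_dag(edges, nodes=None) -> nx.DiGraph:
    """Directed acyclic graph from an edge list; cycles are rejected."""
    g = nx.DiGraph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise SpecificationError("path model must be acyclic")
    return g


def default_dag() -> nx.DiGraph:
    """The a priori path skeleton linking climate, succession, richness,
    EcM dominance and functional diversity to a carbon stock."""
    return build_dag(DEFAULT_EDGES, DEFAULT_NODES)


@dataclass
class IndependenceClaim:
    """One d-separation claim: x independent of y given ``cond``.

    ``y`` is the causally later node (tested as response); ``cond`` is the
    union of both nodes' parents.
    """

    x: str
    y: str
    cond: tuple[str, ...]
    p: float | None = None


def basis_set(dag: nx.DiGraph, exclude_exogenous_pairs: bool = True) -> list[IndependenceClaim]:
    """Shipley's d-separation basis set of a DAG.

    One claim per non-adjacent node pair, conditioned on the union of the
    pair's parents and tested on the causally later node. By default pairs
    of exogenous nodes are skipped (their covariance is free, the
    piecewise-SEM convention); with ``exclude_exogenous_pairs=False`` the
    full construction is used and the basis-set size equals
    (number of node pairs) - (number of edges).
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise SpecificationError("basis set requires an acyclic graph")
    order = {n: i for i, n in enumerate(nx.lexicographical_topological_sort(dag))}
    claims = []
    for a, b in combinations(sorted(dag.nodes, key=order.get), 2):
        if dag.has_edge(a, b) or dag.has_edge(b, a):
            continue
        if exclude_exogenous_pairs and dag.in_degree(a) == 0 and dag.in_degree(b) == 0:
            continue
        x, y = (a, b) if order[a] <= order[b] else (b, a)
        cond = sorted((set(dag.predecessors(x)) | set(dag.predecessors(y))) - {x, y})
        claims.append(IndependenceClaim(x=x, y=y, cond=tuple(cond)))
    return claims


def fisher_c(p_values) -> tuple[float, int, float]:
    """Fisher's C = -2 * sum(ln p_i), df = 2k, upper-tail chi-square p.

    An empty claim list is the saturated model: (0, 0, 1).
    """
    p_values = list(p_values)
    if not p_values:
        return 0.0, 0, 1.0
    p_arr = np.asarray(p_values, dtype=float)
    if np.any((p_arr <= 0) | (p_arr > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    C = float(-2.0 * np.log(p_arr).sum())
    df = 2 * len(p_arr)
    return C, df, float(stats.chi2.sf(C, df))


@dataclass
class PathModel:
    graph: nx.DiGraph
    paths: pd.DataFrame = field(default_factory=pd.DataFrame)
    # cause, effect, est, std_est, se, p per edge
    claims: list[IndependenceClaim] = field(default_factory=list)
    fisher: tuple[float, int, float] = (np.nan, 0, np.nan)
    submodel_method: dict[str, str] = field(default_factory=dict)

    def coefficient(self, cause: str, effect: str, standardized: bool = True) -> float:
        row = self.paths[(self.paths["cause"] == cause) & (self.paths["effect"] == effect)]
        if row.empty:
            raise SpecificationError(f"no fitted edge {cause} -> {effect}")
        return float(row["std_est" if standardized else "est"].iloc[0])


def _node_model(data: pd.DataFrame, response: str, predictors: list[str],
                groups: np.ndarray):
    X = pd.DataFrame({"const": 1.0}, index=data.index)
    for pred in predictors:
        X[pred] = data[pred].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    return _mixed_or_ols(y, X, groups)


def fit_paths(dag: nx.DiGraph, data: pd.DataFrame,
              group_col: str = "ecoregion_id") -> PathModel:
    """Fit every endogenous node's submodel and test the d-sep claims.

    ``data`` must hold one column per DAG node (already on the scale to be
    modelled, e.g. ln stocks) plus the grouping column. Standardized
    coefficients are b * sd(parent) / sd(child); claims are tested by adding
    the claimed-independent variable to the later node's parent model and
    reading its Wald p-value.
    """
    missing = [n for n in dag.nodes if n not in data.columns]
    if missing:
        raise SpecificationError(f"data lacks node column(s): {missing}")
    groups = data[group_col].to_numpy()
    rows = []
    methods = {}
    for node in nx.topological_sort(dag):
        parents = sorted(dag.predecessors(node))
        if not parents:
            continue
        params, bse, cov, _, _, _, method = _node_model(data, node, parents, groups)
        methods[node] = method
        sd_y = float(data[node].std(ddof=0))
        for parent in parents:
            b = float(params[parent])
            se = float(bse[parent])
            sd_x = float(data[parent].std(ddof=0))
            rows.append({
                "cause": parent, "effect": node, "est": b,
                "std_est": b * sd_x / sd_y, "se": se,
                "p": float(2 * stats.norm.sf(abs(b / se))),
            })
    claims = basis_set(dag)
    for claim in claims:
        preds = sorted(set(claim.cond) | {claim.x})
        params, bse, _, _, _, _, _ = _node_model(data, claim.y, preds, groups)
        zstat = float(params[claim.x] / bse[claim.x])
        claim.p = float(2 * stats.norm.sf(abs(zstat)))
    fisher = fisher_c([c.p for c in claims])
    return PathModel(graph=dag, paths=pd.DataFrame(rows), claims=claims,
                     fisher=fisher, submodel_method=methods)


def indirect_effect(model: PathModel, route: list[str], standardized: bool = True) -> float:
    """Product of (standardized) coefficients along a directed route."""
    if len(route) < 2:
        raise SpecificationError("route needs at least two nodes")
    eff = 1.0
    for cause, effect in zip(route[:-1], route[1:]):
        if not model.graph.has_edge(cause, effect):
            raise SpecificationError(f"route uses missing edge {cause} -> {effect}")
        eff *= model.coefficient(cause, effect, standardized=standardized)
    return eff


def simulate_from_dag(dag: nx.DiGraph, coefficients: dict[tuple[str, str], float],
                      n: int, *, n_groups: int = 10, sigma_group: float = 0.2,
                      sigma_resid: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Draw data from a linear-Gaussian SEM with group (ecoregion) intercepts.

    Exogenous nodes are standard normal; each endogenous node is the
    coefficient-weighted sum of its parents plus a group intercept and
    Gaussian noise. Used for calibration of the d-separation test.
    """
    for edge in coefficients:
        if not dag.has_edge(*edge):
            raise SpecificationError(f"coefficient given for missing edge {edge}")
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(n_groups), int(np.ceil(n / n_groups)))[:n]
    data = pd.DataFrame({"ecoregion_id": groups})
    for node in nx.topological_sort(dag):
        parents = list(dag.predecessors(node))
        if not parents:
            data[node] = rng.standard_normal(n)
        else:
            u = rng.normal(0, sigma_group, n_groups)[groups]
            x = sum(coefficients.get((p, node), 0.0) * data[p].to_numpy() for p in parents)
            data[node] = x + u + rng.normal(0, sigma_resid, n)
    return data
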