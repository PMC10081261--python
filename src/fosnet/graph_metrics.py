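"""Thresholded functional graphs, centrality measures and hub reports.

The connectome's correlation matrix is turned into an undirected,
unweighted graph by keeping region pairs with R strictly above a threshold
(0.75 by default; negative correlations never create edges).  On that
graph we compute per-region degree, unnormalized shortest-path betweenness,
the participation coefficient P_i = 1 - sum_s (kappa_is / k_i)^2 over
modules s, and the within-module degree z-score.  Hubs are regions in the
top-k (default 20) of *both* degree and betweenness; regions with the
highest participation coefficient are flagged as connector hubs.

Degree and betweenness come from networkx; participation coefficient and
within-module degree z-score are computed here from per-module edge counts
(the Brain-Connectivity-Toolbox definitions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .connectome import GroupConnectome

__all__ = [
    "ADDICTION_REGIONS",
    "build_graph",
    "degree",
    "betweenness",
    "participation_coefficient",
    "within_module_degree_z",
    "compute_centralities",
    "identify_hubs",
    "HubReport",
    "compare_centrality_distributions",
    "DistributionComparison",
    "minimal_subnetwork",
]

#: Regions repeatedly implicated in nicotine addiction and withdrawal; the
#: default partner set for minimal-subnetwork extraction around the
#: cholinergic regions.
ADDICTION_REGIONS: tuple[str, ...] = (
    "ACA", "ILA", "PL", "DP", "CP", "ACB", "BST", "BLA", "CEA", "VTA", "IPN",
)


def build_graph(
    connectome: GroupConnectome | pd.DataFrame,
    threshold: float = 0.75,
    modules: pd.Series | None = None,
) -> nx.Graph:
    """Threshold R at ``R > threshold`` (strict) into an undirected graph.

    Every region stays a node even at degree 0, so hub ranks are over the
    full panel.  Module labels are attached as the ``module`` node
    attribute when available.
    """
    if isinstance(connectome, GroupConnectome):
        R, modules = connectome.R, connectome.modules
    else:
        R = connectome
    if not -1.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (-1, 1), got {threshold}")
    values = R.to_numpy()
    if np.isnan(values).any():
        raise ValueError("R has missing entries; drop zero-variance regions first")

    g = nx.Graph(threshold=float(threshold))
    g.add_nodes_from(R.index)
    iu, ju = np.triu_indices(len(R), k=1)
    keep = values[iu, ju] > threshold
    g.add_edges_from(
        (R.index[i], R.index[j]) for i, j in zip(iu[keep], ju[keep])
    )
    if modules is not None:
        nx.set_node_attributes(g, modules.to_dict(), "module")
    return g


def degree(graph: nx.Graph) -> pd.Series:
    """Neighbor count per region."""
    return pd.Series(dict(graph.degree()), name="degree").astype(int)


def betweenness(graph: nx.Graph, normalized: bool = False) -> pd.Series:
    """Shortest-path betweenness with fractional credit for tied paths.

    Unnormalized by default: the sum over unordered pairs (s, t), s != t
    != v, of sigma_st(v) / sigma_st; disconnected pairs contribute 0.
    """
    bc = nx.betweenness_centrality(graph, normalized=normalized)
    return pd.Series(bc, name="betweenness")


def _modules_from(graph: nx.Graph) -> dict:
    modules = nx.get_node_attributes(graph, "module")
    missing = [n for n in graph if n not in modules]
    if missing:
        raise ValueError(f"nodes without a module label: {missing[:5]}")
    return modules


def participation_coefficient(graph: nx.Graph) -> pd.Series:
    """P_i = 1 - sum_s (kappa_is / k_i)^2; 0 for isolated nodes.

    kappa_is counts node i's edges into module s.  P_i is 0 when all of a
    node's edges stay in one module and approaches 1 - 1/M as edges spread
    evenly over M modules.
    """
    modules = _modules_from(graph)
    out = {}
    for node in graph:
        k = graph.degree(node)
        if k == 0:
            out[node] = 0.0
            continue
        per_module: dict = {}
        for nbr in graph[node]:
            m = modules[nbr]
            per_module[m] = per_module.get(m, 0) + 1
        out[node] = 1.0 - sum((c / k) ** 2 for c in per_module.values())
    return pd.Series(out, name="participation")


def within_module_degree_z(graph: nx.Graph) -> pd.Series:
    """z_i = (kappa_i - mean_m) / sd_m over node i's own module m.

    kappa_i is i's edge count inside its module; mean/sd are over the
    module's nodes with the sample (ddof=1) standard deviation.  Modules
    of one node, or with zero spread, get z = 0.
    """
    modules = _modules_from(graph)
    within = {
        node: sum(1 for nbr in graph[node] if modules[nbr] == modules[node])
        for node in graph
    }
    out = {}
    by_module: dict = {}
    for node, m in modules.items():
        by_module.setdefault(m, []).append(node)
    for members in by_module.values():
        kappas = np.array([within[n] for n in members], dtype=float)
        if len(members) < 2 or kappas.std(ddof=1) == 0:
            for n in members:
                out[n] = 0.0
            continue
        mu, sd = kappas.mean(), kappas.std(ddof=1)
        for n, kap in zip(members, kappas):
            out[n] = (kap - mu) / sd
    return pd.Series(out, name="within_module_z")


def compute_centralities(graph: nx.Graph) -> pd.DataFrame:
    """Per-region degree, betweenness, participation and within-module z."""
    table = pd.concat(
        [
            degree(graph),
            betweenness(graph),
            participation_coefficient(graph),
            within_module_degree_z(graph),
        ],
        axis=1,
    )
    table.index.name = "region"
    return table


@dataclass(frozen=True)
class HubReport:
    """Hub classification from one graph's centrality table."""

    hubs: list[str]  # top-k of both degree and betweenness
    top_degree: list[str]
    top_betweenness: list[str]
    connector_hubs: list[str]  # top-k by participation coefficient
    participation_ranking: pd.DataFrame = field(repr=False)
    requested_k: int = 20
    effective_k: dict = field(default_factory=dict)


def _top_with_ties(values: pd.Series, k: int) -> list[str]:
    """All regions whose value ties or beats the k-th largest."""
    ranked = values.sort_values(ascending=False, kind="mergesort")
    cutoff = ranked.iloc[min(k, len(ranked)) - 1]
    return list(ranked.index[ranked >= cutoff])


def identify_hubs(centralities: pd.DataFrame, top_k: int = 20) -> HubReport:
    """Hub regions: top-k of both degree and betweenness; connector hubs:
    top-k participation coefficient.  Ties at the boundary are included
    and the effective k per measure is reported."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    n = len(centralities)
    if top_k > n:
        import warnings

        warnings.warn(f"top_k={top_k} exceeds {n} regions; capped", stacklevel=2)
        top_k = n
    top_deg = _top_with_ties(centralities["degree"], top_k)
    top_bet = _top_with_ties(centralities["betweenness"], top_k)
    top_pc = _top_with_ties(centralities["participation"], top_k)
    hubs = [r for r in centralities.index if r in set(top_deg) & set(top_bet)]
    ranking = centralities.sort_values(
        "participation", ascending=False, kind="mergesort"
    ).copy()
    ranking["connector_hub"] = ranking.index.isin(top_pc)
    return HubReport(
        hubs=hubs,
        top_degree=top_deg,
        top_betweenness=top_bet,
        connector_hubs=top_pc,
        participation_ranking=ranking,
        requested_k=top_k,
        effective_k={
            "degree": len(top_deg),
            "betweenness": len(top_bet),
            "participation": len(top_pc),
        },
    )


@dataclass(frozen=True)
class DistributionComparison:
    """Two-sample comparison of a centrality measure between graphs."""

    measure: str
    test: str  # statistic/p are Mann-Whitney; gate_selected records the gate's pick
    gate_selected: str
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    shapiro_p_a: float
    shapiro_p_b: float
    normal: bool  # both samples passed Shapiro-Wilk at alpha = 0.05


def compare_centrality_distributions(
    table_a: pd.DataFrame, table_b: pd.DataFrame, measure: str
) -> DistributionComparison:
    """Compare per-region centralities between two graphs.

    Normality of each sample is assessed with Shapiro-Wilk first; the
    centrality distributions of thresholded brain graphs are heavy-tailed,
    so the reported test is the two-sided Mann-Whitney U, with the gate's
    outcome recorded alongside.
    """
    a = pd.Series(table_a[measure]).dropna().to_numpy(dtype=float)
    b = pd.Series(table_b[measure]).dropna().to_numpy(dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 values per side")
    sw_a = stats.shapiro(a).pvalue if len(set(a)) > 1 else 0.0
    sw_b = stats.shapiro(b).pvalue if len(set(b)) > 1 else 0.0
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    normal = bool(sw_a > 0.05 and sw_b > 0.05)
    return DistributionComparison(
        measure=measure,
        test="mann-whitney",
        gate_selected="parametric" if normal else "mann-whitney",
        statistic=float(u),
        p_value=float(p),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        shapiro_p_a=float(sw_a),
        shapiro_p_b=float(sw_b),
        normal=normal,
    )


def minimal_subnetwork(source, region_set):
    """Induced subgraph (or submatrix) on a named region set.

    ``source`` may be a graph or a correlation DataFrame.  The canonical
    use is the union of the seven cholinergic regions with the
    :data:`ADDICTION_REGIONS` panel.  Unknown names raise, listing valid
    acronyms.
    """
    region_set = list(dict.fromkeys(region_set))
    if isinstance(source, nx.Graph):
        valid = set(source.nodes)
    else:
        valid = set(source.index)
    unknown = [r for r in region_set if r not in valid]
    if unknown:
        raise KeyError(
            f"unknown regions {unknown}; valid acronyms include "
            f"{sorted(valid)[:20]}{'...' if len(valid) > 20 else ''}"
        )
    if isinstance(source, nx.Graph):
        return source.subgraph(region_set).copy()
    keep = [r for r in source.index if r in set(region_set)]
    return source.loc[keep, keep]
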