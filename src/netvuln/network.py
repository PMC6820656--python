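"""Condition-specific subnetwork extraction and topology.

The analyzed subnetwork keeps the reference edges whose miRNA and mRNA are
both differentially expressed.  Centrality treats the bipartite graph as
undirected (standard network-biology practice): betweenness is normalized
by (N-1)(N-2)/2, closeness is computed within each connected component
with Wasserman-Faust scaling, and hubs/bottlenecks are the top
``hub_fraction`` of nodes by degree/betweenness with ties at the boundary
included.  The scale-free check fits ordinary least squares to
(log10 degree, log10 frequency) over distinct degrees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data_io import RegulatoryNetwork
from .errors import DegenerateDataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = ["PowerLawFit", "extract_subnetwork", "topology", "powerlaw_fit"]


@dataclass(frozen=True)
class PowerLawFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def extract_subnetwork(
    reference: RegulatoryNetwork,
    de_mirnas,
    de_mrnas,
) -> RegulatoryNetwork:
    """Edges of ``reference`` whose miRNA is in ``de_mirnas`` and whose
    mRNA is in ``de_mrnas``; nodes without surviving edges are dropped.
    An empty result is valid (logged as a warning)."""
    mi = set(de_mirnas)
    mr = set(de_mrnas)
    edges = [(m, g) for m, g in reference.edges if m in mi and g in mr]
    if not edges:
        logger.warning("subnetwork is empty: no reference edge joins the DE lists")
    return RegulatoryNetwork(edges)


def _graph(network: RegulatoryNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(network.mirnas, kind="mirna")
    g.add_nodes_from(network.mrnas, kind="mrna")
    g.add_edges_from(network.edges)
    return g


def _top_fraction(values: pd.Series, fraction: float) -> pd.Series:
    """Boolean mask of the ceil(fraction*N) largest values, ties at the
    boundary included."""
    n = len(values)
    k = math.ceil(fraction * n)
    k = max(min(k, n), 1)
    cutoff = np.sort(values.to_numpy())[::-1][k - 1]
    return values >= cutoff


def topology(
    network: RegulatoryNetwork,
    hub_fraction: float = 0.10,
    rank_within: str = "all",
) -> pd.DataFrame:
    """Per-node degree, betweenness, closeness, and hub/bottleneck flags.

    ``rank_within`` chooses the population the top-fraction rule ranks
    over: ``"all"`` nodes (default) or ``"mirna"`` only (mRNAs then never
    get flagged).
    """
    if network.n_edges == 0:
        raise DegenerateDataError("cannot compute topology of an empty network")
    if not (0 < hub_fraction < 1):
        raise ParameterError(f"hub_fraction must be in (0,1), got {hub_fraction}")
    if rank_within not in ("all", "mirna"):
        raise ParameterError("rank_within must be 'all' or 'mirna'")
    g = _graph(network)
    bc = nx.betweenness_centrality(g, normalized=True)
    cc = nx.closeness_centrality(g)  # Wasserman-Faust component scaling
    nodes = list(network.mirnas) + list(network.mrnas)
    df = pd.DataFrame(
        {
            "kind": ["mirna"] * len(network.mirnas) + ["mrna"] * len(network.mrnas),
            "degree": [g.degree(n) for n in nodes],
            "betweenness": [bc[n] for n in nodes],
            "closeness": [cc[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    if rank_within == "all":
        df["hub"] = _top_fraction(df["degree"], hub_fraction)
        df["bottleneck"] = _top_fraction(df["betweenness"], hub_fraction)
    else:
        mask = df["kind"] == "mirna"
        hub = pd.Series(False, index=df.index)
        bot = pd.Series(False, index=df.index)
        hub[mask] = _top_fraction(df.loc[mask, "degree"], hub_fraction)
        bot[mask] = _top_fraction(df.loc[mask, "betweenness"], hub_fraction)
        df["hub"] = hub
        df["bottleneck"] = bot
    return df


def powerlaw_fit(network: RegulatoryNetwork) -> PowerLawFit:
    """OLS fit of log10 degree frequency against log10 degree.

    For each distinct degree k with frequency f(k) > 0 over all nodes,
    regress log10 f(k) on log10 k; reports slope, intercept and R^2.
    Requires >= 3 distinct degree values.
    """
    if network.n_edges == 0:
        raise DegenerateDataError("empty network")
    g = _graph(network)
    degrees = np.array([d for _, d in g.degree()], dtype=int)
    ks, freq = np.unique(degrees[degrees > 0], return_counts=True)
    if ks.size < 3:
        raise DegenerateDataError(
            f"degenerate degree distribution: {ks.size} distinct degree value(s)"
        )
    x = np.log10(ks.astype(float))
    y = np.log10(freq.astype(float))
    fit = stats.linregress(x, y)
    return PowerLawFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        n_points=int(ks.size),
    )
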