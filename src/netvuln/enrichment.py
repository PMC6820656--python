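"""Over-representation analysis of gene lists against gene-set collections.

One-sided hypergeometric test per set: with universe size N, set size K,
query size n and overlap k, p = P(X >= k) for X ~ Hypergeom(N, K, n);
fold enrichment is (k/n) / (K/N).  BH adjustment is applied across all
tested sets and a set is called significant when adj_p < alpha and
fold enrichment > fold_cut (both strict).  Sets with zero overlap are
omitted from the output.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .data_io import GeneSetCollection
from .diffexpr import bh_adjust
from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = ["ora"]


def ora(
    query,
    sets: GeneSetCollection,
    universe,
    alpha: float = 0.05,
    fold_cut: float = 1.5,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` within each set.

    Query and set members outside the universe are dropped (logged).
    Returns one row per set with k >= 1, sorted by adj_p then set_id,
    with columns set_id, k, K, n, N, fold_enrichment, p, adj_p,
    significant.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ParameterError("universe is empty")
    uni_set = set(uni)
    q_all = list(dict.fromkeys(query))
    q = [g for g in q_all if g in uni_set]
    dropped = len(q_all) - len(q)
    if dropped:
        logger.info("dropped %d query gene(s) outside the universe", dropped)
    if not q:
        raise ParameterError("query is empty after intersecting with the universe")
    N = len(uni)
    n = len(q)
    q_set = set(q)
    rows = []
    for sid in sets:
        members = [g for g in sets.members(sid) if g in uni_set]
        K = len(members)
        k = sum(1 for g in members if g in q_set)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append((sid, k, K, n, N, fold, p))
    if not rows:
        return pd.DataFrame(
            columns=["set_id", "k", "K", "n", "N", "fold_enrichment", "p",
                     "adj_p", "significant"]
        ).set_index("set_id")
    df = pd.DataFrame(rows, columns=["set_id", "k", "K", "n", "N",
                                     "fold_enrichment", "p"]).set_index("set_id")
    df["adj_p"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = (df["adj_p"] < alpha) & (df["fold_enrichment"] > fold_cut)
    df = df.assign(_id=df.index).sort_values(["adj_p", "_id"]).drop(columns="_id")
    return df
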