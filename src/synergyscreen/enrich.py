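"""Hypergeometric over-representation analysis with BH-FDR control.

For a query gene set drawn from a universe of N genes, a gene set with K
members (after restriction to the universe) and an observed overlap of k
out of n query genes, the enrichment p-value is the upper hypergeometric
tail P(X >= k). Sets smaller than 10 genes after universe restriction
are removed before testing; q-values are Benjamini-Hochberg adjusted
across the surviving sets.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DataError

log = logging.getLogger(__name__)

DEFAULT_MIN_SET_SIZE = 10
DEFAULT_FDR_LEVEL = 0.05


def hypergeom_enrich(query, gene_sets: dict[str, tuple],
                     universe, min_set_size: int = DEFAULT_MIN_SET_SIZE,
                     fdr_level: float = DEFAULT_FDR_LEVEL) -> pd.DataFrame:
    """Test each gene set for over-representation of the query.

    Query genes outside the universe are dropped with a warning; set
    members are restricted to the universe and the < ``min_set_size``
    filter applies after that restriction, since effective population
    sizes drive the test.

    Returns a DataFrame sorted by (q, p, set_id) with columns ``set_id``,
    ``set_size``, ``query_size``, ``overlap``, ``p``, ``q``,
    ``significant`` and ``overlapping_genes``.
    """
    universe = {str(g).upper() for g in universe}
    if not universe:
        raise DataError("hypergeom_enrich: empty universe")
    query = {str(g).upper() for g in query}
    if not query:
        raise DataError("hypergeom_enrich: empty query")
    dropped = query - universe
    if dropped:
        log.warning("hypergeom_enrich: %d query genes outside the universe dropped",
                    len(dropped))
    query &= universe
    if not query:
        raise DataError("hypergeom_enrich: no query genes inside the universe")
    N, n = len(universe), len(query)
    rows = []
    for set_id, members in gene_sets.items():
        members = {str(g).upper() for g in members} & universe
        K = len(members)
        if K < min_set_size:
            continue
        overlap = sorted(query & members)
        k = len(overlap)
        # upper tail P(X >= k); sf(k-1) = P(X > k-1)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_id": set_id, "set_size": K, "query_size": n,
                     "overlap": k, "p": min(p, 1.0),
                     "overlapping_genes": ",".join(overlap)})
    result = pd.DataFrame(
        rows, columns=["set_id", "set_size", "query_size", "overlap", "p",
                       "overlapping_genes"])
    if len(result):
        reject, q, _, _ = multipletests(result["p"].to_numpy(), method="fdr_bh")
        result["q"] = q
        result["significant"] = result["q"] <= fdr_level
    else:
        result["q"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return (result.sort_values(["q", "p", "set_id"])
                  .reset_index(drop=True)
                  [["set_id", "set_size", "query_size", "overlap", "p", "q",
                    "significant", "overlapping_genes"]])


def significant_sets(result: pd.DataFrame, alpha: float = DEFAULT_FDR_LEVEL) -> set[str]:
    """Set ids with q <= alpha."""
    if len(result) == 0:
        return set()
    return set(result.loc[result["q"] <= alpha, "set_id"])


def shared_significant_sets(results, alpha: float = DEFAULT_FDR_LEVEL) -> set[str]:
    """Set ids significant (q <= alpha) in every result list."""
    results = list(results)
    if len(results) < 2:
        raise DataError("shared_significant_sets needs at least two result lists")
    shared = significant_sets(results[0], alpha)
    for r in results[1:]:
        shared &= significant_sets(r, alpha)
    return shared
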