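"""Original-vs-filtered network comparison.

Node-level topology metrics on the undirected bipartite graph (degree,
average shortest path length, closeness centrality, neighbourhood
connectivity, radiality), nonparametric significance tests between the
two networks' metric distributions, and retention ratios of targets,
pathological genes and significant GO terms.

Disconnected graphs are handled per connected component: the average
shortest path length and radiality of a node are computed within its
component, and closeness uses the reachable-only correction
closeness(v) = (reachable - 1) / sum of distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import mannwhitneyu, ttest_ind

from .enrich import significant_sets
from .errors import DataError, InsufficientDataError
from .network import CTNetwork, PathologicalGeneSet

TOPOLOGY_METRICS = ("degree", "aspl", "closeness",
                    "neighborhood_connectivity", "radiality")


def topology_profile(net: CTNetwork | nx.Graph) -> pd.DataFrame:
    """Per-node topology metrics of the (bipartite) graph.

    Returns a DataFrame indexed by node with columns ``partition``,
    ``degree``, ``aspl``, ``closeness``, ``neighborhood_connectivity``
    and ``radiality``. Isolated nodes get NaN for the path-based metrics
    and for neighbourhood connectivity.
    """
    g = net.to_graph() if isinstance(net, CTNetwork) else net
    if g.number_of_edges() == 0:
        raise DataError("topology_profile: graph has no edges")
    rows = {}
    for component in nx.connected_components(g):
        sub = g.subgraph(component)
        nc = len(component)
        dists = {v: nx.single_source_shortest_path_length(sub, v) for v in component}
        diameter = max(max(d.values()) for d in dists.values()) if nc > 1 else 0
        for v in component:
            deg = g.degree(v)
            if nc == 1:
                rows[v] = {"degree": deg, "aspl": float("nan"),
                           "closeness": float("nan"),
                           "neighborhood_connectivity": float("nan"),
                           "radiality": float("nan")}
                continue
            total = sum(dists[v].values())
            rows[v] = {
                "degree": deg,
                "aspl": total / (nc - 1),
                "closeness": (nc - 1) / total,
                "neighborhood_connectivity":
                    sum(g.degree(u) for u in g.neighbors(v)) / deg,
                "radiality":
                    sum(diameter + 1 - d for u, d in dists[v].items() if u != v)
                    / (nc - 1),
            }
    profile = pd.DataFrame.from_dict(rows, orient="index")
    profile["partition"] = [g.nodes[v].get("partition", "") for v in profile.index]
    return profile.sort_index()[["partition", *TOPOLOGY_METRICS]]


def compare_topology(original: pd.DataFrame, filtered: pd.DataFrame,
                     metrics=TOPOLOGY_METRICS, test: str = "mannwhitney",
                     by_partition: bool = False) -> pd.DataFrame:
    """Two-sided test per metric between the two node-metric distributions.

    ``test`` is ``mannwhitney`` (default) or ``welch``. With
    ``by_partition`` the comparison is additionally stratified into
    compound and target nodes; the pooled rows carry partition ``all``.
    """
    if test not in ("mannwhitney", "welch"):
        raise DataError(f"unknown test {test!r}")
    groups = [("all", original, filtered)]
    if by_partition:
        for part in sorted(set(original["partition"]) | set(filtered["partition"])):
            groups.append((part,
                           original[original["partition"] == part],
                           filtered[filtered["partition"] == part]))
    rows = []
    for part, orig, filt in groups:
        for metric in metrics:
            a = orig[metric].dropna().to_numpy()
            b = filt[metric].dropna().to_numpy()
            if len(a) < 3 or len(b) < 3:
                raise InsufficientDataError(
                    f"metric {metric} ({part}): need >= 3 nodes per group, "
                    f"got {len(a)} and {len(b)}")
            if test == "mannwhitney":
                stat, p = mannwhitneyu(a, b, alternative="two-sided")
            else:
                stat, p = ttest_ind(a, b, equal_var=False)
            rows.append({"partition": part, "metric": metric,
                         "statistic": float(stat), "p": float(p),
                         "n_original": len(a), "n_filtered": len(b)})
    return pd.DataFrame(rows)


def _ratio(filtered_count: int, original_count: int) -> float | None:
    """|filtered ∩ ref| / |original ∩ ref|; None when undefined."""
    if original_count == 0:
        return None
    return filtered_count / original_count


@dataclass(frozen=True)
class RetentionReport:
    """Fractions of the original network's content kept after filtering."""

    target_retention: float | None
    pathological_gene_retention: float | None
    herb_retention: float | None
    go_retention: dict[str, float | None]

    def as_dict(self) -> dict:
        return {"target_retention": self.target_retention,
                "pathological_gene_retention": self.pathological_gene_retention,
                "herb_retention": self.herb_retention,
                "go_retention": dict(self.go_retention)}


def retention_report(original: CTNetwork, filtered: CTNetwork,
                     patho: PathologicalGeneSet | None = None,
                     enrich_orig: dict[str, pd.DataFrame] | None = None,
                     enrich_filt: dict[str, pd.DataFrame] | None = None,
                     alpha: float = 0.05) -> RetentionReport:
    """Retention ratios of targets, pathological genes, herbs and GO terms.

    ``enrich_orig``/``enrich_filt`` map an ontology branch name (for
    example GOBP/GOCC/GOMF) to the enrichment result of the original and
    filtered target sets; GO retention is the fraction of the original
    branch's significant terms still significant after filtering.
    Undefined ratios (zero denominator) are reported as None.
    """
    if not set(filtered.compounds) <= set(original.compounds):
        raise DataError("filtered compounds are not a subset of the original")
    if not set(filtered.targets) <= set(original.targets):
        raise DataError("filtered targets are not a subset of the original")
    tr = _ratio(filtered.n_targets, original.n_targets)
    pr = None
    if patho is not None:
        pr = _ratio(len(set(filtered.targets) & patho.genes),
                    len(set(original.targets) & patho.genes))
    herbs_of = lambda net: {h for hs in net.herb_membership.values() for h in hs}
    hr = _ratio(len(herbs_of(filtered)), len(herbs_of(original)))
    go: dict[str, float | None] = {}
    if enrich_orig and enrich_filt:
        for branch in enrich_orig:
            sig_o = significant_sets(enrich_orig[branch], alpha)
            sig_f = significant_sets(enrich_filt.get(branch, pd.DataFrame()), alpha)
            go[branch] = _ratio(len(sig_o & sig_f), len(sig_o))
    return RetentionReport(target_retention=tr, pathological_gene_retention=pr,
                           herb_retention=hr, go_retention=go)


def shared_fraction(nets: list[CTNetwork], what: str = "targets") -> float | None:
    """Fraction of the union of node ids shared by every network."""
    if not nets:
        return None
    sets = [set(getattr(n, what)) for n in nets]
    union = set().union(*sets)
    if not union:
        return None
    shared = sets[0]
    for s in sets[1:]:
        shared = shared & s
    return len(shared) / len(union)
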