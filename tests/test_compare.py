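"""Topology metrics, significance comparison and retention ratios."""

import math
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from synergyscreen import (CTNetwork, DataError, InsufficientDataError,
                           compare_topology, pathological_genes,
                           retention_report, shared_fraction, topology_profile)


# ---------------------------------------------------------------- BFS oracle

def _bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _oracle_profile(g):
    """Straight-line recomputation of all metrics from raw BFS."""
    adj = {v: set(g.neighbors(v)) for v in g}
    out = {}
    comps = list(nx.connected_components(g))
    for comp in comps:
        dists = {v: _bfs_distances(adj, v) for v in comp}
        diam = max((d for dd in dists.values() for d in dd.values()), default=0)
        for v in comp:
            deg = len(adj[v])
            if len(comp) == 1:
                out[v] = (deg, math.nan, math.nan, math.nan, math.nan)
                continue
            total = sum(dists[v].values())
            aspl = total / (len(comp) - 1)
            clo = (len(comp) - 1) / total
            nc = sum(len(adj[u]) for u in adj[v]) / deg
            rad = sum(diam + 1 - d for u, d in dists[v].items() if u != v) / (len(comp) - 1)
            out[v] = (deg, aspl, clo, nc, rad)
    return out


def test_star_graph_center_closed_form():
    g = nx.star_graph(3)  # center node 0
    prof = topology_profile(g)
    assert prof.loc[0, "degree"] == 3
    assert prof.loc[0, "aspl"] == pytest.approx(1.0)
    assert prof.loc[0, "closeness"] == pytest.approx(1.0)
    # leaves: distance 1 to center, 2 to the other two leaves
    assert prof.loc[1, "aspl"] == pytest.approx(5 / 3)


def test_three_node_path_hand_computation():
    g = nx.path_graph(3)  # a-b-c
    prof = topology_profile(g)
    assert prof.loc[0, "aspl"] == pytest.approx(1.5)
    assert prof.loc[0, "closeness"] == pytest.approx(2 / 3)
    # diameter 2: radiality(a) = ((2+1-1) + (2+1-2)) / 2 = 1.5
    assert prof.loc[0, "radiality"] == pytest.approx(1.5)
    assert prof.loc[1, "closeness"] == pytest.approx(1.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_metrics_match_bfs_oracle_on_random_bipartite(seed):
    """All five node metrics agree with an independent BFS-based
    recomputation on random bipartite graphs of <= 50 nodes, including
    disconnected ones."""
    rng = np.random.default_rng(seed)
    g = nx.bipartite.random_graph(15, 30, 0.08, seed=int(rng.integers(1 << 30)))
    if g.number_of_edges() == 0:
        g.add_edge(0, 20)
    prof = topology_profile(g)
    oracle = _oracle_profile(g)
    for v, (deg, aspl, clo, ncon, rad) in oracle.items():
        row = prof.loc[v]
        assert row["degree"] == deg
        for col, want in (("aspl", aspl), ("closeness", clo),
                          ("neighborhood_connectivity", ncon),
                          ("radiality", rad)):
            if math.isnan(want):
                assert math.isnan(row[col])
            else:
                assert row[col] == pytest.approx(want)


def test_edgeless_graph_rejected():
    g = nx.empty_graph(4)
    with pytest.raises(DataError):
        topology_profile(g)


# ------------------------------------------------------- significance tests

def _net(prefix, n_comp, targets_per):
    compounds = tuple(f"{prefix}c{i:03d}" for i in range(n_comp))
    targets = tuple(f"T{j:02d}" for j in range(20))
    edges = set()
    rng = np.random.default_rng(99)
    for c in compounds:
        for t in rng.choice(targets, size=targets_per, replace=False):
            edges.add((c, t))
    return CTNetwork("P", compounds, targets, frozenset(edges),
                     {c: ("h",) for c in compounds})


def test_identical_networks_not_significant():
    net = _net("a", 30, 5)
    prof = topology_profile(net)
    result = compare_topology(prof, prof)
    assert (result["p"] > 0.99).all()


def test_planted_shift_detected_at_n200():
    """Removing 100 degree-1 decoration compounds from a 200-compound
    network shifts the degree/path-length distributions detectably."""
    targets = tuple(f"T{j:02d}" for j in range(20))
    core = {f"c{i:03d}": 6 for i in range(100)}
    edges = set()
    rng = np.random.default_rng(4)
    for c, k in core.items():
        for t in rng.choice(targets, size=k, replace=False):
            edges.add((c, t))
    decor = {f"d{i:03d}": 1 for i in range(100)}
    for c in decor:
        edges.add((c, str(rng.choice(targets))))
    compounds = tuple(sorted(core) + sorted(decor))
    original = CTNetwork("P", compounds, targets, frozenset(edges),
                         {c: ("h",) for c in compounds})
    filtered = original.subnetwork(sorted(core))
    result = compare_topology(topology_profile(original),
                              topology_profile(filtered))
    by_metric = result.set_index("metric")["p"]
    assert by_metric["degree"] < 0.05
    assert by_metric["aspl"] < 0.05


def test_random_label_partitions_rarely_significant():
    """Splitting one graph's node metrics into two random groups is a
    true null: p > 0.05 in at least 94 of 100 seeded replicates."""
    from scipy.stats import mannwhitneyu
    hits = 0
    for rep in range(100):
        rng = np.random.default_rng(1000 + rep)
        g = nx.bipartite.random_graph(20, 40, 0.12,
                                      seed=int(rng.integers(1 << 30)))
        if g.number_of_edges() < 10:
            g = nx.complete_bipartite_graph(20, 40)
        prof = topology_profile(g)
        vals = prof["aspl"].dropna().to_numpy()
        mask = rng.random(len(vals)) < 0.5
        if mask.sum() < 3 or (~mask).sum() < 3:
            hits += 1
            continue
        _, p = mannwhitneyu(vals[mask], vals[~mask], alternative="two-sided")
        if p > 0.05:
            hits += 1
    assert hits >= 94


def test_too_few_nodes_rejected():
    net = _net("a", 30, 5)
    prof = topology_profile(net)
    with pytest.raises(InsufficientDataError):
        compare_topology(prof, prof.iloc[:2])


# ---------------------------------------------------------------- retention

def test_identity_filtering_all_ratios_one():
    net = _net("a", 10, 5)
    patho = pathological_genes([t for t in net.targets], ["T00"], ["T01"], ["T02"])
    report = retention_report(net, net, patho)
    assert report.target_retention == 1.0
    assert report.pathological_gene_retention == 1.0
    assert report.herb_retention == 1.0


def test_no_pathological_genes_left_ratio_zero():
    net = _net("a", 10, 5)
    patho = pathological_genes(["T00"], ["T00"], [], [])
    keep = [c for c in net.compounds
            if not any(e == (c, "T00") for e in net.edges)]
    filtered = net.subnetwork(keep)
    report = retention_report(net, filtered, patho)
    assert report.pathological_gene_retention == 0.0


def test_planted_80pct_target_retention():
    """Deleting exactly 20% of targets (by removing their only
    compounds) realises a 0.80 retention ratio."""
    targets = tuple(f"T{j:02d}" for j in range(10))
    compounds = tuple(f"c{j:02d}" for j in range(10))
    edges = frozenset((c, t) for c, t in zip(compounds, targets))
    net = CTNetwork("P", compounds, targets, edges,
                    {c: ("h",) for c in compounds})
    filtered = net.subnetwork(compounds[:8])
    report = retention_report(net, filtered)
    assert report.target_retention == pytest.approx(0.80)


def test_zero_denominator_reported_missing():
    net = _net("a", 10, 5)
    patho = pathological_genes(["ZZZ"], ["ZZZ"], [], [])  # not in network
    report = retention_report(net, net, patho)
    assert report.pathological_gene_retention is None


def test_shared_fraction():
    a = _net("a", 5, 5)
    b = _net("b", 5, 5)
    assert shared_fraction([a, a]) == 1.0
    frac = shared_fraction([a, b], "targets")
    assert frac is not None and 0 <= frac <= 1
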