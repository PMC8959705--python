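"""Affinity screening, similarity deduplication, multilevel network and
the synergy score."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from synergyscreen import (ConfigError, DataError, build_multilevel,
                           dedupe_by_similarity, network_distances,
                           parse_vina_log, rank_candidates, screen_affinities,
                           synergy_scores)
from synergyscreen.chem import SimilarityMatrix


def _aff(rows):
    return pd.DataFrame(rows, columns=["compound_id", "target_id", "affinity"])


# ------------------------------------------------------------ affinity screen

def test_inclusive_cutoff_boundary():
    table = _aff([("c1", "t1", -9.1), ("c2", "t1", -8.0), ("c3", "t1", -7.9)])
    kept = screen_affinities(table)
    assert kept == {("c1", "t1"), ("c2", "t1")}


def test_all_weak_gives_empty_set():
    table = _aff([("c1", "t1", -5.0)])
    assert screen_affinities(table) == set()


def test_nan_affinity_and_positive_cutoff_rejected():
    with pytest.raises(DataError):
        screen_affinities(_aff([("c1", "t1", float("nan"))]))
    with pytest.raises(ConfigError):
        screen_affinities(_aff([("c1", "t1", -9.0)]), cutoff=8.0)


def test_screen_matches_boolean_mask_oracle():
    rng = np.random.default_rng(6)
    n = 10000
    table = _aff([(f"c{i}", "t", float(a))
                  for i, a in enumerate(rng.uniform(-12, -4, n))])
    kept = screen_affinities(table)
    expected = {(f"c{i}", "t") for i, a in enumerate(table["affinity"])
                if a <= -8.0}
    assert kept == expected


# ---------------------------------------------------------------- dedup

def _sim(ids, pairs):
    n = len(ids)
    v = np.eye(n)
    idx = {c: i for i, c in enumerate(ids)}
    for a, b, s in pairs:
        v[idx[a], idx[b]] = v[idx[b], idx[a]] = s
    return SimilarityMatrix(tuple(ids), v)


def test_pair_above_threshold_keeps_larger_target_count():
    sim = _sim(["a", "b"], [("a", "b", 0.6)])
    kept = dedupe_by_similarity(["a", "b"], sim, {"a": 5, "b": 3})
    assert kept == ("a",)


def test_similarity_exactly_half_keeps_both():
    sim = _sim(["a", "b"], [("a", "b", 0.5)])
    kept = dedupe_by_similarity(["a", "b"], sim, {"a": 5, "b": 3})
    assert kept == ("a", "b")


def test_chain_component_keeps_single_best():
    """A ~ B ~ C chain collapses to the compound with most targets,
    verified against exhaustive component enumeration."""
    sim = _sim(["A", "B", "C"], [("A", "B", 0.7), ("B", "C", 0.8)])
    counts = {"A": 2, "B": 9, "C": 4}
    kept = dedupe_by_similarity(["A", "B", "C"], sim, counts)
    assert kept == ("B",)
    # oracle: build components by brute force over the >0.5 relation
    g = nx.Graph()
    g.add_nodes_from("ABC")
    for i, a in enumerate("ABC"):
        for b in "ABC"[i + 1:]:
            if sim.loc(a, b) > 0.5:
                g.add_edge(a, b)
    expected = tuple(sorted(
        max(sorted(comp), key=lambda c: (counts[c], ))
        for comp in nx.connected_components(g)))
    assert kept == expected


def test_order_independence_and_tie_break():
    sim = _sim(["a", "b", "c"], [("a", "b", 0.9)])
    counts = {"a": 3, "b": 3, "c": 1}
    fwd = dedupe_by_similarity(["a", "b", "c"], sim, counts)
    rev = dedupe_by_similarity(["c", "b", "a"], sim, counts)
    assert fwd == rev == ("a", "c")  # tie a/b resolved to the smaller id


# ------------------------------------------------------- multilevel network

def test_minimal_chain_counts():
    g = build_multilevel({"P": ("h",)}, {"h": ("c",)}, [("c", "t")],
                         {"t": ("pw",)})
    assert g.number_of_nodes() == 5 and g.number_of_edges() == 4


def test_compound_in_two_herbs_single_node():
    g = build_multilevel({"P": ("h1", "h2")}, {"h1": ("c",), "h2": ("c",)},
                         [("c", "t")], {"t": ()})
    assert sum(1 for _, l in g.nodes(data="level") if l == "compound") == 1
    assert g.degree("c") == 3  # two herb edges plus one target edge


def test_nonadjacent_edge_rejected():
    g = build_multilevel({"P": ("h",)}, {"h": ("c",)}, [("c", "t")], {"t": ()})
    g.add_edge("P", "t")
    from synergyscreen.synergy import validate_multilevel
    with pytest.raises(DataError):
        validate_multilevel(g)


def test_distances_direct_and_indirect():
    """A direct compound-target edge has d = 1; a compound reaches a
    foreign target through a shared target and its compound in 3 hops."""
    g = build_multilevel({"P": ("h",)}, {"h": ("c1", "c2")},
                         [("c1", "t1"), ("c2", "t1"), ("c2", "t2")], {})
    d, D, N = network_distances(g, ["c1", "c2"], ["t1", "t2"],
                                screened_pairs=[("c1", "t1"), ("c2", "t1"),
                                                ("c2", "t2")])
    assert d[("c1", "t1")] == 1
    assert d[("c1", "t2")] == 3  # c1 - t1 - c2 - t2
    assert D["t2"] == 3 and D["t1"] == 1
    assert N["t1"] == 2 and N["t2"] == 1


def test_distances_match_bfs_oracle_on_random_multilevel():
    rng = np.random.default_rng(12)
    herbs = {f"h{i}": tuple(f"c{j}" for j in range(8) if rng.random() < 0.5)
             for i in range(3)}
    pairs = [(f"c{j}", f"t{k}") for j in range(8) for k in range(6)
             if rng.random() < 0.3]
    pairs += [("c0", "t0")]
    g = build_multilevel({"P": tuple(herbs)}, herbs, pairs, {})
    compounds = sorted({c for c, _ in pairs})
    targets = sorted({t for _, t in pairs})
    d, D, N = network_distances(g, compounds, targets, screened_pairs=pairs)
    for c in compounds:
        expected = nx.single_source_shortest_path_length(g, c)
        for t in targets:
            want = expected.get(t, math.inf)
            assert d[(c, t)] == want


# ------------------------------------------------------------- synergy score

def test_single_pair_hand_evaluation():
    """One compound, one direct target, A = -9: S = 9."""
    scores = synergy_scores([("c", "t")], {("c", "t"): -9.0},
                            {("c", "t"): 1.0}, {"t": 1.0}, {"t": 1})
    assert scores.loc[0, "S"] == pytest.approx(9.0)
    assert scores.loc[0, "m"] == 1


def test_score_linear_in_total_affinity():
    pairs = [("c", "t1"), ("c", "t2")]
    d = {("c", "t1"): 1.0, ("c", "t2"): 3.0}
    D = {"t1": 3.0, "t2": 3.0}
    N = {"t1": 2, "t2": 1}
    s1 = synergy_scores(pairs, {("c", "t1"): -8.5, ("c", "t2"): -9.0}, d, D, N)
    s2 = synergy_scores(pairs, {("c", "t1"): -17.0, ("c", "t2"): -18.0}, d, D, N)
    assert s2.loc[0, "S"] == pytest.approx(2 * s1.loc[0, "S"])


def test_score_decreases_with_distance():
    pairs = [("c", "t")]
    aff = {("c", "t"): -9.0}
    near = synergy_scores(pairs, aff, {("c", "t"): 1.0}, {"t": 3.0}, {"t": 1})
    far = synergy_scores(pairs, aff, {("c", "t"): 3.0}, {"t": 3.0}, {"t": 1})
    assert far.loc[0, "S"] < near.loc[0, "S"]


def test_scores_match_independent_reimplementation():
    """Six-compound instance: the pipeline scores equal a straight-line
    transcription of the formula evaluated per compound."""
    rng = np.random.default_rng(31)
    compounds = [f"c{i}" for i in range(6)]
    targets = [f"t{j}" for j in range(4)]
    pairs = [(c, t) for c in compounds for t in targets if rng.random() < 0.6]
    pairs += [(c, "t0") for c in compounds if not any(p[0] == c for p in pairs)]
    aff = {p: float(rng.uniform(-12, -8)) for p in pairs}
    herbs = {"h1": tuple(compounds[:3]), "h2": tuple(compounds[3:])}
    g = build_multilevel({"P": ("h1", "h2")}, herbs, pairs, {})
    d, D, N = network_distances(g, compounds, targets, screened_pairs=pairs)
    result = synergy_scores(pairs, aff, d, D, N)
    for row in result.itertuples(index=False):
        ts = [t for c, t in pairs if c == row.compound_id]
        m = len(ts)
        total_a = sum(aff[(row.compound_id, t)] for t in ts)
        control = 0.0
        for t in ts:
            dij = d[(row.compound_id, t)]
            control += (D[t] + 1 - dij) * N[t] / D[t]
        expected = abs(total_a) * control / (m * sum(d[(row.compound_id, t)]
                                                     for t in ts))
        assert row.S == pytest.approx(expected, rel=1e-12)
    # every screened compound scored exactly once
    assert sorted(result["compound_id"]) == sorted(compounds)


def test_missing_affinity_and_unreachable_pair_rejected():
    with pytest.raises(DataError, match="affinity"):
        synergy_scores([("c", "t")], {}, {("c", "t"): 1.0}, {"t": 1.0}, {"t": 1})
    with pytest.raises(DataError, match="unreachable"):
        synergy_scores([("c", "t")], {("c", "t"): -9.0},
                       {("c", "t"): math.inf}, {"t": 1.0}, {"t": 1})


def test_rank_candidates_top_k():
    scores = pd.DataFrame({"compound_id": list("abcdefg"),
                           "S": [7, 6, 5, 4, 3, 2, 1],
                           "m": [1] * 7, "targets": ["t"] * 7})
    ranked = rank_candidates(scores, top_k=5)
    assert list(ranked.loc[ranked["candidate"], "compound_id"]) == list("abcde")


# ---------------------------------------------------------------- vina logs

def test_parse_vina_log(tmp_path):
    log = tmp_path / "c1__t1.log"
    log.write_text(
        "Detected 8 CPUs\n"
        "mode |   affinity | dist from best mode\n"
        "     | (kcal/mol) | rmsd l.b.| rmsd u.b.\n"
        "-----+------------+----------+----------\n"
        "   1       -9.3      0.000      0.000\n"
        "   2       -8.1      1.922      3.104\n")
    assert parse_vina_log(log) == pytest.approx(-9.3)
    from synergyscreen import parse_vina_directory
    table = parse_vina_directory(tmp_path)
    assert table.loc[0, "compound_id"] == "c1"
    assert table.loc[0, "affinity"] == pytest.approx(-9.3)
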