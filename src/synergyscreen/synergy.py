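"""Docking-affinity screening and synergy scoring on a multilevel network.

The final ranking stage of the pipeline: keep compound-target pairs with
best-pose docking energy <= -8 kcal/mol, deduplicate structurally
redundant compounds (Tanimoto similarity strictly greater than 0.5,
keeping the compound with the most screened targets per similarity
component), build the typed prescription-herb-compound-target-pathway
network, and score each remaining compound as

    S_i = |sum_j A_ij| * sum_j[(D_j + 1 - d_ij) * N_j / D_j]
          / (m_i * sum_j d_ij)

where the sums run over compound i's m_i screened targets, A_ij is the
docking affinity (kcal/mol, negative), d_ij the unweighted shortest-path
distance between compound i and target j in the multilevel network, D_j
the maximum finite compound-to-target-j distance and N_j the number of
compounds with a screened edge to target j. The first factor is the
compound's aggregate binding ability; the bracket rewards proximity to
well-connected targets ((D_j + 1 - d_ij)/D_j lies in (0, 1]); the
denominator normalises by target count and distance burden. The grouping
is isolated in :func:`_score_formula` so alternative parses can be swapped.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .chem import SimilarityMatrix
from .errors import ConfigError, DataError

DEFAULT_AFFINITY_CUTOFF = -8.0   # kcal/mol, inclusive
DEFAULT_SIMILARITY_THRESHOLD = 0.5  # strict >
LEVELS = ("prescription", "herb", "compound", "target", "pathway")
_ADJACENT = {frozenset(p) for p in zip(LEVELS, LEVELS[1:])}


def screen_affinities(table: pd.DataFrame,
                      cutoff: float = DEFAULT_AFFINITY_CUTOFF) -> set[tuple[str, str]]:
    """Pairs with affinity <= cutoff (inclusive boundary)."""
    if table is None or len(table) == 0:
        raise DataError("screen_affinities: empty affinity table")
    if cutoff > 0:
        raise ConfigError(
            f"affinity cutoff {cutoff} is positive; docking energies are negative")
    if table["affinity"].isna().any():
        bad = table[table["affinity"].isna()]
        raise DataError(f"NaN affinity for {len(bad)} pairs, "
                        f"first: {bad.iloc[0]['compound_id']}")
    kept = table[table["affinity"] <= cutoff]
    return {(str(r.compound_id), str(r.target_id))
            for r in kept.itertuples(index=False)}


def dedupe_by_similarity(compounds, sim: SimilarityMatrix,
                         target_counts: dict[str, int],
                         threshold: float = DEFAULT_SIMILARITY_THRESHOLD) -> tuple[str, ...]:
    """Collapse structurally redundant compounds.

    Build a graph joining compound pairs with Tanimoto similarity
    strictly above ``threshold``; within each connected component keep
    the compound with the largest screened-target count (ties broken by
    ascending compound id). Compounds without any such neighbour are all
    retained.
    """
    compounds = list(compounds)
    missing = [c for c in compounds if c not in sim.ids]
    if missing:
        raise DataError(f"similarity matrix lacks compounds {missing[:5]}")
    g = nx.Graph()
    g.add_nodes_from(compounds)
    idx = {c: sim.ids.index(c) for c in compounds}
    for i, a in enumerate(compounds):
        for b in compounds[i + 1:]:
            if sim.values[idx[a], idx[b]] > threshold:
                g.add_edge(a, b)
    kept = []
    for component in nx.connected_components(g):
        best = sorted(component, key=lambda c: (-target_counts.get(c, 0), c))[0]
        kept.append(best)
    return tuple(sorted(kept))


def build_multilevel(prescription_herbs: dict[str, tuple],
                     herb_compounds: dict[str, tuple],
                     screened_pairs, target_pathways: dict[str, tuple]) -> nx.Graph:
    """Typed five-level network; edges join adjacent levels only.

    Parameters map each level onto the next: prescription -> herbs,
    herb -> compounds, screened (compound, target) pairs, and
    target -> pathways.
    """
    g = nx.Graph()

    def add(node, level):
        if node in g and g.nodes[node]["level"] != level:
            raise DataError(f"node {node} assigned to two levels")
        g.add_node(node, level=level)

    for p, herbs in prescription_herbs.items():
        add(p, "prescription")
        for h in herbs:
            add(h, "herb")
            g.add_edge(p, h)
    for h, comps in herb_compounds.items():
        add(h, "herb")
        for c in comps:
            add(c, "compound")
            g.add_edge(h, c)
    for c, t in screened_pairs:
        add(c, "compound")
        add(t, "target")
        g.add_edge(c, t)
    for t, paths in target_pathways.items():
        add(t, "target")
        for pw in paths:
            add(pw, "pathway")
            g.add_edge(t, pw)
    validate_multilevel(g)
    return g


def validate_multilevel(g: nx.Graph):
    """Every edge must join two adjacent levels."""
    for u, v in g.edges:
        pair = frozenset((g.nodes[u]["level"], g.nodes[v]["level"]))
        if pair not in _ADJACENT:
            raise DataError(f"edge ({u}, {v}) joins non-adjacent levels {sorted(pair)}")


def network_distances(g: nx.Graph, compounds, targets,
                      screened_pairs=None):
    """Distances d_ij, per-target maxima D_j and screened degrees N_j.

    d_ij is the unweighted shortest-path length from compound i to
    target j in the multilevel network; D_j the maximum finite d_ij over
    the given compounds; N_j the number of screened compound-target
    edges at j (falling back to compound-neighbour count in ``g`` when
    ``screened_pairs`` is not given).
    """
    compounds, targets = list(compounds), list(targets)
    d: dict[tuple[str, str], float] = {}
    for c in compounds:
        lengths = nx.single_source_shortest_path_length(g, c)
        for t in targets:
            d[(c, t)] = float(lengths.get(t, math.inf))
    D = {}
    for t in targets:
        finite = [d[(c, t)] for c in compounds if math.isfinite(d[(c, t)])]
        D[t] = max(finite) if finite else math.inf
    if screened_pairs is not None:
        pairs = set(screened_pairs)
        N = {t: sum(1 for c in compounds if (c, t) in pairs) for t in targets}
    else:
        N = {t: sum(1 for u in g.neighbors(t)
                    if g.nodes[u]["level"] == "compound") for t in targets}
    return d, D, N


def _score_formula(affinities: list[float], d: list[float], D: list[float],
                   N: list[int]) -> float:
    """Canonical grouping of the synergy score (see module docstring)."""
    m = len(affinities)
    binding = abs(sum(affinities))
    control = sum((Dj + 1 - dj) * Nj / Dj for dj, Dj, Nj in zip(d, D, N))
    return binding * control / (m * sum(d))


@dataclass(frozen=True)
class SynergyScore:
    compound_id: str
    S: float
    m: int
    targets: tuple[str, ...]


def synergy_scores(screened_pairs, affinities: dict[tuple[str, str], float],
                   distances, D: dict[str, float], N: dict[str, int],
                   compounds=None) -> pd.DataFrame:
    """Score every compound with at least one screened target.

    Returns a DataFrame sorted by descending S (ties by compound id)
    with columns ``compound_id``, ``S``, ``m`` and ``targets``.
    """
    pairs = sorted(set(screened_pairs))
    per_compound: dict[str, list[str]] = {}
    for c, t in pairs:
        per_compound.setdefault(c, []).append(t)
    if compounds is not None:
        per_compound = {c: ts for c, ts in per_compound.items()
                        if c in set(compounds)}
    if not per_compound:
        raise DataError("synergy_scores: no screened pairs")
    rows = []
    for c, ts in sorted(per_compound.items()):
        a, dd, DD, NN = [], [], [], []
        for t in ts:
            if (c, t) not in affinities:
                raise DataError(f"missing affinity for screened pair ({c}, {t})")
            dij = distances[(c, t)]
            if not math.isfinite(dij):
                raise DataError(f"pair ({c}, {t}) is unreachable in the network")
            a.append(affinities[(c, t)])
            dd.append(dij)
            DD.append(D[t])
            NN.append(N[t])
        rows.append({"compound_id": c, "S": _score_formula(a, dd, DD, NN),
                     "m": len(ts), "targets": ",".join(ts)})
    out = pd.DataFrame(rows).sort_values(["S", "compound_id"],
                                         ascending=[False, True])
    return out.reset_index(drop=True)


def rank_candidates(scores: pd.DataFrame, top_k: int = 5) -> pd.DataFrame:
    """Flag the top_k compounds by synergy score as candidates."""
    out = scores.copy()
    out["candidate"] = False
    out.loc[out.index[:top_k], "candidate"] = True
    return out


_VINA_RESULT = re.compile(r"^\s*1\s+(-?\d+(?:\.\d+)?)\s")


def parse_vina_log(path: str | Path) -> float:
    """Extract the top-mode affinity (kcal/mol) from a docking log file.

    Tolerant of header variations: takes the first table row whose mode
    number is 1 after a line starting with ``mode`` or ``-----``.
    """
    in_table = False
    for line in Path(path).read_text().splitlines():
        low = line.strip().lower()
        if low.startswith("mode") or set(low) <= {"-", "+", "|", " "} and "-" in low:
            in_table = True
            continue
        if in_table:
            m = _VINA_RESULT.match(line)
            if m:
                return float(m.group(1))
    raise DataError(f"no top-mode affinity found in {path}")


def parse_vina_directory(directory: str | Path) -> pd.DataFrame:
    """Parse a directory of ``<compound>__<target>.log`` docking logs."""
    rows = []
    for path in sorted(Path(directory).glob("*.log")):
        stem = path.stem
        if "__" not in stem:
            raise DataError(f"log file {path.name} is not named <compound>__<target>.log")
        cid, tid = stem.split("__", 1)
        rows.append({"compound_id": cid, "target_id": tid,
                     "affinity": parse_vina_log(path)})
    if not rows:
        raise DataError(f"no .log files in {directory}")
    return pd.DataFrame(rows)
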