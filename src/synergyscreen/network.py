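"""Per-prescription compound-target (C-T) networks and pathological genes.

Targets predicted by several servers are unioned per compound; each
prescription's bipartite C-T network is built from its herb membership.
The pathological gene set is defined as the disease-portal list
(GeneCards-style) intersected with the union of the three curated
sources (Integrity, TTD, DisGeNet-style).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError, MembershipError, ParseError

log = logging.getLogger(__name__)


@dataclass
class CTNetwork:
    """Bipartite compound-target network of one prescription."""

    prescription_id: str
    compounds: tuple[str, ...]
    targets: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    herb_membership: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.compounds or not self.targets:
            raise DataError("CTNetwork needs at least one compound and one target")
        cset, tset = set(self.compounds), set(self.targets)
        for c, t in self.edges:
            if c not in cset or t not in tset:
                raise DataError(f"edge ({c}, {t}) has an endpoint outside the node lists")

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree_of(self, compound: str) -> int:
        return sum(1 for c, _ in self.edges if c == compound)

    def to_matrix(self) -> np.ndarray:
        """Binary n x m matrix T with T[i, j] = 1 iff compound i targets j."""
        tindex = {t: j for j, t in enumerate(self.targets)}
        cindex = {c: i for i, c in enumerate(self.compounds)}
        T = np.zeros((self.n_compounds, self.n_targets))
        for c, t in self.edges:
            T[cindex[c], tindex[t]] = 1.0
        return T

    @classmethod
    def from_matrix(cls, prescription_id, compounds, targets, T,
                    herb_membership=None) -> "CTNetwork":
        T = np.asarray(T)
        edges = frozenset(
            (compounds[i], targets[j]) for i, j in zip(*np.nonzero(T)))
        return cls(prescription_id, tuple(compounds), tuple(targets), edges,
                   herb_membership or {})

    def subnetwork(self, keep_compounds) -> "CTNetwork":
        """Induced subnetwork on the given compounds; targets keep >=1 edge."""
        keep = [c for c in self.compounds if c in set(keep_compounds)]
        edges = frozenset((c, t) for c, t in self.edges if c in set(keep))
        targets = tuple(t for t in self.targets if any(c_t[1] == t for c_t in edges))
        return CTNetwork(self.prescription_id, tuple(keep), targets, edges,
                         {c: h for c, h in self.herb_membership.items() if c in set(keep)})

    def to_graph(self) -> nx.Graph:
        """Undirected bipartite graph with ``partition`` node attributes."""
        g = nx.Graph()
        g.add_nodes_from(self.compounds, partition="compound")
        g.add_nodes_from(self.targets, partition="target")
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class PathologicalGeneSet:
    """Disease-associated genes with per-source provenance."""

    genes: frozenset[str]
    provenance: dict[str, frozenset[str]]

    def __len__(self):
        return len(self.genes)


def _normalize(symbols) -> set[str]:
    return {str(s).strip().upper() for s in symbols if str(s).strip()}


def union_predictions(tables: dict[str, pd.DataFrame],
                      compound_column: str = "compound_id",
                      target_column: str = "target_id") -> dict[str, set[str]]:
    """Union the per-server prediction tables into per-compound target sets.

    Target symbols are upper-cased before set operations (prediction
    servers disagree on casing). Compounds present in any table with no
    valid target rows are retained with empty sets and logged.
    """
    if not tables:
        raise DataError("union_predictions: no prediction tables given")
    result: dict[str, set[str]] = {}
    for name, table in tables.items():
        for col in (compound_column, target_column):
            if col not in table.columns:
                raise ParseError(f"table {name!r} lacks column {col!r}")
        for lineno, row in enumerate(table.itertuples(index=False), start=2):
            raw_cid = getattr(row, compound_column)
            raw_tid = getattr(row, target_column)
            cid = "" if pd.isna(raw_cid) else str(raw_cid).strip()
            if not cid:
                raise ParseError(f"table {name!r}: empty compound id", line=lineno)
            result.setdefault(cid, set())
            if not pd.isna(raw_tid) and str(raw_tid).strip():
                result[cid].add(str(raw_tid).strip().upper())
    empty = sorted(c for c, ts in result.items() if not ts)
    if empty:
        log.info("union_predictions: %d compounds with zero predicted targets: %s",
                 len(empty), ", ".join(empty[:10]))
    return result


def build_network(prescription_id: str,
                  herb_membership: dict[str, tuple[str, ...]],
                  target_sets: dict[str, set[str]]) -> CTNetwork:
    """Assemble the bipartite C-T network of one prescription.

    Parameters
    ----------
    herb_membership:
        compound -> herbs of this prescription containing it. Every
        compound must map to at least one herb; compounds occurring in
        several herbs appear once.
    target_sets:
        per-compound predicted target sets (already unioned). Compounds
        with zero targets stay in the compound list but contribute no
        edges (their score would be zero regardless); they are excluded
        from matrices implicitly by their zero row.
    """
    compounds = tuple(sorted(herb_membership))
    if not compounds:
        raise DataError(f"prescription {prescription_id}: no compounds")
    for c in compounds:
        if not herb_membership[c]:
            raise MembershipError(
                f"compound {c} belongs to no herb of prescription {prescription_id}")
    missing = [c for c in compounds if c not in target_sets]
    if missing:
        raise DataError(
            f"prescription {prescription_id}: no prediction entry for {missing[:5]}")
    edges = frozenset(
        (c, t) for c in compounds for t in target_sets[c])
    targets = tuple(sorted({t for _, t in edges}))
    if not targets:
        raise DataError(f"prescription {prescription_id}: network has no targets")
    return CTNetwork(prescription_id, compounds, targets, edges,
                     {c: tuple(herb_membership[c]) for c in compounds})


def pathological_genes(genecards, integrity, ttd, disgenet) -> PathologicalGeneSet:
    """GeneCards ∩ (Integrity ∪ TTD ∪ DisGeNet), case-normalized."""
    gc = _normalize(genecards)
    if not gc:
        raise DataError("pathological_genes: empty GeneCards list")
    sources = {
        "genecards": frozenset(gc),
        "integrity": frozenset(_normalize(integrity)),
        "ttd": frozenset(_normalize(ttd)),
        "disgenet": frozenset(_normalize(disgenet)),
    }
    union = sources["integrity"] | sources["ttd"] | sources["disgenet"]
    return PathologicalGeneSet(frozenset(gc & union), sources)
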