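"""End-to-end orchestration: simulate -> ADMET -> networks -> collaborative
filter -> comparison -> enrichment -> docking screen -> synergy ranking.

Every stage writes its outputs under the configured directory and
contributes counts to a machine-readable :class:`RunSummary`. Stage
failures propagate with the stage name and leave a ``FAILED`` marker
next to any partial outputs.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .admet import screen_table
from .chem import similarity_matrix
from .collab import retain_top_half, collab_scores
from .compare import (compare_topology, retention_report, shared_fraction,
                      topology_profile)
from .config import PipelineConfig
from .enrich import hypergeom_enrich, shared_significant_sets
from .errors import DataError, SynergyScreenError
from .io import write_inputs, write_network
from .network import build_network, pathological_genes, union_predictions
from .synergy import (build_multilevel, dedupe_by_similarity, network_distances,
                      rank_candidates, screen_affinities, synergy_scores)
from .synthetic import generate_affinities, generate_inputs

log = logging.getLogger(__name__)

GO_BRANCHES = ("GOBP", "GOCC", "GOMF")
PATHWAY_CATEGORY = "KEGG"


@dataclass
class RunSummary:
    """Per-stage counts and outputs of one pipeline run."""

    seed: int
    version: str = __version__
    counts: dict = field(default_factory=dict)
    prescriptions: dict = field(default_factory=dict)
    shared: dict = field(default_factory=dict)
    candidates: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"seed": self.seed, "version": self.version,
                "counts": self.counts, "prescriptions": self.prescriptions,
                "shared": self.shared, "candidates": self.candidates,
                "outputs": self.outputs}

    def write(self, path):
        Path(path).write_text(json.dumps(self.as_dict(), indent=2, sort_keys=True))


@contextmanager
def _stage(name: str, out_dir: Path):
    log.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"{name}: {exc}\n")
        raise SynergyScreenError(f"stage {name!r} failed: {exc}") from exc
    log.info("stage %s: done", name)


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Run the full pipeline on synthetic inputs; returns the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(seed=config.seed)

    with _stage("simulate", out):
        inputs = generate_inputs(config.synth)
        summary.outputs.update(write_inputs(inputs, out / "inputs"))
        summary.counts["compounds_total"] = int(len(inputs.compounds))

    with _stage("admet", out):
        passing, verdicts = screen_table(inputs.compounds,
                                         policy=config.missing_policy,
                                         thresholds=config.admet_thresholds)
        verdicts.to_csv(out / "verdicts.tsv", sep="\t", index=False)
        summary.outputs["verdicts"] = str(out / "verdicts.tsv")
        summary.counts["compounds_active"] = len(passing)

    with _stage("network", out):
        target_sets = union_predictions(inputs.predictions)
        smiles_of = dict(zip(inputs.compounds["compound_id"],
                             inputs.compounds["smiles"]))
        patho = pathological_genes(*(inputs.genes.source_lists[s] for s in
                                     ("genecards", "integrity", "ttd", "disgenet")))
        summary.counts["pathological_genes"] = len(patho)
        originals: dict[str, object] = {}
        for pid, grp in inputs.membership.groupby("prescription_id"):
            active = grp[grp["compound_id"].isin(passing)]
            herb_map: dict[str, tuple] = {}
            for row in active.itertuples(index=False):
                herb_map.setdefault(row.compound_id, set()).add(row.herb_id)
            herb_map = {c: tuple(sorted(h)) for c, h in herb_map.items()}
            if not herb_map:
                raise DataError(f"prescription {pid}: no active compounds")
            originals[pid] = build_network(pid, herb_map, target_sets)

    with _stage("collab_filter", out):
        filtered, sims = {}, {}
        for pid, net in originals.items():
            sim = similarity_matrix({c: smiles_of[c] for c in net.compounds},
                                    n_bits=config.fingerprint_bits,
                                    radius=config.fingerprint_radius)
            sims[pid] = sim
            scores = collab_scores(sim, net.to_matrix())
            result = retain_top_half(scores, net,
                                     fraction=config.retention_fraction)
            filtered[pid] = result.retained_network
            table = pd.DataFrame({
                "compound_id": net.compounds,
                "s": [scores[c] for c in net.compounds],
                "retained": [c in set(result.retained_compounds)
                             for c in net.compounds]})
            table.to_csv(out / f"scores_{pid}.tsv", sep="\t", index=False)
            write_network(result.retained_network,
                          out / f"network_{pid}_filtered.tsv",
                          out / f"network_{pid}_filtered.graphml")
            write_network(net, out / f"network_{pid}_original.tsv")

    with _stage("enrichment", out):
        universe = inputs.genes.universe
        by_category: dict[str, dict] = {}
        for set_id, genes in inputs.genes.gene_sets.items():
            cat = inputs.genes.set_categories[set_id]
            by_category.setdefault(cat, {})[set_id] = genes
        enrich = {}  # (pid, which) -> {category: result}
        for pid in originals:
            for which, net in (("original", originals[pid]),
                               ("filtered", filtered[pid])):
                per_cat = {}
                for cat, sets in by_category.items():
                    per_cat[cat] = hypergeom_enrich(
                        net.targets, sets, universe,
                        min_set_size=config.min_set_size,
                        fdr_level=config.fdr_level)
                enrich[(pid, which)] = per_cat
                combined = pd.concat(
                    [df.assign(category=cat) for cat, df in per_cat.items()],
                    ignore_index=True)
                combined.to_csv(out / f"enrichment_{pid}_{which}.tsv",
                                sep="\t", index=False)

    with _stage("compare", out):
        topo_rows, comp_rows = [], []
        for pid in originals:
            prof_o = topology_profile(originals[pid])
            prof_f = topology_profile(filtered[pid])
            topo_rows.append(prof_o.assign(prescription=pid, network="original",
                                           node=prof_o.index))
            topo_rows.append(prof_f.assign(prescription=pid, network="filtered",
                                           node=prof_f.index))
            comp = compare_topology(prof_o, prof_f, by_partition=True)
            comp_rows.append(comp.assign(prescription=pid))
            report = retention_report(
                originals[pid], filtered[pid], patho,
                enrich_orig={b: enrich[(pid, "original")][b] for b in GO_BRANCHES},
                enrich_filt={b: enrich[(pid, "filtered")][b] for b in GO_BRANCHES},
                alpha=config.fdr_level)
            summary.prescriptions[pid] = {
                "original": {"compounds": originals[pid].n_compounds,
                             "targets": originals[pid].n_targets,
                             "edges": originals[pid].n_edges},
                "filtered": {"compounds": filtered[pid].n_compounds,
                             "targets": filtered[pid].n_targets,
                             "edges": filtered[pid].n_edges},
                "retention": report.as_dict(),
            }
        pd.concat(topo_rows, ignore_index=True).to_csv(
            out / "topology.tsv", sep="\t", index=False)
        pd.concat(comp_rows, ignore_index=True).to_csv(
            out / "comparison.tsv", sep="\t", index=False)
        for what in ("compounds", "targets"):
            summary.shared[what] = {
                "original": shared_fraction(list(originals.values()), what),
                "filtered": shared_fraction(list(filtered.values()), what)}

    with _stage("pathways", out):
        pathway_results_filt = [
            enrich[(pid, "filtered")][PATHWAY_CATEGORY] for pid in originals]
        shared_paths = shared_significant_sets(pathway_results_filt,
                                               alpha=config.fdr_level)
        summary.counts["shared_pathways"] = len(shared_paths)
        if config.curated_pathways:
            curated = [p for p in config.curated_pathways
                       if p in inputs.genes.gene_sets]
        else:
            # rank shared pathways by mean q across prescriptions
            mean_q = {}
            for p in shared_paths:
                qs = [float(df.loc[df["set_id"] == p, "q"].iloc[0])
                      for df in pathway_results_filt]
                mean_q[p] = sum(qs) / len(qs)
            curated = sorted(shared_paths,
                             key=lambda p: (mean_q[p], p))[:config.n_curated_pathways]
        if not curated:
            raise DataError("no shared significant pathways to carry forward")
        summary.counts["curated_pathways"] = len(curated)
        summary.shared["curated_pathway_ids"] = sorted(curated)
        pathway_genes = {p: set(inputs.genes.gene_sets[p]) for p in curated}
        all_path_genes = set().union(*pathway_genes.values())
        filtered_targets = set().union(*(set(f.targets) for f in filtered.values()))
        pathway_targets = sorted(filtered_targets & all_path_genes)
        summary.counts["pathway_targets"] = len(pathway_targets)
        if not pathway_targets:
            raise DataError("no filtered targets fall in the curated pathways")

    with _stage("docking_screen", out):
        pairs = sorted({(c, t) for f in filtered.values() for c, t in f.edges
                        if t in set(pathway_targets)})
        summary.counts["docking_pairs"] = len(pairs)
        affinities = generate_affinities(pairs, config.synth)
        affinities.to_csv(out / "affinities.tsv", sep="\t", index=False)
        summary.outputs["affinities"] = str(out / "affinities.tsv")
        screened = screen_affinities(affinities, cutoff=config.affinity_cutoff)
        if not screened:
            raise DataError("no screened pairs at the affinity cutoff")
        summary.counts["screened_pairs"] = len(screened)

    with _stage("synergy", out):
        screened_compounds = sorted({c for c, _ in screened})
        target_counts = {c: sum(1 for cc, _ in screened if cc == c)
                         for c in screened_compounds}
        sim_all = similarity_matrix(
            {c: smiles_of[c] for c in screened_compounds},
            n_bits=config.fingerprint_bits, radius=config.fingerprint_radius)
        kept = dedupe_by_similarity(screened_compounds, sim_all, target_counts,
                                    threshold=config.similarity_threshold)
        summary.counts["screened_compounds"] = len(screened_compounds)
        summary.counts["deduplicated_compounds"] = len(kept)
        kept_pairs = sorted((c, t) for c, t in screened if c in set(kept))
        kept_targets = sorted({t for _, t in kept_pairs})

        prescription_herbs, herb_compounds = {}, {}
        for pid in originals:
            herbs = set()
            for c in kept:
                for h in filtered[pid].herb_membership.get(c, ()):
                    herbs.add(h)
                    herb_compounds.setdefault(h, set()).add(c)
            if herbs:
                prescription_herbs[pid] = tuple(sorted(herbs))
        herb_compounds = {h: tuple(sorted(cs)) for h, cs in herb_compounds.items()}
        target_pathways = {
            t: tuple(sorted(p for p in curated if t in pathway_genes[p]))
            for t in kept_targets}
        multilevel = build_multilevel(prescription_herbs, herb_compounds,
                                      kept_pairs, target_pathways)
        nx.write_graphml(multilevel, out / "multilevel.graphml")
        summary.counts["multilevel_nodes"] = {
            level: sum(1 for _, l in multilevel.nodes(data="level") if l == level)
            for level in ("prescription", "herb", "compound", "target", "pathway")}
        summary.counts["multilevel_edges"] = multilevel.number_of_edges()

        aff_map = {(str(r.compound_id), str(r.target_id)): float(r.affinity)
                   for r in affinities.itertuples(index=False)}
        d, D, N = network_distances(multilevel, kept, kept_targets,
                                    screened_pairs=kept_pairs)
        scores = synergy_scores(kept_pairs, aff_map, d, D, N)
        ranking = rank_candidates(scores, top_k=config.top_k)
        ranking.to_csv(out / "ranking.tsv", sep="\t", index=False)
        summary.outputs["ranking"] = str(out / "ranking.tsv")
        summary.candidates = [
            {"compound_id": r.compound_id, "S": round(float(r.S), 6),
             "m": int(r.m)}
            for r in ranking[ranking["candidate"]].itertuples(index=False)]

    summary.write(out / "summary.json")
    summary.outputs["summary"] = str(out / "summary.json")
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return summary
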