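"""Readers and writers for the pipeline's on-disk formats.

All interchange formats are plain text: CSV for the compound property
table, TSV for memberships/predictions/affinities/edge lists, one gene
per line for gene lists, standard GMT for gene sets, and GraphML for
network exports.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import DataError
from .network import CTNetwork
from .synthetic import GENE_SOURCES, SERVER_NAMES, SyntheticInputs


def read_compounds(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"compound_id", "MW", "Hdon", "Hacc", "AlogP", "RBN",
                "OB", "DL", "BBB", "Caco2", "TPSA"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"compound table {path} lacks columns {sorted(missing)}")
    return df


def read_membership(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"prescription_id", "herb_id", "compound_id"} - set(df.columns)
    if missing:
        raise DataError(f"membership table {path} lacks columns {sorted(missing)}")
    return df


def read_prediction_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]


def write_gene_list(genes, path):
    Path(path).write_text("\n".join(genes) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Standard GMT: id <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    from gseapy.parser import read_gmt as _read_gmt  # heavy import, deferred
    return _read_gmt(str(path))


def write_gmt(gene_sets: dict, path, descriptions: dict | None = None):
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for set_id, genes in gene_sets.items():
            desc = descriptions.get(set_id, "na")
            fh.write("\t".join([set_id, desc, *genes]) + "\n")


def read_affinities(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"compound_id", "target_id", "affinity"} - set(df.columns)
    if missing:
        raise DataError(f"affinity table {path} lacks columns {sorted(missing)}")
    return df


def write_network(net: CTNetwork, edge_path, graphml_path=None):
    """Edge list TSV (+ optional GraphML with herb/prescription attributes)."""
    edges = pd.DataFrame(sorted(net.edges), columns=["compound_id", "target_id"])
    edges.to_csv(edge_path, sep="\t", index=False)
    if graphml_path:
        g = net.to_graph()
        for c, herbs in net.herb_membership.items():
            g.nodes[c]["herbs"] = ";".join(herbs)
            g.nodes[c]["prescription"] = net.prescription_id
        nx.write_graphml(g, graphml_path)


def write_inputs(inputs: SyntheticInputs, out_dir) -> dict[str, str]:
    """Write every generated input under ``out_dir``; returns path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def record(key, name):
        paths[key] = str(out / name)
        return out / name

    inputs.compounds.to_csv(record("compounds", "compounds.csv"), index=False)
    inputs.membership.to_csv(record("membership", "herb_membership.tsv"),
                             sep="\t", index=False)
    for server in SERVER_NAMES:
        inputs.predictions[server].to_csv(
            record(f"predictions_{server}", f"predictions_{server}.tsv"),
            sep="\t", index=False)
    for source in GENE_SOURCES:
        write_gene_list(inputs.genes.source_lists[source],
                        record(f"genes_{source}", f"genes_{source}.txt"))
    write_gmt(inputs.genes.gene_sets, record("genesets", "genesets.gmt"),
              descriptions=inputs.genes.set_categories)
    return paths
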