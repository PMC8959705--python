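"""Seeded synthetic stand-ins for every external input of the pipeline.

The generator emulates, at realistic scale, the data a multi-prescription
network-pharmacology study pulls from external services: a compound
property export (structures plus ADMET fields), herb/prescription
membership, three overlapping compound-target prediction tables, four
disease-gene source lists, GO/pathway gene sets in GMT form, and docking
affinities. Everything is driven by a single root seed through
independent per-generator substreams, so adding one generator never
perturbs the output of another.

Identifiers are synthetic (``C0001`` compounds, ``G000123`` gene/target
symbols, ``H03`` herbs, ``RX1`` prescriptions); no claim is made to any
real gene or compound identity. Targets are drawn from the head of the
gene-symbol universe so that target sets, pathological genes and gene
sets overlap the way protein-coding disease genes do in real data.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from ._smiles import DRUGLIKE_SMILES
from .config import SynthConfig
from .errors import ConfigError, DataError

# substream tags: one per generator
_STREAM_STRUCTURE = 1
_STREAM_PROPS = 2
_STREAM_PREDICT = 3
_STREAM_GENES = 4
_STREAM_AFFINITY = 5

SERVER_NAMES = ("sea", "hitpick", "targetnet")
GENE_SOURCES = ("genecards", "integrity", "ttd", "disgenet")
SET_CATEGORIES = ("GOBP", "GOCC", "GOMF", "KEGG")

#: truncated-normal parameters (mean, sd, lo, hi) for the sampled ADMET
#: fields, centred near the screening thresholds so the screen is
#: discriminative by construction.
_SAMPLED_PASS = {
    "OB": (45.0, 15.0, 30.0, 100.0),
    "DL": (0.30, 0.15, 0.10, 1.0),
    "BBB": (0.80, 0.40, 0.30, 3.0),
    "Caco2": (0.90, 0.40, 0.40, 2.5),
    "TPSA": (45.0, 12.0, 0.0, 60.0),
}
_SAMPLED_FAIL = {
    "OB": (20.0, 8.0, 0.0, 29.9),
    "DL": (0.05, 0.03, 0.0, 0.099),
    "BBB": (0.0, 0.20, -1.0, 0.299),
    "Caco2": (0.10, 0.20, -1.0, 0.399),
    "TPSA": (85.0, 20.0, 60.1, 200.0),
}


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _truncnorm(rng, mean, sd, lo, hi) -> float:
    """Rejection-sampled truncated normal (bounds are a few sd wide here)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def gene_symbol(i: int) -> str:
    return f"G{i + 1:06d}"


def computed_properties(smiles: str) -> dict[str, float]:
    """Structure-derived ADMET fields: MW, Hdon, Hacc, AlogP, RBN."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DataError(f"library SMILES failed to parse: {smiles!r}")
    return {
        "MW": round(Descriptors.MolWt(mol), 2),
        "Hdon": float(Lipinski.NumHDonors(mol)),
        "Hacc": float(Lipinski.NumHAcceptors(mol)),
        "AlogP": round(Crippen.MolLogP(mol), 3),
        "RBN": float(rdMolDescriptors.CalcNumRotatableBonds(mol)),
    }


def _lipinski_ok(props: dict[str, float]) -> bool:
    return (props["MW"] <= 500 and props["Hdon"] <= 5 and props["Hacc"] <= 10
            and props["AlogP"] <= 5 and props["RBN"] <= 10)


@functools.lru_cache(maxsize=1)
def _library() -> tuple[tuple[str, bool], ...]:
    """(smiles, passes computed Lipinski-style criteria) per library entry."""
    return tuple(
        (smi, _lipinski_ok(computed_properties(smi))) for smi in DRUGLIKE_SMILES)


_DECORATIONS = ("F", "Cl", "C", "O")


def _decorate(smiles: str, rng) -> str:
    """Attach 1-2 small substituents at random H-bearing carbons."""
    mol = Chem.MolFromSmiles(smiles)
    rw = Chem.RWMol(mol)
    n_subs = int(rng.integers(1, 3))
    for _ in range(n_subs):
        rw.UpdatePropertyCache(strict=False)
        candidates = [a.GetIdx() for a in rw.GetAtoms()
                      if a.GetSymbol() == "C" and a.GetTotalNumHs() > 0]
        if not candidates:
            break
        idx = int(rng.choice(candidates))
        new = rw.AddAtom(Chem.Atom(str(rng.choice(_DECORATIONS))))
        rw.AddBond(idx, new, Chem.BondType.SINGLE)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return smiles
    return Chem.MolToSmiles(out)


@dataclass
class GeneResources:
    """Four disease-gene source lists plus GMT-style annotation sets."""

    source_lists: dict[str, tuple[str, ...]]
    gene_sets: dict[str, tuple[str, ...]]
    set_categories: dict[str, str]
    universe: tuple[str, ...]


@dataclass
class SyntheticInputs:
    """Bundle of every generated pipeline input."""

    config: SynthConfig
    compounds: pd.DataFrame
    membership: pd.DataFrame
    predictions: dict[str, pd.DataFrame]
    genes: GeneResources
    target_universe: tuple[str, ...] = field(default_factory=tuple)


def _build_membership(config: SynthConfig, rng) -> pd.DataFrame:
    """Prescription -> herb -> compound-slot skeleton.

    Some herbs come from a pool shared between prescriptions (like the
    harmonising herbs reused across classical formulas); their compounds
    are therefore shared too.
    """
    lo_h, hi_h = config.herbs_per_prescription
    n_shared_pool = max(1, int(round(config.shared_herb_fraction * hi_h)))
    shared_pool = [f"HS{i + 1:02d}" for i in range(n_shared_pool)]
    rows = []
    herb_counter = 0
    for p in range(config.n_prescriptions):
        pid = f"RX{p + 1}"
        n_herbs = int(rng.integers(lo_h, hi_h + 1))
        n_shared = min(len(shared_pool),
                       int(round(config.shared_herb_fraction * n_herbs)))
        herbs = list(rng.choice(shared_pool, size=n_shared, replace=False))
        for _ in range(n_herbs - n_shared):
            herb_counter += 1
            herbs.append(f"H{herb_counter:02d}")
        for h in herbs:
            rows.append({"prescription_id": pid, "herb_id": h})
    return pd.DataFrame(rows)


def generate_compound_table(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the compound property table and herb membership table.

    Returns
    -------
    compounds:
        One row per unique compound: ``compound_id``, ``smiles``, the ten
        ADMET fields, and a ``literature`` bypass flag (all False here;
        the flag exists for user-supplied curated compounds). A fraction
        ``admet_pass_fraction`` of compounds is constructed to pass the
        full ten-criterion screen.
    membership:
        Long table ``prescription_id, herb_id, compound_id``.
    """
    rng_struct = _rng(config, _STREAM_STRUCTURE)
    rng_props = _rng(config, _STREAM_PROPS)
    skeleton = _build_membership(config, rng_struct)
    herbs = sorted(skeleton["herb_id"].unique())
    lo_c, hi_c = config.compounds_per_herb
    herb_sizes = {h: int(rng_struct.integers(lo_c, hi_c + 1)) for h in herbs}
    if config.n_compounds is not None:
        # exact total: distribute compounds over herbs round-robin
        n = config.n_compounds
        herb_sizes = {h: 0 for h in herbs}
        for i in range(n):
            herb_sizes[herbs[i % len(herbs)]] += 1
    n_total = sum(herb_sizes.values())
    if n_total == 0:
        raise ConfigError("configuration yields zero compounds")

    library = _library()
    passing_idx = [i for i, (_, ok) in enumerate(library) if ok]
    records, member_rows = [], []
    counter = 0
    for h in herbs:
        for _ in range(herb_sizes[h]):
            counter += 1
            cid = f"C{counter:04d}"
            should_pass = bool(rng_props.random() < config.admet_pass_fraction)
            if should_pass:
                smi, props = None, None
                for _ in range(8):
                    base = library[int(rng_props.choice(passing_idx))][0]
                    cand = _decorate(base, rng_props) if rng_props.random() < 0.5 else base
                    p = computed_properties(cand)
                    if _lipinski_ok(p):
                        smi, props = cand, p
                        break
                if smi is None:  # decoration kept pushing it out; use base
                    smi = library[int(rng_props.choice(passing_idx))][0]
                    props = computed_properties(smi)
                sampled = {k: _truncnorm(rng_props, *v) for k, v in _SAMPLED_PASS.items()}
            else:
                base = library[int(rng_props.integers(len(library)))][0]
                smi = _decorate(base, rng_props) if rng_props.random() < 0.5 else base
                props = computed_properties(smi)
                # force at least one sampled criterion into its failing range
                fields = list(_SAMPLED_PASS)
                n_fail = int(rng_props.integers(1, len(fields) + 1))
                failing = set(rng_props.choice(fields, size=n_fail, replace=False))
                sampled = {
                    k: _truncnorm(rng_props, *(_SAMPLED_FAIL[k] if k in failing
                                               else _SAMPLED_PASS[k]))
                    for k in fields}
            records.append({
                "compound_id": cid, "smiles": smi, **props,
                "OB": round(sampled["OB"], 2), "DL": round(sampled["DL"], 3),
                "BBB": round(sampled["BBB"], 3), "Caco2": round(sampled["Caco2"], 3),
                "TPSA": round(sampled["TPSA"], 2), "literature": False,
            })
            member_rows.append({"herb_id": h, "compound_id": cid})
    compounds = pd.DataFrame(records)
    members = pd.DataFrame(member_rows)
    membership = skeleton.merge(members, on="herb_id")
    membership = membership.sort_values(
        ["prescription_id", "herb_id", "compound_id"]).reset_index(drop=True)
    return compounds, membership


def generate_ct_predictions(compounds: pd.DataFrame,
                            config: SynthConfig) -> dict[str, pd.DataFrame]:
    """Three overlapping compound->target edge lists.

    Per compound, a union target count is drawn from
    ``config.targets_per_compound``; each target is reported either by
    all three servers (probability ``prediction_overlap``) or by a
    uniformly random non-empty subset, so the union always realises the
    drawn count.
    """
    if compounds is None or len(compounds) == 0:
        raise DataError("generate_ct_predictions: empty compound table")
    rng = _rng(config, _STREAM_PREDICT)
    lo, hi = config.targets_per_compound
    universe = np.arange(config.n_targets_universe)
    # Zipf-like popularity: a few promiscuous targets, a long rare tail
    weights = 1.0 / (universe + 1.0) ** config.target_popularity_exponent
    weights /= weights.sum()
    tables: dict[str, list] = {s: [] for s in SERVER_NAMES}
    for cid in sorted(compounds["compound_id"].astype(str)):
        k = int(rng.integers(lo, hi + 1))
        targets = rng.choice(universe, size=k, replace=False, p=weights)
        for t in sorted(targets):
            symbol = gene_symbol(int(t))
            if rng.random() < config.prediction_overlap:
                servers = SERVER_NAMES
            else:
                mask = int(rng.integers(1, 2 ** len(SERVER_NAMES)))
                servers = tuple(s for b, s in enumerate(SERVER_NAMES)
                                if mask >> b & 1)
            for s in servers:
                tables[s].append({"compound_id": cid, "target_id": symbol})
    return {s: pd.DataFrame(rows, columns=["compound_id", "target_id"])
            for s, rows in tables.items()}


def generate_gene_resources(config: SynthConfig) -> GeneResources:
    """Four disease-gene lists with controlled overlap, plus GMT sets.

    The pathological set (portal list intersected with the union of the
    three curated sources) realises exactly
    ``config.n_pathological_genes`` genes; ``source_overlap`` is the
    fraction of the portal list confirmed by at least one curated
    source. Gene sets span sizes below and above the 10-gene filter, and
    a third of them are enriched for target-region genes so that
    over-representation analysis has signal to find.
    """
    rng = _rng(config, _STREAM_GENES)
    n_uni = config.n_gene_universe
    universe = [gene_symbol(i) for i in range(n_uni)]
    gc_n = int(np.ceil(config.n_pathological_genes / config.source_overlap))
    if gc_n > n_uni:
        raise ConfigError(
            f"need {gc_n} portal genes but the universe has only {n_uni}")
    # portal list biased toward the target region of the symbol universe
    weights = np.ones(n_uni)
    weights[:config.n_targets_universe] = 3.0
    weights /= weights.sum()
    gc_idx = rng.choice(n_uni, size=gc_n, replace=False, p=weights)
    genecards = sorted(gene_symbol(int(i)) for i in gc_idx)
    confirmed = sorted(rng.choice(genecards, size=config.n_pathological_genes,
                                  replace=False))
    curated: dict[str, set[str]] = {s: set() for s in GENE_SOURCES[1:]}
    for g in confirmed:
        mask = int(rng.integers(1, 2 ** 3))
        for b, s in enumerate(GENE_SOURCES[1:]):
            if mask >> b & 1:
                curated[s].add(g)
    outside = sorted(set(universe) - set(genecards))
    for s in GENE_SOURCES[1:]:
        n_noise = int(round(0.3 * len(curated[s])))
        if n_noise and outside:
            noise = rng.choice(outside, size=min(n_noise, len(outside)),
                               replace=False)
            curated[s].update(str(g) for g in noise)
    source_lists = {"genecards": tuple(genecards)}
    source_lists.update({s: tuple(sorted(curated[s])) for s in GENE_SOURCES[1:]})

    lo, hi = config.gene_set_size
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_gene_sets)]
    if lo < 10 and min(sizes) >= 10:
        sizes[0] = lo          # guarantee the <10 filter is exercised
    if hi >= 10 and max(sizes) < 10:
        sizes[-1] = hi
    # "signal" sets emulate disease pathways: built around the popular
    # (hub) end of the target region, which every C-T network covers
    nt = config.n_targets_universe
    hub = 1.0 / (np.arange(nt) + 1.0) ** config.target_popularity_exponent
    target_weights = np.ones(n_uni)
    target_weights[:nt] = 9.0 * (n_uni - nt) * hub / hub.sum()
    target_weights /= target_weights.sum()
    gene_sets, categories = {}, {}
    for i, size in enumerate(sizes):
        cat = SET_CATEGORIES[i % len(SET_CATEGORIES)]
        set_id = f"{cat}{i + 1:04d}"
        p = target_weights if rng.random() < (1 / 3) else None
        idx = rng.choice(n_uni, size=size, replace=False, p=p)
        gene_sets[set_id] = tuple(sorted(gene_symbol(int(j)) for j in idx))
        categories[set_id] = cat
    return GeneResources(source_lists=source_lists, gene_sets=gene_sets,
                         set_categories=categories, universe=tuple(universe))


def generate_affinities(pairs, config: SynthConfig) -> pd.DataFrame:
    """Best-pose docking affinities (kcal/mol) for compound-target pairs.

    A fraction ``fraction_strong`` of pairs is drawn from the strong-
    binding tail (<= -8 kcal/mol); the rest from a negative-skewed normal
    strictly above -8.
    """
    pairs = list(pairs)
    if not pairs:
        raise DataError("generate_affinities: empty pair list")
    rng = _rng(config, _STREAM_AFFINITY)
    rows = []
    for cid, tid in pairs:
        if rng.random() < config.fraction_strong:
            a = _truncnorm(rng, -9.0, 1.0, -15.0, -8.0)
        else:
            a = _truncnorm(rng, config.affinity_mean, config.affinity_sd,
                           -7.999, -0.1)
        rows.append({"compound_id": cid, "target_id": tid,
                     "affinity": round(a, 2)})
    return pd.DataFrame(rows, columns=["compound_id", "target_id", "affinity"])


def generate_inputs(config: SynthConfig) -> SyntheticInputs:
    """Generate every pipeline input (affinities are made later, once the
    docking pair list is known)."""
    compounds, membership = generate_compound_table(config)
    predictions = generate_ct_predictions(compounds, config)
    genes = generate_gene_resources(config)
    targets = tuple(gene_symbol(i) for i in range(config.n_targets_universe))
    return SyntheticInputs(config=config, compounds=compounds,
                           membership=membership, predictions=predictions,
                           genes=genes, target_universe=targets)
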