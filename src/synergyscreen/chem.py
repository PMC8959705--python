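"""Circular fingerprints and Tanimoto similarity.

ECFP6 here means a Morgan/circular fingerprint of radius 3 (diameter 6)
folded to a fixed bit length (2048 by default). Only similarities computed
within this package are consumed downstream, so bit-level identity with
other toolkits is not required. Salts and mixtures are reduced to the
largest organic fragment before fingerprinting, since herbal-database
exports frequently carry counter-ions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.DataStructs import ExplicitBitVect, TanimotoSimilarity

from .errors import ChemistryError

RDLogger.DisableLog("rdApp.*")

DEFAULT_BITS = 2048
DEFAULT_RADIUS = 3


@dataclass(frozen=True)
class Fingerprint:
    """Folded binary circular fingerprint of one compound."""

    compound_id: str
    bits: ExplicitBitVect

    @property
    def n_bits(self) -> int:
        return self.bits.GetNumBits()

    def on_bits(self) -> frozenset[int]:
        return frozenset(self.bits.GetOnBits())


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric Tanimoto matrix over an ordered compound list."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape does not match id list")

    def loc(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def reindex(self, ids) -> "SimilarityMatrix":
        """Restrict/reorder to the given compound ids."""
        idx = [self.ids.index(i) for i in ids]
        return SimilarityMatrix(tuple(ids), self.values[np.ix_(idx, idx)])


def parse_mol(smiles: str):
    """Parse a SMILES string, keeping the largest organic fragment."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"unparsable SMILES: {smiles!r}", smiles=smiles)
    if len(Chem.GetMolFrags(mol)) > 1:
        mol = rdMolStandardize.LargestFragmentChooser().choose(mol)
    return mol


def fingerprint(smiles: str, compound_id: str = "", n_bits: int = DEFAULT_BITS,
                radius: int = DEFAULT_RADIUS) -> Fingerprint:
    """Compute the folded circular fingerprint of one SMILES."""
    mol = parse_mol(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return Fingerprint(compound_id or smiles, gen.GetFingerprint(mol))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two fingerprints."""
    if a.n_bits != b.n_bits:
        raise ChemistryError(
            f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    return float(TanimotoSimilarity(a.bits, b.bits))


def similarity_matrix(smiles_by_id: dict[str, str], n_bits: int = DEFAULT_BITS,
                      radius: int = DEFAULT_RADIUS) -> SimilarityMatrix:
    """Pairwise Tanimoto matrix C with unit diagonal.

    Parameters
    ----------
    smiles_by_id:
        Ordered mapping compound_id -> SMILES. The matrix rows/columns
        follow this order.

    Raises
    ------
    ChemistryError
        Aggregated over every unparsable SMILES in the input.
    """
    if not smiles_by_id:
        raise ChemistryError("similarity_matrix requires at least one compound")
    offenders = []
    fps = []
    for cid, smi in smiles_by_id.items():
        try:
            fps.append(fingerprint(smi, cid, n_bits=n_bits, radius=radius))
        except ChemistryError:
            offenders.append((cid, smi))
    if offenders:
        listing = "; ".join(f"{cid}: {smi!r}" for cid, smi in offenders)
        raise ChemistryError(f"unparsable SMILES for {len(offenders)} compounds: {listing}")
    n = len(fps)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = tanimoto(fps[i], fps[j])
    return SimilarityMatrix(tuple(smiles_by_id), values)
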