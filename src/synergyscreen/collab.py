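"""Collaborative-filtering reduction of a compound-target network.

With C the n x n Tanimoto similarity matrix of the compounds and T the
n x m binary compound-target matrix, the recommendation matrix is
X = C . T and each compound's score is the row mean

    s_i = (1/m) * sum_j x_ij .

s_i rewards compounds whose chemical neighbours share their targets. The
top 50% of compounds by s_i (ceil(n/2); ties broken by compound id) and
every target still connected to a retained compound are kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chem import SimilarityMatrix
from .errors import DataError
from .network import CTNetwork


@dataclass(frozen=True)
class CollabResult:
    scores: dict[str, float]
    retained_compounds: tuple[str, ...]
    retained_network: CTNetwork


def collab_scores(C: SimilarityMatrix | np.ndarray, T: np.ndarray,
                  compounds=None) -> dict[str, float]:
    """Per-compound scores s_i = row means of X = C . T.

    ``C`` may be a SimilarityMatrix (its id order defines the compounds)
    or a plain array, in which case ``compounds`` supplies the ids.
    """
    if isinstance(C, SimilarityMatrix):
        ids = C.ids
        Cv = C.values
    else:
        Cv = np.asarray(C, dtype=float)
        if compounds is None:
            raise DataError("collab_scores: compound ids required with a plain array")
        ids = tuple(compounds)
    T = np.asarray(T, dtype=float)
    n = len(ids)
    if Cv.shape != (n, n):
        raise DataError(f"C must be {n}x{n}, got {Cv.shape}")
    if T.ndim != 2 or T.shape[0] != n:
        raise DataError(f"T must have {n} rows, got shape {T.shape}")
    X = Cv @ T
    s = X.mean(axis=1)
    return {cid: float(v) for cid, v in zip(ids, s)}


def retain_top_half(scores: dict[str, float], net: CTNetwork,
                    fraction: float = 0.5) -> CollabResult:
    """Keep the ceil(n * fraction) highest-scoring compounds.

    Ties at the cutoff are broken by ascending compound id so that the
    retention set is deterministic across platforms. Retained targets
    are those with at least one edge to a retained compound.
    """
    if not (0.0 < fraction <= 1.0):
        raise DataError("retention fraction must be in (0, 1]")
    missing = [c for c in net.compounds if c not in scores]
    if missing:
        raise DataError(f"scores missing for compounds {missing[:5]}")
    k = math.ceil(net.n_compounds * fraction)
    ranked = sorted(net.compounds, key=lambda c: (-scores[c], c))
    retained = tuple(sorted(ranked[:k]))
    return CollabResult(scores=dict(scores), retained_compounds=retained,
                        retained_network=net.subnetwork(retained))
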