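"""Hellinger distances between tumor pieces and 2D spatial reconstruction.

Piece-to-piece distances are Hellinger distances between barcode
frequency profiles; the layout is a stress-majorization (SMACOF) 2D
embedding of the full distance matrix, and piece/barcode orderings come
from average-linkage hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.manifold import smacof

from .qc_normalize import ClonalProfile

__all__ = [
    "PieceDistanceMatrix",
    "PieceLayout",
    "hellinger",
    "hellinger_matrix",
    "force_layout",
    "cluster_pieces",
    "linkage_to_newick",
]


@dataclass
class PieceDistanceMatrix:
    piece_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.piece_ids), len(self.piece_ids)):
            raise ValueError("distance matrix shape does not match piece ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.piece_ids, columns=self.piece_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class PieceLayout:
    coordinates: pd.DataFrame  # index = piece ids, columns = x, y
    seed: int
    stress: float


def _aligned_freqs(p: ClonalProfile, q: ClonalProfile) -> tuple[np.ndarray, np.ndarray]:
    union = p.frequencies.index.union(q.frequencies.index)
    return (
        p.frequencies.reindex(union, fill_value=0.0).to_numpy(),
        q.frequencies.reindex(union, fill_value=0.0).to_numpy(),
    )


def hellinger(p: ClonalProfile, q: ClonalProfile) -> float:
    """Hellinger distance between two frequency profiles.

    H(p, q) = (1/sqrt(2)) * || sqrt(p) - sqrt(q) ||_2 over the union
    barcode set; bounded in [0, 1], 0 iff identical, 1 iff disjoint.
    """
    for prof in (p, q):
        total = prof.frequencies.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"profile {prof.sample_id!r} is not normalized (sum = {total:.6g})"
            )
    pv, qv = _aligned_freqs(p, q)
    return float(np.sqrt(((np.sqrt(pv) - np.sqrt(qv)) ** 2).sum() / 2.0))


def hellinger_matrix(piece_profiles: list[ClonalProfile]) -> PieceDistanceMatrix:
    if len(piece_profiles) < 2:
        raise ValueError("need >= 2 pieces")
    n = len(piece_profiles)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = hellinger(piece_profiles[i], piece_profiles[j])
    return PieceDistanceMatrix(
        piece_ids=[p.sample_id for p in piece_profiles], values=mat
    )


def force_layout(distances: PieceDistanceMatrix, seed: int = 0) -> PieceLayout:
    """2D embedding of the pieces by metric stress majorization.

    Minimizes sum over pairs of (embedded distance - input distance)^2 on
    the complete weighted graph (SMACOF); deterministic for a given seed.
    """
    n = len(distances.piece_ids)
    if n < 2:
        raise ValueError("need >= 2 pieces to lay out")
    coords, stress = smacof(
        distances.values,
        metric=True,
        n_components=2,
        init=None,
        n_init=8,
        max_iter=500,
        eps=1e-9,
        random_state=seed,
    )
    df = pd.DataFrame(coords, index=distances.piece_ids, columns=["x", "y"])
    return PieceLayout(coordinates=df, seed=seed, stress=float(stress))


def cluster_pieces(piece_profiles: list[ClonalProfile]) -> dict:
    """Average-linkage clustering of pieces (Hellinger) and barcodes.

    Barcodes are clustered on Euclidean distance between their
    square-root frequency vectors across pieces.  Returns linkage
    matrices and leaf orders for heatmap rendering.
    """
    if len(piece_profiles) < 2:
        raise ValueError("need >= 2 pieces")
    dist = hellinger_matrix(piece_profiles)
    piece_linkage = hierarchy.linkage(dist.condensed(), method="average")
    piece_order = [
        dist.piece_ids[i] for i in hierarchy.leaves_list(piece_linkage)
    ]

    union = piece_profiles[0].frequencies.index
    for p in piece_profiles[1:]:
        union = union.union(p.frequencies.index)
    freq_mat = np.vstack(
        [p.frequencies.reindex(union, fill_value=0.0).to_numpy() for p in piece_profiles]
    )
    barcode_vectors = np.sqrt(freq_mat.T)  # barcodes x pieces
    out = {
        "piece_linkage": piece_linkage,
        "piece_order": piece_order,
        "distance_matrix": dist,
        "barcode_ids": list(union),
    }
    if len(union) >= 2:
        bc_linkage = hierarchy.linkage(barcode_vectors, method="average")
        out["barcode_linkage"] = bc_linkage
        out["barcode_order"] = [
            union[i] for i in hierarchy.leaves_list(bc_linkage)
        ]
    else:
        out["barcode_linkage"] = None
        out["barcode_order"] = list(union)
    return out


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(linkage)

    def build(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"
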