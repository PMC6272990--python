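"""Dice similarity, neighbor-joining and band-bootstrap clade support.

Genetic similarity between two band profiles is the Dice coefficient
2a/(2a+b+c), where a counts shared band presences and b, c the presences
unique to each profile; dissimilarity is its complement.  Trees are built
with canonical Saitou–Nei neighbor joining (Q-criterion, plain-average
distance update), which recovers additive distances exactly.  Clade
support comes from resampling band columns with replacement, rebuilding
the tree per replicate, and mapping each internal bipartition's replicate
frequency onto the original tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .matrix import BandMatrix, BandMatrixError

__all__ = [
    "dice_similarity",
    "similarity_matrix",
    "dissimilarity_matrix",
    "group_mean_similarity",
    "nj_tree",
    "PhyloTree",
    "bootstrap_support",
    "write_newick",
]


def dice_similarity(x, y) -> float:
    """Dice coefficient 2a/(2a+b+c) between two 0/1 profiles."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    denom = 2 * a + b + c
    if denom == 0:
        raise ValueError("Dice coefficient undefined: both profiles are all-zero")
    return 2.0 * a / denom


def _pairwise_dice(values: np.ndarray) -> np.ndarray:
    v = values.astype(float)
    totals = v.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if len(zero) > 1:
        raise BandMatrixError(
            f"Dice undefined between all-zero profiles (rows {zero.tolist()})"
        )
    shared = v @ v.T
    denom = totals[:, None] + totals[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(denom > 0, 2.0 * shared / denom, 0.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def similarity_matrix(m: BandMatrix) -> pd.DataFrame:
    """Pairwise Dice similarities as a labelled square frame."""
    sim = _pairwise_dice(m.values)
    ids = list(m.sample_ids)
    return pd.DataFrame(sim, index=ids, columns=ids)


def dissimilarity_matrix(m: BandMatrix) -> DistanceMatrix:
    """1 - Dice for every sample pair."""
    d = 1.0 - _pairwise_dice(m.values)
    np.fill_diagonal(d, 0.0)
    # enforce exact symmetry against float noise
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, ids=list(m.sample_ids))


def group_mean_similarity(m: BandMatrix, groups: Mapping[str, str]) -> pd.DataFrame:
    """Mean Dice similarity between (and within) groups.

    Off-diagonal (g, h) averages Dice over all cross-group sample pairs;
    the diagonal averages over distinct within-group pairs and is NaN for
    singleton groups.
    """
    sim = _pairwise_dice(m.values)
    labels = np.array([groups[s] for s in m.sample_ids])
    order = list(dict.fromkeys(labels))
    out = pd.DataFrame(index=order, columns=order, dtype=float)
    for gi, g in enumerate(order):
        a = np.flatnonzero(labels == g)
        for h in order[gi:]:
            b = np.flatnonzero(labels == h)
            if g == h:
                if len(a) < 2:
                    out.loc[g, g] = np.nan
                else:
                    iu = np.triu_indices(len(a), k=1)
                    out.loc[g, g] = float(sim[np.ix_(a, a)][iu].mean())
            else:
                val = float(sim[np.ix_(a, b)].mean())
                out.loc[g, h] = val
                out.loc[h, g] = val
    return out


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class PhyloTree:
    """An unrooted tree (root is a trifurcation) with optional supports.

    ``supports`` maps canonical bipartitions (frozenset of the smaller
    leaf-name side) to percentage support in [0, 100].
    """

    tree: TreeNode
    supports: dict[frozenset, float] | None = None

    @property
    def leaf_names(self) -> frozenset:
        return frozenset(t.name for t in self.tree.tips())


def _clamped(li: float, lj: float) -> tuple[float, float]:
    # negative limb clamped to 0, deficit moved to the sister edge so the
    # pair's summed length (their mutual distance) is preserved
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(d: DistanceMatrix | np.ndarray, ids=None) -> PhyloTree:
    """Canonical Saitou–Nei neighbor joining.

    Ties in the Q criterion are broken by the lowest (row, column) index
    pair in the current working order, so the result is deterministic.
    Exact on additive distances; negative branch estimates are clamped to
    zero with the deficit transferred to the sister edge.
    """
    if isinstance(d, DistanceMatrix):
        mat = d.data.astype(float).copy()
        ids = list(d.ids)
    else:
        mat = np.asarray(d, dtype=float).copy()
        if ids is None:
            raise ValueError("ids required with a raw matrix")
        ids = list(ids)
        if mat.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(mat, mat.T):
            raise ValueError("distance matrix must be symmetric")
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    while len(nodes) > 3:
        k = len(nodes)
        r = mat.sum(axis=1)
        q = (k - 2) * mat - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: scan upper triangle row-major
        iu = np.triu_indices(k, 1)
        best = np.argmin(q[iu])
        i, j = int(iu[0][best]), int(iu[1][best])
        dij = mat[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = _clamped(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        parent = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (mat[i] + mat[j] - dij)
        keep = [t for t in range(k) if t not in (i, j)]
        mat = np.vstack([mat[keep][:, keep], dnew[keep]])
        mat = np.hstack([mat, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[t] for t in keep] + [parent]

    # closed-form three-point limbs for the final trifurcation
    a, b, c = nodes
    la = 0.5 * (mat[0, 1] + mat[0, 2] - mat[1, 2])
    lb = 0.5 * (mat[0, 1] + mat[1, 2] - mat[0, 2])
    lc = 0.5 * (mat[0, 2] + mat[1, 2] - mat[0, 1])
    a.length, b.length, c.length = (max(v, 0.0) for v in (la, lb, lc))
    root = TreeNode(children=[a, b, c])
    return PhyloTree(tree=root)


def _bipartitions(tree: TreeNode, full: frozenset) -> dict[frozenset, TreeNode]:
    """Canonical internal bipartitions: smaller side (lexicographic tie-break)."""
    bips: dict[frozenset, TreeNode] = {}
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        other = full - side
        if len(side) < 2 or len(other) < 2:
            continue  # trivial split
        if len(side) < len(other):
            key = side
        elif len(other) < len(side):
            key = other
        else:
            key = min(side, other, key=lambda s: tuple(sorted(s)))
        bips[key] = node
    return bips


def bootstrap_support(
    m: BandMatrix,
    n_reps: int = 1000,
    seed: int = 0,
    unit: str = "band",
) -> PhyloTree:
    """Neighbor-joining tree of a band matrix with bootstrap supports.

    Resamples characters with replacement (``unit="band"`` resamples band
    columns, ``unit="primer"`` resamples whole primer blocks), rebuilds the
    Dice dissimilarity and NJ tree per replicate, and scores each internal
    bipartition of the original tree by its replicate frequency in percent.
    Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    result = nj_tree(dissimilarity_matrix(m))
    full = result.leaf_names
    original = _bipartitions(result.tree, full)
    counts = {bip: 0 for bip in original}

    rng = np.random.default_rng(seed)
    if unit == "band":
        blocks = [np.array([j]) for j in range(m.n_bands)]
    elif unit == "primer":
        blocks = [m.primer_columns(p) for p in m.primers]
    else:
        raise ValueError(f"unknown bootstrap unit: {unit!r}")

    for _ in range(n_reps):
        choice = rng.integers(0, len(blocks), size=len(blocks))
        cols = np.concatenate([blocks[t] for t in choice])
        values = m.values[:, cols]
        rep_d = 1.0 - _pairwise_dice(values)
        np.fill_diagonal(rep_d, 0.0)
        rep_tree = nj_tree((rep_d + rep_d.T) / 2.0, ids=list(m.sample_ids))
        rep_bips = _bipartitions(rep_tree.tree, full)
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1

    result.supports = {bip: 100.0 * c / n_reps for bip, c in counts.items()}
    return result


def write_newick(t: PhyloTree, path: str | Path) -> None:
    """Write Newick with branch lengths; integer supports label internal nodes."""
    tree = t.tree
    if t.supports is not None:
        full = t.leaf_names
        for bip, node in _bipartitions(tree, full).items():
            if bip in t.supports:
                node.name = str(int(round(t.supports[bip])))
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
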