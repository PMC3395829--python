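"""Corrected distances, neighbor-joining, bootstrap support, clade extraction.

Virtual-taxon delimitation only consumes clade memberships and their bootstrap
supports, so tree inference here is distance based: Jukes-Cantor corrected
distances on the multiple alignment, Saitou-Nei neighbor joining (exact on
additive matrices), and a nonparametric bootstrap that resamples alignment
columns with replacement and counts bipartition recovery.

Trees are unrooted; internally they hang off a trifurcating root node, and
bipartitions are canonicalised as the side NOT containing the lexicographically
smallest leaf, which makes the bipartition set invariant to input order.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix

from .seqops import Alignment

#: distance assigned when the mismatch proportion saturates the JC correction
JC_CEILING = 5.0

Bipartition = frozenset


@dataclass
class _Node:
    name: str | None = None
    children: list[tuple["_Node", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class SupportTree:
    """Unrooted tree with branch lengths and per-bipartition bootstrap support.

    ``support`` maps each internal-edge bipartition (canonical leaf frozenset)
    to a percentage in [0, 100]; it is empty until bootstrap is run.
    """

    root: _Node
    leaves: list[str]
    support: dict[Bipartition, float] = field(default_factory=dict)

    def bipartitions(self) -> dict[Bipartition, float]:
        """Canonical bipartition -> branch length, for all internal edges.

        An internal edge is one whose child end is an internal node; its
        bipartition is (leaves below child | rest).  The canonical form is the
        side not containing the smallest leaf label.  Trivial splits (a side
        of size < 2) are excluded.
        """
        out: dict[Bipartition, float] = {}
        all_leaves = frozenset(self.leaves)
        anchor = min(self.leaves)

        def walk(node: _Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset()
            for child, length in node.children:
                side = walk(child)
                if not child.is_leaf:
                    canon = side if anchor not in side else all_leaves - side
                    if len(canon) >= 2 and len(all_leaves - canon) >= 2:
                        out[canon] = length
                below = below | side
            return below

        walk(self.root)
        return out

    def newick(self, with_support: bool = False) -> str:
        all_leaves = frozenset(self.leaves)
        anchor = min(self.leaves)

        def leafset(node: _Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            s = frozenset()
            for c, _ in node.children:
                s |= leafset(c)
            return s

        def fmt(node: _Node, length: float | None) -> str:
            if node.is_leaf:
                core = node.name
            else:
                inner = ",".join(fmt(c, ln) for c, ln in node.children)
                label = ""
                if with_support and self.support:
                    side = leafset(node)
                    canon = side if anchor not in side else all_leaves - side
                    if canon in self.support:
                        label = f"{self.support[canon]:g}"
                core = f"({inner}){label}"
            return core if length is None else f"{core}:{length:.6f}"

        return fmt(self.root, None) + ";"


def write_newick(tree: SupportTree, path, with_support: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick(with_support=with_support) + "\n")


# ---------------------------------------------------------------------------
# JC69 distances on an MSA
# ---------------------------------------------------------------------------

def _p_matrix(arr: np.ndarray, ok: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise mismatch proportions (one-hot matmul, no per-pair loop).

    Returns (p, comparable-column counts); p is NaN where no columns compare.
    """
    matches = np.zeros((arr.shape[0],) * 2)
    okf = ok.astype(np.float32)
    for b in b"ACGT":
        M = ((arr == chr(b)) & ok).astype(np.float32)
        matches += M @ M.T
    comparable = okf @ okf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 1.0 - matches / comparable
    np.fill_diagonal(p, 0.0)
    return p, comparable


def _jc_correct(p: np.ndarray, ceiling: float) -> np.ndarray:
    d = np.where(
        p >= 0.75, ceiling, -0.75 * np.log(np.clip(1.0 - 4.0 * p / 3.0, 1e-300, None))
    )
    np.fill_diagonal(d, 0.0)
    return d


def jc69_distance(msa: Alignment, ceiling: float = JC_CEILING) -> DistanceMatrix:
    """Jukes-Cantor corrected distances, d = -(3/4) ln(1 - 4p/3).

    p is the mismatch proportion over columns where both rows carry an
    unambiguous base.  p >= 0.75 saturates the correction; such pairs get
    ``ceiling`` with a warning.
    """
    if msa.n_rows < 2:
        raise ValueError("need at least 2 rows")
    arr = np.array([list(r) for r in msa.rows])
    ok = np.isin(arr, list("ACGT"))
    p, comparable = _p_matrix(arr, ok)
    for i, j in zip(*np.where(np.triu(comparable == 0, k=1))):
        raise ValueError(
            f"no comparable columns between rows {msa.ids[i]!r} and {msa.ids[j]!r}"
        )
    for i, j in zip(*np.where(np.triu(p >= 0.75, k=1))):
        warnings.warn(
            f"JC69 saturated (p={p[i, j]:.3f}) for pair ({msa.ids[i]}, {msa.ids[j]}); "
            f"using ceiling {ceiling}",
            RuntimeWarning,
            stacklevel=2,
        )
    return DistanceMatrix(_jc_correct(p, ceiling), list(msa.ids))


def _p_distances(arr: np.ndarray, ok: np.ndarray, ceiling: float) -> np.ndarray:
    """JC69 distances without warnings, for bootstrap replicates."""
    p, comparable = _p_matrix(arr, ok)
    p = np.where(comparable == 0, 1.0, p)  # incomparable -> ceiling
    return _jc_correct(p, ceiling)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> SupportTree:
    """Saitou-Nei neighbor joining with the Q criterion.

    Ties in Q pick the pair whose (smallest leaf label of each cluster) sorts
    first.  Negative branch lengths are clamped to zero with the deficit moved
    to the sibling edge; the final three clusters join at a trifurcating root.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    nodes: list[_Node] = [_Node(name=lb) for lb in labels]
    minlab: list[str] = list(labels)
    d = dm.data.astype(float).copy()
    active = list(range(len(labels)))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        qmin = Q[iu].min()
        ties = [(x, y) for x, y in zip(*iu) if Q[x, y] == qmin]
        x, y = min(
            ties,
            key=lambda t: tuple(sorted((minlab[active[t[0]]], minlab[active[t[1]]]))),
        )
        i, j = active[x], active[y]
        dij = sub[x, y]
        bi = 0.5 * dij + (r[x] - r[y]) / (2 * (m - 2))
        bj = dij - bi
        # Kuhner-Felsenstein: clamp negatives, shift deficit to the sibling
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        bi = max(bi, 0.0)
        bj = max(bj, 0.0)
        parent = _Node(children=[(nodes[i], bi), (nodes[j], bj)])
        # distances from the new node
        new_row = 0.5 * (d[i, active] + d[j, active] - dij)
        k = len(nodes)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[k, active] = new_row
        d[active, k] = new_row
        d[k, k] = 0.0
        nodes.append(parent)
        minlab.append(min(minlab[i], minlab[j]))
        active = [a for a in active if a not in (i, j)] + [k]

    a, b, c = active
    # closed-form lengths for the final trifurcation
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = _Node(
        children=[
            (nodes[a], max(la, 0.0)),
            (nodes[b], max(lb, 0.0)),
            (nodes[c], max(lc, 0.0)),
        ]
    )
    return SupportTree(root=root, leaves=sorted(labels))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    msa: Alignment, n_reps: int = 100, seed: int | None = None,
    ceiling: float = JC_CEILING,
) -> SupportTree:
    """Reference NJ tree plus column-resampling bootstrap supports.

    Each replicate resamples alignment columns with replacement, recomputes
    JC69 distances and the NJ tree, and scores which reference bipartitions
    reappear; support is the recovery percentage.  Fewer than 4 leaves give a
    tree with no internal edges (support map empty).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ref_dm = jc69_distance(msa, ceiling=ceiling)
    tree = neighbor_joining(ref_dm)
    if msa.n_rows < 4:
        return tree

    rng = np.random.default_rng(seed)
    arr = np.array([list(r) for r in msa.rows])
    ok_base = np.isin(arr, list("ACGT"))
    ref_bps = set(tree.bipartitions())
    counts = {bp: 0 for bp in ref_bps}
    L = msa.n_cols
    ids = list(msa.ids)
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rd = _p_distances(arr[:, cols], ok_base[:, cols], ceiling)
        rep_tree = neighbor_joining(DistanceMatrix(rd, ids))
        rep_bps = set(rep_tree.bipartitions())
        for bp in ref_bps & rep_bps:
            counts[bp] += 1
    tree.support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return tree


def supported_clades(
    tree: SupportTree, min_support: float = 50.0
) -> list[frozenset]:
    """Leaf sets of internal edges whose support >= ``min_support``.

    Each qualifying bipartition contributes its smaller side (ties by sorted
    leaf labels); the list is ordered smallest-first, then lexicographically.
    """
    if tree.support is None:
        raise ValueError("supports not set; run bootstrap_support first")
    all_leaves = frozenset(tree.leaves)
    out = []
    for bp, sup in tree.support.items():
        if sup >= min_support:
            other = all_leaves - bp
            side = min((bp, other), key=lambda s: (len(s), tuple(sorted(s))))
            out.append(side)
    out.sort(key=lambda s: (len(s), tuple(sorted(s))))
    return out
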