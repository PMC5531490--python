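"""Distance-based phylogenetics: p-distance, Poisson correction,
neighbor-joining, and column-resampling bootstrap.

The pipeline mirrors the classic MEGA workflow for protein alignments:
pairwise proportion of differing residues (gap columns excluded pairwise),
the Poisson correction d = −ln(1 − p) to substitutions per site under an
equal-rates model, Saitou–Nei neighbor-joining with negative branch lengths
clamped to zero, and bootstrap supports mapped onto the full-data tree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceMatrix",
    "Tree",
    "TreeNode",
    "p_distance",
    "poisson_correct",
    "nj_tree",
    "bootstrap_support",
    "write_phylip",
]

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with taxon labels."""

    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} taxa")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "d", m)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.taxa.index(p) for p in pair)
        return float(self.d[i, j])


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    raw_length: float = 0.0  # pre-clamp NJ estimate, kept for diagnostics
    support: float | None = None  # bootstrap %, internal edges only
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        return [lf for c in self.children for lf in c.leaves()]


@dataclass
class Tree:
    """Unrooted tree represented with an arbitrary internal root node."""

    root: TreeNode
    taxa: tuple[str, ...]

    def leaf_names(self) -> set[str]:
        return {lf.name for lf in self.root.leaves()}

    # -- bipartitions ------------------------------------------------------
    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial bipartitions keyed by the canonical leaf-set of one
        side (the side *not* containing the alphabetically first taxon)."""
        all_taxa = frozenset(self.leaf_names())
        ref = min(all_taxa)
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_taxa) - 1:
                side = all_taxa - below if ref in below else below
                out[side] = node
            return below

        walk(self.root)
        return out

    # -- distances ---------------------------------------------------------
    def path_lengths(self) -> DistanceMatrix:
        """All-pairs leaf path-length matrix (additivity oracle)."""
        taxa = sorted(self.leaf_names())
        idx = {t: i for i, t in enumerate(taxa)}
        n = len(taxa)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf():
                return {node.name: 0.0}
            sub = [
                {t: dist + c.length for t, dist in walk(c).items()}
                for c in node.children
            ]
            for a in range(len(sub)):
                for b in range(a + 1, len(sub)):
                    for ta, da in sub[a].items():
                        for tb, db in sub[b].items():
                            d[idx[ta], idx[tb]] = d[idx[tb], idx[ta]] = da + db
            merged: dict[str, float] = {}
            for s in sub:
                merged.update(s)
            return merged

        walk(self.root)
        return DistanceMatrix(tuple(taxa), d)

    # -- newick ------------------------------------------------------------
    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode, top: bool = False) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:.0f}"
            if top:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.10g}"

        return fmt(self.root, top=True) + ";"


def p_distance(taxa, sequences, complete_deletion: bool = False) -> DistanceMatrix:
    """Pairwise proportion of differing residues.

    Gap handling is pairwise deletion by default: each pair is compared over
    the columns where neither member carries a gap.  With
    ``complete_deletion`` every column containing any gap is dropped for all
    pairs.  A pair sharing no comparable column is an error.
    """
    taxa = tuple(taxa)
    seqs = [s.upper() for s in sequences]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences must be aligned (equal length)")
    arr = np.array([list(s) for s in seqs])
    gap = np.isin(arr, list(GAP_CHARS))
    if complete_deletion:
        keep = ~gap.any(axis=0)
        arr, gap = arr[:, keep], gap[:, keep]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            if not ok.any():
                raise ValueError(f"taxa {taxa[i]!r} and {taxa[j]!r} share no gap-free columns")
            d[i, j] = d[j, i] = float(np.mean(arr[i, ok] != arr[j, ok]))
    return DistanceMatrix(taxa, d)


def poisson_correct(p_matrix: DistanceMatrix, saturation_warn: float = 0.95) -> DistanceMatrix:
    """Poisson-corrected distances d = −ln(1 − p), substitutions per site.

    Undefined at p ≥ 1; a warning is raised for near-saturated pairs
    (p > ``saturation_warn``) where the correction is unreliable.
    """
    p = p_matrix.d
    if np.any(p >= 1.0):
        raise ValueError("p-distance ≥ 1: Poisson correction undefined (saturated pair)")
    if np.any(p > saturation_warn):
        warnings.warn("p-distance near saturation; corrected distances are unreliable", stacklevel=2)
    return DistanceMatrix(p_matrix.taxa, -np.log1p(-p))


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor-joining.

    Agglomerates the pair minimizing Q_ij = (r−2)·d_ij − R_i − R_j, with
    ties broken deterministically toward the lowest (creation-order) index
    pair.  Branch lengths follow the standard NJ formulas; negatives are
    clamped to 0 (the raw estimate is retained on each node).  The returned
    tree is unrooted, represented with a trifurcating root for ≥3 taxa.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    D = dm.d.copy()
    active = list(range(n))  # indices into `nodes`, in creation order
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n)}

    def get(i: int, j: int) -> float:
        return dist[(i, j)] if i <= j else dist[(j, i)]

    def put(i: int, j: int, v: float) -> None:
        dist[(i, j) if i <= j else (j, i)] = v

    while len(active) > 3:
        r = len(active)
        R = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best, best_q = None, math.inf
        for a_pos in range(r):
            for b_pos in range(a_pos + 1, r):
                i, j = active[a_pos], active[b_pos]
                q = (r - 2) * get(i, j) - R[i] - R[j]
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and (i, j) < best):
                    best, best_q = (i, j), q
        i, j = best
        dij = get(i, j)
        li_raw = 0.5 * dij + (R[i] - R[j]) / (2 * (r - 2))
        lj_raw = dij - li_raw
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].raw_length, nodes[j].raw_length = li_raw, lj_raw
        nodes[i].length, nodes[j].length = max(li_raw, 0.0), max(lj_raw, 0.0)
        u = len(nodes)
        nodes.append(parent)
        for k in active:
            if k in (i, j):
                continue
            put(u, k, 0.5 * (get(i, k) + get(j, k) - dij))
        active = [k for k in active if k not in (i, j)] + [u]

    # final trifurcation among the last three nodes
    a, b, c = active
    la = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    lb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    lc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    for node, raw in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
        node.raw_length = raw
        node.length = max(raw, 0.0)
    return Tree(root=root, taxa=dm.taxa)


def bootstrap_support(
    taxa,
    sequences,
    n_replicates: int = 1000,
    seed: int | None = None,
    complete_deletion: bool = False,
) -> Tree:
    """Column-resampling bootstrap supports mapped onto the full-data tree.

    Alignment columns are resampled with replacement; each replicate is run
    through p-distance → Poisson correction → neighbor-joining, and support
    for each internal bipartition of the full-data tree is the percentage
    of replicates containing it.
    """
    taxa = tuple(taxa)
    seqs = [s.upper() for s in sequences]
    full = nj_tree(poisson_correct(p_distance(taxa, seqs, complete_deletion)))
    biparts = full.bipartitions()
    counts = {bp: 0 for bp in biparts}
    rng = np.random.default_rng(seed)
    n_sites = len(seqs[0])
    arr = np.array([list(s) for s in seqs])
    n_ok = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, n_sites, size=n_sites)
        rep_seqs = ["".join(row) for row in arr[:, cols]]
        try:
            rep = nj_tree(poisson_correct(p_distance(taxa, rep_seqs, complete_deletion)))
        except ValueError:  # saturated or incomparable replicate
            continue
        n_ok += 1
        rep_biparts = set(rep.bipartitions())
        for bp in counts:
            if bp in rep_biparts:
                counts[bp] += 1
    if n_ok == 0:
        raise RuntimeError("all bootstrap replicates failed")
    for bp, node in biparts.items():
        node.support = 100.0 * counts[bp] / n_ok
    return full


def write_phylip(dm: DistanceMatrix) -> str:
    """Square PHYLIP distance-matrix text."""
    lines = [f"{len(dm.taxa)}"]
    for t, row in zip(dm.taxa, dm.d):
        name = t[:10].ljust(10)
        lines.append(name + "  " + "  ".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"
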