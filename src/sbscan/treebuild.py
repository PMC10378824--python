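"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap,
and a clade/motif concordance statistic.

Neighbor joining with uncorrected p-distances deliberately replaces the
maximum-likelihood fits used for published trees of these genomes: the point
of this module is a correct, deterministic, dependency-free tree builder for
testing clade/motif concordance, not reproduction of any published topology.
NJ is exact on additive distance matrices, which is what the property tests
exercise.  Negative NJ branch lengths are clamped to zero and flagged.

Bootstrap support resamples alignment columns with replacement (default 250
replicates, mirroring common practice for these datasets) and reports, per
internal edge of the reference tree, the percentage of replicate trees
containing the same bipartition.

Clade/motif concordance: for the smaller side of every internal edge, purity
is the frequency of the most common motif label divided by the clade size;
the overall statistic is the mean over clades with at least two leaves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from Bio import SeqIO

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "p_distance",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "clade_motif_concordance",
    "read_alignment",
    "write_phylip",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValueError("distance matrix has negative entries")


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree stored rooted at an internal trifurcation."""

    root: TreeNode
    has_clamped_lengths: bool = False

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def rec(n: TreeNode) -> None:
            for c in n.children:
                if not c.is_leaf:
                    out.append(c)
                    rec(c)

        rec(self.root)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Canonical non-trivial bipartitions (side not containing the first
        leaf label, so keys are comparable across trees on the same taxa)."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        bips = set()
        for node in self.internal_nodes():
            side = frozenset(l.name for l in node.leaves())
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            bips.add(side if ref not in side else all_leaves - side)
        return bips

    def clades(self) -> list[frozenset[str]]:
        """Smaller side of each internal edge (ties: canonical side)."""
        all_leaves = frozenset(self.leaf_names())
        out = []
        for node in self.internal_nodes():
            side = frozenset(l.name for l in node.leaves())
            other = all_leaves - side
            if not other:
                continue
            if len(side) < len(other):
                out.append(side)
            elif len(other) < len(side):
                out.append(other)
            else:
                out.append(side if min(all_leaves) not in side else other)
        return out

    def to_newick(self, include_support: bool = True) -> str:
        def rec(n: TreeNode) -> str:
            if n.is_leaf:
                return f"{n.name}:{n.length:.6g}"
            inner = ",".join(rec(c) for c in n.children)
            label = ""
            if include_support and n.support is not None:
                label = f"{n.support:g}"
            return f"({inner}){label}:{n.length:.6g}"

        inner = ",".join(rec(c) for c in self.root.children)
        return f"({inner});"


def p_distance(a: str, b: str, gap_as_difference: bool = True) -> float:
    """Uncorrected proportion of differing columns between aligned sequences.

    Columns where both sequences have a gap are ignored; a gap against a base
    counts as a difference by default (set ``gap_as_difference=False`` to
    ignore those columns too).
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal lengths")
    a, b = a.upper(), b.upper()
    diff = compared = 0
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        if x == "-" or y == "-":
            if gap_as_difference:
                compared += 1
                diff += 1
            continue
        compared += 1
        if x != y:
            diff += 1
    if compared == 0:
        return 0.0
    return diff / compared


def distance_matrix(
    alignment: list[tuple[str, str]], gap_as_difference: bool = True
) -> DistanceMatrix:
    labels = [name for name, _ in alignment]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence ids in alignment")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(
                alignment[i][1], alignment[j][1], gap_as_difference
            )
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Standard neighbor joining; deterministic via lowest-index tie-breaks.

    Exact on additive matrices.  Negative branch lengths are clamped to zero
    and flagged on the returned tree.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) pair on ties
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or Q[i, j] < Q[best[0], best[1]] - 1e-12:
                    best = (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        child_i = nodes[i]
        child_j = nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        new = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]

    # final three nodes joined at the unrooted trifurcation
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = clamp((dab + dac - dbc) / 2)
    b.length = clamp((dab + dbc - dac) / 2)
    c.length = clamp((dac + dbc - dab) / 2)
    tree = Tree(TreeNode(children=[a, b, c]), has_clamped_lengths=clamped)
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0", stacklevel=2)
    return tree


def bootstrap_support(
    alignment: list[tuple[str, str]],
    replicates: int = 250,
    seed: int | None = None,
    gap_as_difference: bool = True,
) -> Tree:
    """NJ tree with per-internal-edge bootstrap support percentages.

    ``replicates=0`` returns the tree without support annotations.
    Reproducible given ``seed``.
    """
    ref = neighbor_joining(distance_matrix(alignment, gap_as_difference))
    if replicates == 0:
        return ref
    ncol = len(alignment[0][1])
    rng = np.random.default_rng(seed)
    all_leaves = frozenset(n for n, _ in alignment)
    ref_label = min(all_leaves)
    counts: dict[frozenset[str], int] = {}
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        res = [(name, "".join(seq[c] for c in cols)) for name, seq in alignment]
        try:
            t = neighbor_joining(distance_matrix(res, gap_as_difference))
        except ValueError:
            continue
        for bip in t.bipartitions():
            counts[bip] = counts.get(bip, 0) + 1
    for node in ref.internal_nodes():
        side = frozenset(l.name for l in node.leaves())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        key = side if ref_label not in side else all_leaves - side
        node.support = 100.0 * counts.get(key, 0) / replicates
    return ref


def clade_motif_concordance(
    tree: Tree, motif_map: dict[str, str]
) -> tuple[list[tuple[frozenset[str], float]], float]:
    """Per-clade motif purity and the overall mean.

    Purity of a clade = frequency of its most common motif label / clade
    size.  Clades are the smaller sides of internal edges; a tree without
    internal edges (2-3 leaves) contributes its full leaf set as one clade.
    The overall statistic averages clades with at least two leaves.
    """
    missing = [l for l in tree.leaf_names() if l not in motif_map]
    if missing:
        raise ValueError(f"no motif label for leaves: {missing}")
    clades = [c for c in tree.clades() if len(c) >= 2]
    if not clades:
        clades = [frozenset(tree.leaf_names())]
    out = []
    for clade in clades:
        labels = [motif_map[l] for l in clade]
        top = max(labels.count(x) for x in set(labels))
        out.append((clade, top / len(clade)))
    overall = float(np.mean([p for _, p in out]))
    return out, overall


def read_alignment(path: str | Path) -> list[tuple[str, str]]:
    """Aligned FASTA (gaps allowed); all sequences must share one length."""
    alignment = [
        (rec.id, str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if alignment:
        lens = {len(s) for _, s in alignment}
        if len(lens) != 1:
            raise ValueError(f"alignment has unequal sequence lengths: {sorted(lens)}")
    return alignment


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP square distance-matrix format."""
    lines = [f"    {len(dm.labels)}"]
    for label, row in zip(dm.labels, dm.d):
        name = label[:10].ljust(10)
        lines.append(name + "  " + "  ".join(f"{x:.6f}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")
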