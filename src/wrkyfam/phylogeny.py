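"""Neighbor-joining phylogeny over pairwise domain distances.

Distances are p-distances computed on a pairwise global alignment (same
scoring as the classifier): one minus the fraction of identically aligned
columns.  Trees are agglomerated with the Saitou-Nei neighbor-joining
criterion, joining at each step the pair minimising

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

with branch lengths from the standard limb-length formulas.  Ties are broken
toward the lexicographically smallest index pair, and negative branch-length
estimates are clamped to zero (the tree records that this happened).  The
result is an unrooted tree represented with a trifurcating root, serialised
to and from Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .classify import DEFAULT_SCORING, AlignScoring, make_aligner


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix over an ordered taxon list."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n},{n})")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.d < -1e-12):
            raise ValueError("distance matrix has negative entries")


@dataclass
class TreeNode:
    """Node of a (possibly multifurcating) tree; leaves carry taxon names."""

    name: Optional[str] = None
    length: float = 0.0
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

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


@dataclass
class Tree:
    """Unrooted tree (trifurcating root node) with branch lengths >= 0."""

    root: TreeNode
    negative_branch_clamped: bool = False

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()


def pairwise_distance(
    seq_a: str, seq_b: str, scoring: AlignScoring = DEFAULT_SCORING
) -> float:
    """p-distance on the optimal global alignment of two sequences.

    1 minus (identical columns / alignment columns); pairwise alignments
    contain no gap-gap columns, so the denominator is the alignment length.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = make_aligner(scoring)
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a, b = str(aln[0]), str(aln[1])
    identical = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return 1.0 - identical / len(a)


def distance_matrix(
    records: Sequence[tuple[str, str]], scoring: AlignScoring = DEFAULT_SCORING
) -> DistanceMatrix:
    """All-pairs p-distance matrix for ``(id, sequence)`` records."""
    taxa = [name for name, _ in records]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon ids")
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = pairwise_distance(records[i][1], records[j][1], scoring)
    return DistanceMatrix(taxa, d)


def nj_tree(m: DistanceMatrix) -> Tree:
    """Neighbor joining (Saitou-Nei) with deterministic tie-breaking."""
    n = len(m.taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in m.taxa]
    d = m.d.copy()
    clamped = False

    if n == 2:
        # single edge; split its length across the two leaves
        half = max(0.0, d[0, 1]) / 2.0
        nodes[0].length = nodes[1].length = half
        return Tree(TreeNode(children=nodes), negative_branch_clamped=False)

    active = list(range(n))
    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lexicographically smallest (i, j) among the minima
        best = None
        for a in range(k):
            for b in range(a + 1, k):
                if best is None or q[a, b] < q[best[0], best[1]] - 1e-12:
                    best = (a, b)
        ai, bj = best
        i, j = active[ai], active[bj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[bj]) / (2.0 * (k - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped = True
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to every remaining taxon
        new_row = np.zeros(d.shape[0] + 1)
        for m_idx in active:
            if m_idx in (i, j):
                continue
            new_row[m_idx] = 0.5 * (d[i, m_idx] + d[j, m_idx] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : -1] = new_row[:-1]
        d[: -1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    # final three nodes joined at the trifurcating root
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    if min(li, lj, lk) < 0:
        clamped = True
    nodes[i].length = max(0.0, li)
    nodes[j].length = max(0.0, lj)
    nodes[k].length = max(0.0, lk)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return Tree(root, negative_branch_clamped=clamped)


def to_newick(t: Tree, precision: int = 6) -> str:
    def fmt(node: TreeNode, with_length: bool) -> str:
        if node.is_leaf:
            core = node.name or ""
        else:
            core = "(" + ",".join(fmt(c, True) for c in node.children) + ")"
            if node.name:
                core += node.name
        if with_length:
            core += f":{node.length:.{precision}f}"
        return core

    return fmt(t.root, False) + ";"


class NewickError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


def parse_newick(s: str) -> Tree:
    """Parse a Newick string (branch lengths optional) into a Tree."""
    text = s.strip()
    if not text.endswith(";"):
        raise NewickError("missing terminating ';'", len(text))
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(text) and text[pos] == "(":
            open_at = pos
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(text):
                    raise NewickError("unbalanced parentheses", open_at)
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise NewickError(f"unexpected character {text[pos]!r}", pos)
        # label
        start = pos
        while pos < len(text) and text[pos] not in ",():;":
            pos += 1
        label = text[start:pos]
        if label:
            node.name = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            try:
                node.length = float(text[start:pos])
            except ValueError:
                raise NewickError(
                    f"bad branch length {text[start:pos]!r}", start
                ) from None
        return node

    root = parse_node()
    if pos != len(text) - 1 or text[pos] != ";":
        raise NewickError("trailing characters", pos)
    return Tree(root)


def bipartitions(t: Tree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions (one side each), as a topology fingerprint.

    Two unrooted trees over the same taxa are topologically equal iff their
    bipartition sets are equal.
    """
    all_leaves = frozenset(t.leaf_names())
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not t.root and 1 < len(below) < len(all_leaves) - 1:
            complement = all_leaves - below
            side = below if sorted(below) <= sorted(complement) else complement
            splits.add(side)
        return below

    walk(t.root)
    return splits


def same_topology(a: Tree, b: Tree) -> bool:
    if set(a.leaf_names()) != set(b.leaf_names()):
        return False
    return bipartitions(a) == bipartitions(b)


def leaf_path_lengths(t: Tree) -> dict[tuple[str, str], float]:
    """Sum of branch lengths between every leaf pair (for additivity checks)."""
    dists: dict[tuple[str, str], float] = {}

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        sides = [walk(c) for c in node.children]
        for idx, c in enumerate(node.children):
            for name in sides[idx]:
                sides[idx][name] += c.length
        for a_idx in range(len(sides)):
            for b_idx in range(a_idx + 1, len(sides)):
                for na, da in sides[a_idx].items():
                    for nb, db in sides[b_idx].items():
                        key = (na, nb) if na < nb else (nb, na)
                        dists[key] = da + db
        merged: dict[str, float] = {}
        for side in sides:
            merged.update(side)
        return merged

    walk(t.root)
    return dists
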