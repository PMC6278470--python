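"""Distance-based phylogenetics: p/Poisson distances, NJ, bootstrap, newick.

The "poisson" model is the Poisson-corrected distance -ln(1 - p) applied to
nucleotide p-distances (the correction MEGA labels "Poisson"); gap handling
is pairwise deletion: each pair is compared over the columns where both rows
carry an unambiguous base.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

SATURATION_WARN_P = 0.75
_BASES = frozenset("ACGT")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: list[list[float]]
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.taxa)
        assert len(self.d) == n and all(len(row) == n for row in self.d)
        for i in range(n):
            assert self.d[i][i] == 0.0, "diagonal must be zero"
            for j in range(i + 1, n):
                assert math.isclose(self.d[i][j], self.d[j][i], abs_tol=1e-12)
                assert self.d[i][j] >= 0 and math.isfinite(self.d[i][j])

    def get(self, a: str, b: str) -> float:
        return self.d[self.taxa.index(a)][self.taxa.index(b)]


class Node:
    __slots__ = ("name", "children", "length", "support", "parent", "raw_length")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.children: list[Node] = []
        self.length = length
        self.raw_length: float | None = None  # pre-clamp NJ estimate
        self.support: int | None = None
        self.parent: Node | None = None

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> set[str]:
        return {leaf.name for leaf in self.leaves()}


@dataclass
class Tree:
    root: Node

    @property
    def taxa(self) -> set[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the leaf set of one side (canonical:
        the side not containing the alphabetically first taxon)."""
        all_taxa = self.taxa
        anchor = min(all_taxa)
        splits: set[frozenset[str]] = set()
        for node in _iter_nodes(self.root):
            if node is self.root or node.is_leaf():
                continue
            side = node.leaf_names()
            if anchor in side:
                side = all_taxa - side
            if 1 < len(side) < len(all_taxa) - 1:
                splits.add(frozenset(side))
        return splits


def _iter_nodes(node: Node):
    yield node
    for c in node.children:
        yield from _iter_nodes(c)


# ---------------------------------------------------------------------------
# distances

def pairwise_distance(rows: list[tuple[str, str]], model: str = "poisson") -> DistanceMatrix:
    """Distance matrix from aligned rows under the p or poisson model.

    Pairwise deletion of gaps: only columns where both rows are in
    {A,C,G,T} are compared. A pair with no comparable column is an error;
    near-saturated pairs (p >= 0.75) are flagged and logged.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    if len(rows) < 2:
        raise ValueError("need at least 2 rows")
    taxa = [name for name, _ in rows]
    enc = np.array([[ord(c) for c in seq] for _, seq in rows], dtype=np.int16)
    ok = np.isin(enc, [ord(c) for c in "ACGT"])
    n = len(rows)
    d = [[0.0] * n for _ in range(n)]
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable columns between {taxa[i]!r} and {taxa[j]!r}")
            mism = int((enc[i][both] != enc[j][both]).sum())
            p = mism / compared
            if p >= SATURATION_WARN_P:
                saturated.append((taxa[i], taxa[j]))
                log.warning("pair (%s, %s) near-saturated: p=%.3f",
                            taxa[i], taxa[j], p)
            if model == "p":
                dist = p
            else:
                if p >= 1.0:
                    raise ValueError(f"saturated pair ({taxa[i]}, {taxa[j]}): p={p}")
                dist = -math.log(1.0 - p)
            d[i][j] = d[j][i] = dist
    return DistanceMatrix(taxa, d, saturated)


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic smallest-(i,j) tie-break.

    Returns an unrooted tree with a root trifurcation; negative branch-length
    estimates are clamped to 0 (the raw value is kept on ``raw_length``).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[Node] = [Node(name) for name in dm.taxa]
    d = {(i, j): dm.d[i][j] for i in range(n) for j in range(n)}
    active = list(range(n))
    next_id = n

    def dist(i: int, j: int) -> float:
        return 0.0 if i == j else d[(min(i, j), max(i, j))]

    node_of = {i: nodes[i] for i in range(n)}
    while len(active) > 2:
        r = len(active)
        sums = {i: sum(dist(i, k) for k in active) for i in active}
        best = None
        best_q = math.inf
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dist(i, j) - sums[i] - sums[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dij - li
        parent = Node()
        for child, raw in ((node_of[i], li), (node_of[j], lj)):
            child.raw_length = raw
            child.length = max(0.0, raw)
            if raw < 0:
                log.info("clamped negative NJ branch length %.6g", raw)
            parent.add(child)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            d[(min(k, u), max(k, u))] = 0.5 * (dist(i, k) + dist(j, k) - dij)
        node_of[u] = parent
        active = [k for k in active if k not in (i, j)] + [u]

    # join the last two clusters through the root (trifurcation normally
    # arises because the last parent already has two children)
    i, j = active
    dij = dist(i, j)
    a, b = node_of[i], node_of[j]
    if not b.is_leaf() and b.name is None:
        root = b
        a.raw_length = dij
        a.length = max(0.0, dij)
        root.add(a)
    else:
        root = a if (not a.is_leaf() and a.name is None) else Node()
        if root is a:
            b.raw_length = dij
            b.length = max(0.0, dij)
            root.add(b)
        else:
            a.raw_length = dij / 2
            b.raw_length = dij / 2
            a.length = b.length = max(0.0, dij / 2)
            root.add(a)
            root.add(b)
    return Tree(root)


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_support(rows: list[tuple[str, str]], model: str = "poisson",
                      n_replicates: int = 100, seed: int = 0) -> Tree:
    """NJ tree from the full alignment with bipartition bootstrap supports.

    Columns are resampled with replacement per replicate (seeded); support
    is the percentage of replicate NJ trees containing the same bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    length = len(rows[0][1])
    if length < 2:
        raise ValueError("alignment must have at least 2 columns")
    tree = neighbor_joining(pairwise_distance(rows, model))
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    names = [n for n, _ in rows]
    mat = np.array([list(s) for _, s in rows])
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        sampled = ["".join(r) for r in mat[:, cols]]
        rep_rows = list(zip(names, sampled))
        try:
            rep_tree = neighbor_joining(pairwise_distance(rep_rows, model))
        except ValueError:
            continue  # replicate with an incomparable pair
        for split in rep_tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    all_taxa = tree.taxa
    anchor = min(all_taxa)
    for node in _iter_nodes(tree.root):
        if node is tree.root or node.is_leaf():
            continue
        side = node.leaf_names()
        if anchor in side:
            side = all_taxa - side
        if 1 < len(side) < len(all_taxa) - 1:
            node.support = round(100 * counts.get(frozenset(side), 0) / n_replicates)
    return tree


# ---------------------------------------------------------------------------
# rooting, monophyly, newick

def root_with_outgroup(tree: Tree, taxon: str) -> Tree:
    """Root on the outgroup's pendant edge (split at its midpoint)."""
    target = None
    for node in _iter_nodes(tree.root):
        if node.is_leaf() and node.name == taxon:
            target = node
    if target is None:
        raise ValueError(f"taxon {taxon!r} not in tree")
    if target.parent is None:
        return tree
    new_root = Node()
    old_parent = target.parent
    half = target.length / 2
    # detach and re-hang the path from old_parent up to the old root
    old_parent.children.remove(target)
    _reverse_path(old_parent)
    target.length = half
    old_parent.length = half
    old_parent.support = None  # root edge split is trivial (outgroup vs rest)
    new_root.add(target)
    new_root.add(old_parent)
    _suppress_unary(new_root)
    return Tree(new_root)


def _suppress_unary(node: Node) -> None:
    """Merge single-child internal nodes left over from re-rooting."""
    for child in list(node.children):
        _suppress_unary(child)
    if len(node.children) == 1 and node.parent is not None:
        (child,) = node.children
        child.length += node.length
        child.support = child.support if child.support is not None else node.support
        parent = node.parent
        idx = parent.children.index(node)
        parent.children[idx] = child
        child.parent = parent


def _reverse_path(node: Node) -> None:
    """Make ``node`` a root by reversing parent links above it."""
    parent = node.parent
    node.parent = None
    prev = node
    prev_length = node.length
    prev_support = node.support
    while parent is not None:
        grand = parent.parent
        parent.children.remove(prev)
        length, support = parent.length, parent.support
        parent.length = prev_length
        parent.support = prev_support
        prev.add(parent)
        prev, parent = parent, grand
        prev_length, prev_support = length, support


def is_monophyletic(tree: Tree, taxa: set[str]) -> bool:
    """True iff some edge's bipartition isolates exactly ``taxa``."""
    taxa = set(taxa)
    all_taxa = tree.taxa
    if not taxa <= all_taxa:
        raise ValueError("unknown taxa: " + ",".join(sorted(taxa - all_taxa)))
    if taxa == all_taxa or len(taxa) == 1:
        return True
    for node in _iter_nodes(tree.root):
        side = node.leaf_names()
        if side == taxa or (all_taxa - side) == taxa:
            return True
    return False


def to_newick(tree: Tree, decimals: int = 6) -> str:
    def fmt(node: Node) -> str:
        if node.is_leaf():
            label = node.name or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            label = f"({inner})"
            if node.support is not None:
                label += str(node.support)
        if node.parent is not None:
            label += f":{node.length:.{decimals}f}"
        return label

    return fmt(tree.root) + ";"


def write_newick(tree: Tree, path: str | os.PathLike, decimals: int = 6) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_newick(tree, decimals) + "\n")


def read_newick(text: str) -> Tree:
    """Parse a newick string with branch lengths and integer supports."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            node.add(parse_node())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                node.add(parse_node())
            if pos >= len(s) or s[pos] != ")":
                raise ValueError("unbalanced parentheses in newick")
            pos += 1
        label = _scan(lambda c: c not in ":,();")
        if label:
            if node.is_leaf():
                node.name = label
            else:
                node.support = int(label)
        if pos < len(s) and s[pos] == ":":
            pos += 1
            num = _scan(lambda c: c not in ",();")
            node.length = float(num)
        return node

    def _scan(pred) -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and pred(s[pos]):
            pos += 1
        return s[start:pos]

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in newick at {pos}")
    return Tree(root)
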