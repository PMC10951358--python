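"""Distance-based tree building, outgroup rooting and monophyly testing.

Trees are built from a :class:`~diagmark.distances.DistanceMatrix` by
Saitou–Nei neighbour joining (unrooted) or UPGMA average-linkage clustering
(rooted, ultrametric). Species discrimination is then scored on the
outgroup-rooted tree: a taxon counts as discriminated when its accessions
form a complete, exclusive clade, and the discrimination success rate is
100 * (number of monophyletic taxa) / (number of ingroup taxa).

Determinism: agglomeration ties are broken by the smallest (row, column)
index pair in the current label order, and negative neighbour-joining branch
lengths are clamped to zero with the deficit moved to the sister branch so
path lengths are conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .core_io import Alignment, TaxonMap
from .distances import DistanceMatrix, distance_matrix

logger = logging.getLogger(__name__)


class LabellingError(KeyError):
    """A requested leaf is absent from the tree."""


class RootingError(ValueError):
    """The outgroup does not map to a single edge."""


class TreeStateError(ValueError):
    """Operation requires a rooted (or unrooted) tree."""


@dataclass
class Node:
    """Tree node; ``length`` is the branch to the parent, ``support`` the
    bootstrap percentage of that branch (internal nodes only)."""

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = field(default=None, repr=False, compare=False)

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterable["Node"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.walk() if n.is_leaf)


@dataclass
class Tree:
    root: Node
    rooted: bool = False

    def leaves(self) -> list[Node]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def find_leaf(self, name: str) -> Node:
        for n in self.root.walk():
            if n.is_leaf and n.name == name:
                return n
        raise LabellingError(f"leaf {name!r} not in tree")

    def mrca(self, names: Iterable[str]) -> Node:
        """Most recent common ancestor of the named leaves."""
        targets = set(names)
        unknown = targets - self.leaf_names()
        if unknown:
            raise LabellingError(f"leaves not in tree: {sorted(unknown)}")
        paths = []
        for name in targets:
            node = self.find_leaf(name)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        mrca = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            step = paths[0][depth]
            if all(p[depth] is step for p in paths):
                mrca = step
            else:
                break
        return mrca

    def bipartitions(self) -> set[frozenset[str]]:
        """Unrooted splits, each canonicalized to the side not containing the
        lexicographically smallest leaf."""
        all_leaves = self.leaf_names()
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_names()
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
        return splits


@dataclass(frozen=True)
class DiscriminationReport:
    """Monophyly of each ingroup taxon and the resulting success rate."""

    monophyly: tuple[tuple[str, bool], ...]
    n_monophyletic: int
    n_taxa: int
    rate_percent: float

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\tmonophyletic\n")
            for taxon, mono in self.monophyly:
                fh.write(f"{taxon}\t{int(mono)}\n")
            fh.write(f"# discrimination_success_rate\t{self.rate_percent:.1f}\n")


def _check_matrix(matrix: DistanceMatrix, min_n: int) -> None:
    if len(matrix.labels) < min_n:
        raise ValueError(f"need >= {min_n} labels, got {len(matrix.labels)}")
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("distance matrix contains non-finite entries")


def nj_tree(matrix: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbour joining; returns an unrooted tree.

    Iteratively joins the pair minimizing
    Q(i,j) = (r-2) d(i,j) - R_i - R_j, with branch lengths
    l_i = d(i,j)/2 + (R_i - R_j)/(2(r-2)); the final three nodes are joined
    by the three-point closed form.
    """
    _check_matrix(matrix, 3)
    D = matrix.values.astype(float).copy()
    nodes = [Node(name=lab) for lab in matrix.labels]

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest (row, col) pair among the minima, row-major
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, lj)
        parent = Node()
        nodes[i].length, nodes[j].length = li, lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_row = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], new_row[keep]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # three-point closed form
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    root = Node()
    for node, length in zip(nodes, (l0, l1, l2)):
        node.length = max(length, 0.0)
        root.add_child(node)
    return Tree(root=root, rooted=False)


def upgma_tree(matrix: DistanceMatrix) -> Tree:
    """Average-linkage agglomeration; rooted ultrametric tree.

    Node heights are half the merge distance; leaf branch lengths therefore
    make every root-to-leaf path equal.
    """
    _check_matrix(matrix, 2)
    D = matrix.values.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    nodes = [Node(name=lab) for lab in matrix.labels]
    heights = [0.0] * len(nodes)
    sizes = [1] * len(nodes)

    while len(nodes) > 1:
        i, j = np.unravel_index(int(np.argmin(D)), D.shape)
        if i > j:
            i, j = j, i
        h = 0.5 * D[i, j]
        parent = Node()
        nodes[i].length = h - heights[i]
        nodes[j].length = h - heights[j]
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        merged = (sizes[i] * D[i, :] + sizes[j] * D[j, :]) / (sizes[i] + sizes[j])
        keep = [k for k in range(len(nodes)) if k not in (i, j)]
        D_new = np.full((len(keep) + 1, len(keep) + 1), np.inf)
        D_new[:len(keep), :len(keep)] = D[np.ix_(keep, keep)]
        D_new[-1, :len(keep)] = D_new[:len(keep), -1] = merged[keep]
        D = D_new
        nodes = [nodes[k] for k in keep] + [parent]
        heights = [heights[k] for k in keep] + [h]
        sizes = [sizes[k] for k in keep] + [sizes[i] + sizes[j]]

    return Tree(root=nodes[0], rooted=True)


def _adjacency(tree: Tree) -> dict[int, list[tuple[Node, Node, float, float | None]]]:
    """Undirected edge list keyed by id(node): (node, nbr, length, support)."""
    adj: dict[int, list] = {}
    for node in tree.root.walk():
        adj.setdefault(id(node), [])
        for child in node.children:
            length = child.length if child.length is not None else 0.0
            adj.setdefault(id(child), [])
            adj[id(node)].append((node, child, length, child.support))
            adj[id(child)].append((child, node, length, child.support))
    return adj


def root_with_outgroup(tree: Tree, outgroup_accessions: Iterable[str]) -> Tree:
    """Root on the edge separating the outgroup from the ingroup.

    The chosen edge's length is split equally between the two root children.
    The outgroup must be present and form one side of a single split.
    """
    outgroup = frozenset(outgroup_accessions)
    all_leaves = tree.leaf_names()
    missing = outgroup - all_leaves
    if missing:
        raise LabellingError(f"outgroup accessions not in tree: {sorted(missing)}")
    if not outgroup or outgroup == all_leaves:
        raise RootingError("outgroup must be a proper non-empty leaf subset")

    # locate the edge whose child side equals the outgroup (or its complement)
    target = None
    for node in tree.root.walk():
        if node is tree.root:
            continue
        side = node.leaf_names()
        if side == outgroup or side == all_leaves - outgroup:
            target = node
            break
    if target is None:
        raise RootingError("outgroup accessions do not form a detachable subtree")

    adj = _adjacency(tree)
    u, v = target.parent, target
    edge_len = v.length if v.length is not None else 0.0
    edge_sup = v.support

    def build(prev: Node, node: Node) -> Node:
        fresh = Node(name=node.name)
        for a, b, length, support in adj[id(node)]:
            if b is prev:
                continue
            child = build(node, b)
            child.length = length
            child.support = support if not b.is_leaf else None
            fresh.add_child(child)
        return fresh

    root = Node()
    for top in (v, u):
        side = build(u if top is v else v, top)
        side.length = edge_len / 2.0
        side.support = edge_sup if not top.is_leaf else None
        root.add_child(side)
    # outgroup side first, by convention
    if not (root.children[0].leaf_names() >= outgroup):
        root.children.reverse()
    _suppress_unifurcations(root)
    return Tree(root=root, rooted=True)


def _suppress_unifurcations(root: Node) -> None:
    """Merge non-root degree-2 nodes (left behind when re-rooting an already
    rooted tree) into their single child, summing branch lengths."""
    for node in list(root.walk()):
        for i, child in enumerate(list(node.children)):
            while len(child.children) == 1:
                grand = child.children[0]
                grand.length = (grand.length or 0.0) + (child.length or 0.0)
                grand.parent = node
                node.children[i] = grand
                child = grand


def is_monophyletic(tree: Tree, accession_set: Iterable[str]) -> bool:
    """True iff the MRCA of the set has exactly that set as leaf descendants."""
    if not tree.rooted:
        raise TreeStateError("monophyly is defined on rooted trees only")
    targets = frozenset(accession_set)
    mrca = tree.mrca(targets)
    return mrca.leaf_names() == targets


def discrimination_success_rate(tree: Tree, taxon_map: TaxonMap) -> DiscriminationReport:
    """Fraction of ingroup taxa that are monophyletic, as a percentage."""
    if not tree.rooted:
        raise TreeStateError("discrimination rate requires an outgroup-rooted tree")
    leaves = tree.leaf_names()
    results = []
    for taxon in taxon_map.ingroup_taxa():
        accs = [a for a in taxon_map.accessions_of(taxon) if a in leaves]
        if not accs:
            raise LabellingError(f"taxon {taxon!r} has no leaf in the tree")
        results.append((taxon, is_monophyletic(tree, accs)))
    n_mono = sum(m for _, m in results)
    n_taxa = len(results)
    return DiscriminationReport(
        monophyly=tuple(results),
        n_monophyletic=n_mono,
        n_taxa=n_taxa,
        rate_percent=100.0 * n_mono / n_taxa,
    )


def bootstrap_support(
    alignment: Alignment,
    taxon_map: TaxonMap | None,
    model: str,
    method: str = "nj",
    replicates: int = 1000,
    seed: int | None = None,
    gamma_shape: float | None = None,
) -> Tree:
    """Point-estimate tree with bootstrap percentages on internal edges.

    Columns are resampled with replacement per replicate; the support of an
    internal edge is the percentage of successful replicate trees containing
    the same unrooted bipartition. Replicates whose resampled alignment
    leaves some pair with no comparable site are skipped with a warning.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    builders: dict[str, Callable[[DistanceMatrix], Tree]] = {
        "nj": nj_tree, "upgma": upgma_tree}
    if method not in builders:
        raise ValueError(f"unknown method {method!r}")
    build = builders[method]

    point = build(distance_matrix(alignment, model, gamma_shape))
    point_splits = point.bipartitions()
    counts = {s: 0 for s in point_splits}

    rng = np.random.default_rng(seed)
    n_ok = 0
    skipped = 0
    for _ in range(replicates):
        cols = rng.integers(0, alignment.length, size=alignment.length)
        seqs = ["".join(s[c] for c in cols) for s in alignment.sequences]
        boot = Alignment(name=alignment.name, accessions=list(alignment.accessions),
                         sequences=seqs)
        try:
            rep_tree = build(distance_matrix(boot, model, gamma_shape))
        except ValueError:
            skipped += 1
            continue
        n_ok += 1
        rep_splits = rep_tree.bipartitions()
        for s in point_splits:
            if s in rep_splits:
                counts[s] += 1
    if skipped:
        logger.warning("bootstrap: %d of %d replicates skipped (no-overlap pairs)",
                       skipped, replicates)

    denom = max(n_ok, 1)
    all_leaves = point.leaf_names()
    ref = min(all_leaves)
    for node in point.root.walk():
        if node is point.root or node.is_leaf:
            continue
        side = node.leaf_names()
        if ref in side:
            side = all_leaves - side
        if side in counts:
            node.support = 100.0 * counts[side] / denom
    return point


# ---------------------------------------------------------------------------
# Newick serialization

class NewickError(ValueError):
    pass


def _format_node(node: Node) -> str:
    if node.is_leaf:
        out = node.name or ""
    else:
        out = "(" + ",".join(_format_node(c) for c in node.children) + ")"
        if node.support is not None:
            out += str(int(round(node.support)))
    if node.length is not None:
        out += f":{node.length:.10g}"
    return out


def tree_to_newick(tree: Tree) -> str:
    return _format_node(tree.root) + ";"


def write_newick(tree: Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")


def parse_newick_string(text: str, rooted: bool | None = None) -> Tree:
    """Parse standard Newick with branch lengths and internal support labels.

    Numeric internal-node labels are read as bootstrap support. A tree whose
    root has exactly two children is treated as rooted unless overridden.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_node())
                if pos >= len(s):
                    raise NewickError("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise NewickError(f"unexpected character {s[pos]!r} at {pos}")
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if label:
            if node.is_leaf:
                node.name = label
            else:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError as exc:
                raise NewickError(f"bad branch length {s[start:pos]!r}") from exc
        return node

    root = parse_node()
    if pos != len(s):
        raise NewickError(f"trailing characters after position {pos}")
    if rooted is None:
        rooted = len(root.children) == 2
    return Tree(root=root, rooted=rooted)


def parse_newick(path: str | Path, rooted: bool | None = None) -> Tree:
    with open(path) as fh:
        return parse_newick_string(fh.read(), rooted=rooted)
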