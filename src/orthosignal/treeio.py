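"""Unrooted trees: newick I/O, bipartitions, RF distances, two-chain diagnostics.

Trees are stored unrooted: any rooted newick input is normalized by collapsing
the root so that the (arbitrary) internal anchor node has degree >= 3 and no
degree-2 nodes remain.  Numeric internal-node labels are interpreted as
support values attached to the corresponding edge, matching the convention of
maximum-likelihood tree writers.  Newick parsing and writing are delegated to
dendropy; all topological computation (bipartitions, Robinson-Foulds,
pruning/regrafting, patristic distances) is implemented here on a lightweight
node structure.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np


class TreeError(ValueError):
    """Invalid tree structure or incompatible tree pair."""


class NewickParseError(TreeError):
    """Malformed newick input."""


# --------------------------------------------------------------------------
# Bipartitions


class Bipartition:
    """An unordered pair of disjoint taxon sets induced by removing one edge.

    Equality and hashing ignore which side is which; a bipartition is
    *nontrivial* iff both sides contain at least two taxa.
    """

    __slots__ = ("_a", "_b", "_sides")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        fa, fb = frozenset(side_a), frozenset(side_b)
        if not fa or not fb:
            raise ValueError("bipartition sides must be nonempty")
        if fa & fb:
            raise ValueError("bipartition sides must be disjoint")
        # canonical order so side_a/side_b are deterministic
        if (len(fa), tuple(sorted(fa))) > (len(fb), tuple(sorted(fb))):
            fa, fb = fb, fa
        self._a, self._b = fa, fb
        self._sides = frozenset((fa, fb))

    @property
    def side_a(self) -> frozenset:
        return self._a

    @property
    def side_b(self) -> frozenset:
        return self._b

    @property
    def leaves(self) -> frozenset:
        return self._a | self._b

    @property
    def nontrivial(self) -> bool:
        return len(self._a) >= 2 and len(self._b) >= 2

    def restrict(self, taxa: Iterable[str]) -> "Bipartition | None":
        """Restriction to a taxon subset, or None if a side becomes empty."""
        taxa = frozenset(taxa)
        ra, rb = self._a & taxa, self._b & taxa
        if not ra or not rb:
            return None
        return Bipartition(ra, rb)

    def __eq__(self, other) -> bool:
        return isinstance(other, Bipartition) and self._sides == other._sides

    def __hash__(self) -> int:
        return hash(self._sides)

    def __repr__(self) -> str:
        a = ",".join(sorted(self._a))
        b = ",".join(sorted(self._b))
        return f"{{{a}}}|{{{b}}}"


# --------------------------------------------------------------------------
# Node structure


class _Node:
    __slots__ = ("label", "children", "length", "support")

    def __init__(self, label=None, children=None, length=None, support=None):
        self.label = label
        self.children: list[_Node] = children if children is not None else []
        self.length = length
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "_Node":
        return _Node(
            self.label,
            [c.copy() for c in self.children],
            self.length,
            self.support,
        )


def _postorder(node: _Node) -> Iterator[_Node]:
    stack, out = [node], []
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return reversed(out)


class UnrootedTree:
    """An unrooted phylogenetic tree with optional branch lengths and supports.

    Internally anchored at an arbitrary internal node of degree >= 3 (for
    trees with >= 3 leaves).  All derived quantities (bipartitions, distances)
    are invariant to the choice of anchor.
    """

    def __init__(self, root: _Node):
        self._root = root
        self._normalize()
        self._validate()
        self._leaves = frozenset(n.label for n in _postorder(self._root) if n.is_leaf)
        self._biparts: frozenset | None = None
        self._edge_meta: dict | None = None

    # -- construction / normalization

    def _normalize(self) -> None:
        root = self._root
        # suppress unifurcations below the root
        for node in list(_postorder(root)):
            i = 0
            while i < len(node.children):
                c = node.children[i]
                if len(c.children) == 1:
                    g = c.children[0]
                    if c.length is not None or g.length is not None:
                        g.length = (c.length or 0.0) + (g.length or 0.0)
                    if g.support is None:
                        g.support = c.support
                    node.children[i] = g
                else:
                    i += 1
        # collapse a rooted (degree-2) root into a trifurcation
        while len(root.children) == 2:
            x, y = root.children
            if y.is_leaf and not x.is_leaf:
                x, y = y, x
            if y.is_leaf:
                break  # two-leaf tree; rejected in validation
            if x.length is not None or y.length is not None:
                x.length = (x.length or 0.0) + (y.length or 0.0)
            if x.support is None:
                x.support = y.support
            root.children = [x] + y.children
        while len(root.children) == 1:
            root = root.children[0]
            root.length = None
            self._root = root

    def _validate(self) -> None:
        labels = [n.label for n in _postorder(self._root) if n.is_leaf]
        if len(labels) < 3:
            raise TreeError(
                f"an unrooted tree needs >= 3 leaves, got {len(labels)}"
            )
        if len(set(labels)) != len(labels):
            dups = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate leaf labels: {dups}")
        if any(not lab for lab in labels):
            raise TreeError("empty leaf label")
        for n in _postorder(self._root):
            if n.length is not None and n.length < 0:
                raise TreeError(f"negative branch length {n.length}")

    # -- basic queries

    @property
    def leaves(self) -> frozenset:
        return self._leaves

    def __len__(self) -> int:
        return len(self._leaves)

    def copy(self) -> "UnrootedTree":
        return UnrootedTree(self._root.copy())

    def _edges(self):
        """All edges as (child node, leafset below), anchor excluded.

        Caches per-edge metadata: bipartition (nontrivial edges only),
        length, support, and whether the edge is internal.
        """
        if self._edge_meta is None:
            below: dict[int, frozenset] = {}
            meta = {}
            n_leaves = len(self._leaves)
            order = list(_postorder(self._root))
            for node in order:
                if node.is_leaf:
                    below[id(node)] = frozenset((node.label,))
                else:
                    s = frozenset()
                    for c in node.children:
                        s |= below[id(c)]
                    below[id(node)] = s
            biparts = {}
            for node in order:
                if node is self._root:
                    continue
                b = below[id(node)]
                internal = 2 <= len(b) <= n_leaves - 2
                if internal:
                    bp = Bipartition(b, self._leaves - b)
                    biparts[bp] = node
            meta["below"] = below
            meta["biparts"] = biparts
            self._edge_meta = meta
        return self._edge_meta

    def bipartitions(self) -> frozenset:
        """All nontrivial bipartitions (N-3 of them for a resolved tree)."""
        if self._biparts is None:
            self._biparts = frozenset(self._edges()["biparts"])
        return self._biparts

    def bipartition_supports(self) -> dict:
        """Support value per nontrivial bipartition (None where absent)."""
        return {bp: node.support for bp, node in self._edges()["biparts"].items()}

    def internal_supports(self) -> list:
        """Support values on internal (nontrivial) edges, missing ones dropped."""
        return [
            node.support
            for node in self._edges()["biparts"].values()
            if node.support is not None
        ]

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in _postorder(self._root) if n is not self._root)

    def internal_length(self) -> float:
        meta = self._edges()
        below = meta["below"]
        n = len(self._leaves)
        tot = 0.0
        for node in _postorder(self._root):
            if node is self._root:
                continue
            b = below[id(node)]
            if 2 <= len(b) <= n - 2:
                tot += node.length or 0.0
        return tot

    def has_branch_lengths(self) -> bool:
        return all(
            n.length is not None for n in _postorder(self._root) if n is not self._root
        )

    # -- distances

    def patristic_matrix(self) -> tuple[list, np.ndarray]:
        """Sorted leaf labels and the matrix of path-length distances."""
        adj: dict[int, list] = {}
        node_of: dict[int, _Node] = {}

        def link(a: _Node, b: _Node, w: float):
            adj.setdefault(id(a), []).append((id(b), w))
            adj.setdefault(id(b), []).append((id(a), w))

        stack = [self._root]
        leaf_nodes = []
        while stack:
            n = stack.pop()
            node_of[id(n)] = n
            if n.is_leaf:
                leaf_nodes.append(n)
            for c in n.children:
                link(n, c, c.length or 0.0)
                stack.append(c)
        labels = sorted(n.label for n in leaf_nodes)
        idx = {lab: i for i, lab in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)))
        for src in leaf_nodes:
            dist = {id(src): 0.0}
            stack = [id(src)]
            while stack:
                u = stack.pop()
                for v, w in adj.get(u, ()):
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            i = idx[src.label]
            for nid, d in dist.items():
                n = node_of[nid]
                if n.is_leaf and n.label != src.label:
                    m[i, idx[n.label]] = d
        return labels, m

    def scale_lengths(self, factor: float) -> "UnrootedTree":
        """New tree with every branch length multiplied by ``factor``."""
        if factor < 0:
            raise TreeError("scale factor must be >= 0")
        root = self._root.copy()
        for n in _postorder(root):
            if n.length is not None:
                n.length *= factor
        return UnrootedTree(root)

    # -- mutation (used by the synthetic generator)

    def prune_taxa(self, drop: Iterable[str]) -> "UnrootedTree":
        """New tree with the given leaves removed (degree-2 nodes collapsed)."""
        drop = frozenset(drop)
        kept = self._leaves - drop
        if len(kept) < 3:
            raise TreeError("pruning would leave fewer than 3 leaves")

        def rebuild(node: _Node) -> _Node | None:
            if node.is_leaf:
                if node.label in drop:
                    return None
                return _Node(node.label, None, node.length, node.support)
            kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
            if not kids:
                return None
            new = _Node(node.label, kids, node.length, node.support)
            return new

        root = rebuild(self._root)
        return UnrootedTree(root)

    def relocate_leaf(self, leaf: str, attach_near: str) -> "UnrootedTree":
        """SPR move: detach ``leaf`` and reattach it on the pendant edge of
        ``attach_near`` (creating a cherry with that taxon).

        Branch lengths: the target pendant edge is split in half and the moved
        leaf keeps its original pendant length.
        """
        if leaf == attach_near:
            raise TreeError("cannot attach a leaf next to itself")
        if leaf not in self._leaves or attach_near not in self._leaves:
            raise TreeError("leaf not in tree")
        root = self._root.copy()
        parent: dict[int, _Node] = {}
        target = None
        moved = None
        stack = [root]
        while stack:
            n = stack.pop()
            for c in n.children:
                parent[id(c)] = n
                stack.append(c)
            if n.is_leaf:
                if n.label == leaf:
                    moved = n
                elif n.label == attach_near:
                    target = n
        p = parent[id(moved)]
        p.children.remove(moved)
        # splice out p if it became degree-2 (handled by normalization too,
        # but doing it here keeps the target search valid)
        tl = target.length
        half = None if tl is None else tl / 2.0
        tp = parent[id(target)]
        i = tp.children.index(target)
        new_leaf = _Node(target.label, None, half, None)
        joint = _Node(None, [new_leaf, _Node(moved.label, None, moved.length, None)], half, None)
        tp.children[i] = joint
        return UnrootedTree(root)

    # -- output

    def to_newick(self, *, lengths: bool = True, supports: bool = True) -> str:
        out = io.StringIO()

        def fmt(x: float) -> str:
            return f"{x:.10g}"

        def write(node: _Node):
            if node.is_leaf:
                out.write(_quote_label(node.label))
            else:
                out.write("(")
                for i, c in enumerate(node.children):
                    if i:
                        out.write(",")
                    write(c)
                out.write(")")
                if supports and node.support is not None:
                    s = node.support
                    out.write(fmt(s) if isinstance(s, float) and not s.is_integer() else str(int(s)) if isinstance(s, float) else str(s))
            if lengths and node.length is not None and node is not self._root:
                out.write(f":{fmt(node.length)}")

        write(self._root)
        out.write(";")
        return out.getvalue()

    def __repr__(self) -> str:
        return f"UnrootedTree({len(self._leaves)} leaves)"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


# --------------------------------------------------------------------------
# Parsing


def _convert(dnode) -> _Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return _Node(label, None, dnode.edge.length, None)
    support = None
    if dnode.label is not None:
        try:
            support = float(dnode.label)
        except ValueError:
            support = None
    kids = [_convert(c) for c in dnode.child_nodes()]
    return _Node(None, kids, dnode.edge.length, support)


def parse_newick(text: str) -> UnrootedTree:
    """Parse a single newick string into a normalized :class:`UnrootedTree`.

    Numeric internal-node labels become edge support values; bracketed
    comments are ignored; rooted inputs are unrooted by collapsing the root.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise NewickParseError(f"malformed newick: {exc}") from None
    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        raise NewickParseError("malformed newick: no tree found")
    return UnrootedTree(_convert(dtree.seed_node))


def write_newick(tree: UnrootedTree, path=None, **kw) -> str:
    """Serialize a tree; if ``path`` is given, also write it (one line)."""
    s = tree.to_newick(**kw)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def read_trees(path, burnin: int = 0, thin: int = 1) -> list:
    """Read a multi-tree file (one newick per line), with burn-in/thinning."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees[burnin::thin]


# --------------------------------------------------------------------------
# Distances and chain comparison


def bipartitions(tree: UnrootedTree) -> frozenset:
    """All nontrivial bipartitions of ``tree``."""
    return tree.bipartitions()


def rf_distance(t1: UnrootedTree, t2: UnrootedTree) -> tuple[int, float]:
    """Robinson-Foulds distance and its normalization by 2(N-3).

    The denominator is 2(N-3) even for multifurcating trees so that
    normalized distances stay comparable along an MCMC chain trace.
    """
    if t1.leaves != t2.leaves:
        raise TreeError(
            "leaf-set mismatch: "
            f"{sorted(t1.leaves ^ t2.leaves)} not shared"
        )
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    rf = len(b1 ^ b2)
    denom = 2 * (len(t1.leaves) - 3)
    return rf, (rf / denom) if denom > 0 else 0.0


def edge_decompositions(tree: UnrootedTree):
    """For each nontrivial edge: (bipartition, below components, above components).

    The components are the leaf sets of the subtrees meeting at each end of
    the edge (excluding the edge itself) -- the four-or-more groups from
    which site-concordance quartets are drawn.
    """
    meta = tree._edges()
    below = meta["below"]
    parent: dict[int, _Node] = {}
    stack = [tree._root]
    while stack:
        n = stack.pop()
        for c in n.children:
            parent[id(c)] = n
            stack.append(c)
    out = []
    for bp, node in meta["biparts"].items():
        below_comps = [below[id(c)] for c in node.children]
        p = parent[id(node)]
        above_comps = [below[id(s)] for s in p.children if s is not node]
        if p is not tree._root:
            above_comps.append(tree.leaves - below[id(p)])
        out.append((bp, below_comps, above_comps))
    return out


@dataclass
class ChainComparison:
    """Bipartition-frequency discrepancy between two MCMC tree samples."""

    maxdiff: float
    meandiff: float
    per_bipartition: dict = field(repr=False)

    @property
    def converged(self) -> bool:
        """Topological convergence by the common maxdiff < 0.3 rule."""
        return self.maxdiff < 0.3


def _bipartition_freqs(trees: Sequence[UnrootedTree]) -> dict:
    counts: dict[Bipartition, int] = {}
    for t in trees:
        for bp in t.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    n = len(trees)
    return {bp: c / n for bp, c in counts.items()}


def chain_discrepancy(
    chain1: Sequence[UnrootedTree],
    chain2: Sequence[UnrootedTree],
    burnin: int = 0,
    thin: int = 1,
) -> ChainComparison:
    """maxdiff / meandiff between two chains' bipartition frequencies.

    Frequencies are computed over trees retained after burn-in and thinning;
    discrepancies are taken over the union of nontrivial bipartitions observed
    in either chain (a bipartition absent from a chain has frequency 0), the
    most inclusive consistent convention.
    """
    c1 = list(chain1)[burnin::thin]
    c2 = list(chain2)[burnin::thin]
    if not c1 or not c2:
        raise TreeError("no trees retained after burn-in/thinning")
    leaves = c1[0].leaves
    for t in c1 + c2:
        if t.leaves != leaves:
            raise TreeError("all chain trees must share one leaf set")
    f1 = _bipartition_freqs(c1)
    f2 = _bipartition_freqs(c2)
    per = {}
    for bp in set(f1) | set(f2):
        per[bp] = (f1.get(bp, 0.0), f2.get(bp, 0.0))
    if not per:
        return ChainComparison(0.0, 0.0, per)
    diffs = [abs(a - b) for a, b in per.values()]
    return ChainComparison(max(diffs), float(np.mean(diffs)), per)
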