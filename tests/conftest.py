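"""Shared fixtures and independent oracles.

The oracles here deliberately take a different route from the package:
dendropy's own bipartition machinery for splits/RF, and explicit
enumeration for everything else, so that implementation and check never
share code.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from orthosignal.treeio import UnrootedTree, parse_newick


# --------------------------------------------------------------------------
# Random tree generation (test inputs, not oracles)


def random_resolved_newick(labels, rng) -> str:
    """Random fully resolved unrooted topology over ``labels``."""
    items = [f"{lab}:{rng.uniform(0.05, 1.0):.4f}" for lab in labels]
    while len(items) > 3:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a},{b}):{rng.uniform(0.05, 1.0):.4f}")
    return "(" + ",".join(items) + ");"


def random_tree(labels, rng) -> UnrootedTree:
    return parse_newick(random_resolved_newick(labels, rng))


# --------------------------------------------------------------------------
# dendropy-based oracles


def dendropy_splits(newick: str) -> set:
    """Nontrivial splits of an unrooted tree as frozenset pairs, via dendropy."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    taxa = frozenset(t.label for t in tree.taxon_namespace)
    out = set()
    for bp in tree.bipartition_encoding:
        side = frozenset(
            t.label for t in tree.taxon_namespace if bp.leafset_bitmask & tree.taxon_namespace.taxon_bitmask(t)
        )
        other = taxa - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(frozenset((side, other)))
    return out


def oracle_clan_recovered(newick: str, clan_taxa: set) -> bool:
    """Edge-enumeration clan test: is some edge side exactly the present clan taxa?

    Assumes >= 2 clan taxa present.  Uses dendropy edges directly, including
    trivial ones (pendant edges cover the <= 1-other-taxon case).
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    taxa = {lf.taxon.label for lf in tree.leaf_node_iter()}
    present = frozenset(clan_taxa & taxa)
    if present == taxa:
        # no non-clan taxon to exclude: the separation is vacuously realized
        return True
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in edge.head_node.leaf_iter())
        if side == present or taxa - side == present:
            return True
    return False


def oracle_rf(newick1: str, newick2: str) -> int:
    ns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=ns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=ns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


# --------------------------------------------------------------------------
# Fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def quartet_tree():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
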