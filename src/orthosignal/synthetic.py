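"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates the shape of real animal-phylogeny supermatrix
studies at desk scale: a species tree in which each major lineage is a
clan, gene trees with per-clan taxon dropout and controlled clan-violating
rearrangements (a stand-in for hidden paralogy and gene/species-tree
conflict), amino-acid alignments evolved with gamma rate heterogeneity and
optional per-lineage compositional shifts, and exact-profile constructors
that build a gene-tree set recovering a requested per-n clan histogram.

Every generator is a pure function of (spec, seed); truth tables record the
dropout and rearrangements actually applied so downstream expectations can
be recomputed independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from orthosignal.clans import ClanDefinition, ClanStatus, clan_status
from orthosignal.matrix import AMINO_ACIDS, Alignment
from orthosignal.treeio import UnrootedTree, _Node

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")

#: Worked-example per-n clan-recovery histograms of five published animal
#: phylogenomics datasets (orthogroup counts recovering n of 5 countable
#: clans, n = 5..0).  Used to rebuild datasets with those exact profiles.
ANIMAL_DATASET_PROFILES = {
    "Chang2015": {5: 1, 4: 8, 3: 25, 2: 56, 1: 107, 0: 3},
    "Whelan2015_D10": {5: 1, 4: 15, 3: 24, 2: 51, 1: 100, 0: 19},
    "Whelan2015_D20": {5: 2, 4: 8, 3: 19, 2: 45, 1: 83, 0: 21},
    "Simion2017": {5: 25, 4: 125, 3: 307, 2: 583, 1: 625, 0: 54},
    "Whelan2017_MCRS": {5: 3, 4: 19, 3: 20, 2: 33, 1: 36, 0: 16},
}

# Five residues whose frequencies are inflated in composition-shifted
# lineages; which residues they are is immaterial to the metrics under test.
_SHIFT_RESIDUES = "AVLIF"


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic generators.

    Defaults mirror a scaled-down animal-phylogeny dataset: five countable
    clans (four phyla plus an outgroup clan) and one singleton clan, with a
    designated fast lineage carrying the long-stem / composition-shift
    behaviour.  Branch lengths are exponential with mean ``branch_scale``
    substitutions/site; ``stem_stretch`` multiplies the fast clan's stem.
    """

    clan_sizes: dict = field(
        default_factory=lambda: {
            "Bilateria": 8,
            "Cnidaria": 5,
            "Ctenophora": 4,
            "Porifera": 5,
            "Placozoa": 1,
            "Outgroup": 5,
        }
    )
    n_orthogroups: int = 100
    dropout: dict = field(default_factory=dict)  # clan -> per-taxon drop prob
    default_dropout: float = 0.2
    violation_rate: float = 0.3
    n_violating_moves: int = 1
    aln_length: tuple = (200, 600)
    gamma_shape: float = 0.5
    comp_shift: float = 0.0
    stem_stretch: float = 1.0
    fast_clan: str = "Ctenophora"
    branch_scale: float = 0.1
    gap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if sum(self.clan_sizes.values()) < 4:
            raise ValueError("need at least 4 taxa in total")
        probs = [self.violation_rate, self.default_dropout, self.gap_fraction]
        probs += list(self.dropout.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.stem_stretch < 1:
            raise ValueError("stem_stretch must be >= 1")

    def taxa_of(self, clan: str) -> list:
        return [f"{clan}_{i + 1}" for i in range(self.clan_sizes[clan])]

    def clans(self) -> list:
        return [ClanDefinition(name, self.taxa_of(name)) for name in self.clan_sizes]

    def clan_of(self, taxon: str) -> str:
        return taxon.rsplit("_", 1)[0]

    def dropout_of(self, clan: str) -> float:
        return self.dropout.get(clan, self.default_dropout)


# --------------------------------------------------------------------------
# Species tree


def _random_join(items: list, rng, scale: float) -> _Node:
    """Random binary join of subtree items, exponential internal lengths."""
    items = list(items)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        parent = _Node(None, [a, b], float(rng.exponential(scale)), None)
        items.append(parent)
    return items[0]


def simulate_species_tree(spec: SyntheticSpec, seed: int | None = None) -> UnrootedTree:
    """Species tree with every clan monophyletic (as a clan).

    Each clan is a random binary subtree; clan roots are joined into a random
    binary backbone.  The fast clan's stem is multiplied by ``stem_stretch``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    clan_roots = []
    for name in spec.clan_sizes:
        leaves = [
            _Node(t, None, float(rng.exponential(spec.branch_scale)), None)
            for t in spec.taxa_of(name)
        ]
        if len(leaves) == 1:
            sub = leaves[0]
        else:
            sub = _random_join(leaves, rng, spec.branch_scale)
        if name == spec.fast_clan and sub.length is not None:
            sub.length *= spec.stem_stretch
        elif name == spec.fast_clan:
            sub.length = float(rng.exponential(spec.branch_scale)) * spec.stem_stretch
        clan_roots.append(sub)
    root = _random_join(clan_roots, rng, spec.branch_scale)
    root.length = None
    return UnrootedTree(root)


# --------------------------------------------------------------------------
# Gene trees


def simulate_gene_trees(
    species: UnrootedTree, spec: SyntheticSpec, seed: int | None = None
) -> tuple[dict, pd.DataFrame]:
    """Gene trees with dropout and clan-violating relocations, plus truth table.

    Per orthogroup, each taxon is dropped with its clan's dropout
    probability; with probability ``violation_rate`` the tree then receives
    ``n_violating_moves`` subtree-prune-regraft moves, each detaching one
    member of a clan and reattaching it as a cherry with a member of a
    different clan (both clans are thereby violated).  Trees reduced below 4
    leaves are resampled.  The truth table records, per orthogroup, the
    dropped taxa, the moves applied, and the clans those moves violate.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    clans = spec.clans()
    countable = [c for c in clans if c.countable]
    trees = {}
    records = []
    for i in range(spec.n_orthogroups):
        og = f"OG{i + 1:04d}"
        for _attempt in range(100):
            drop = [
                t
                for t in sorted(species.leaves)
                if rng.random() < spec.dropout_of(spec.clan_of(t))
            ]
            if len(species.leaves) - len(drop) >= 4:
                break
        else:
            raise RuntimeError("dropout leaves too few taxa; lower dropout rates")
        tree = species.prune_taxa(drop) if drop else species.copy()
        moves = []
        violated = set()
        if rng.random() < spec.violation_rate:
            for _m in range(spec.n_violating_moves):
                mv = _violating_move(tree, countable, rng)
                if mv is None:
                    continue
                tree, leaf, source_clan, target_clan = mv
                moves.append((leaf, target_clan))
                violated.update((source_clan, target_clan))
        trees[og] = tree
        records.append(
            {
                "orthogroup": og,
                "n_leaves": len(tree.leaves),
                "dropped": ";".join(sorted(drop)),
                "moves": ";".join(f"{l}->{c}" for l, c in moves),
                "violated_clans": ";".join(sorted(violated)),
            }
        )
    return trees, pd.DataFrame(records)


def _violating_move(tree: UnrootedTree, countable: Sequence[ClanDefinition], rng):
    """One guaranteed clan-violating leaf relocation, or None if impossible."""
    present = {c.name: sorted(c.taxa & tree.leaves) for c in countable}
    eligible = [n for n, taxa in present.items() if len(taxa) >= 2]
    if len(eligible) < 2:
        return None
    by_name = {c.name: c for c in countable}
    for _try in range(20):
        src, tgt = (eligible[k] for k in rng.choice(len(eligible), 2, replace=False))
        leaf = present[src][rng.integers(len(present[src]))]
        near = present[tgt][rng.integers(len(present[tgt]))]
        moved = tree.relocate_leaf(leaf, near)
        if (
            clan_status(moved, by_name[src]) is ClanStatus.VIOLATED
            and clan_status(moved, by_name[tgt]) is ClanStatus.VIOLATED
        ):
            return moved, leaf, src, tgt
    return None


# --------------------------------------------------------------------------
# Alignments


def simulate_alignment(
    gene_tree: UnrootedTree, spec: SyntheticSpec, seed: int | None = None
) -> Alignment:
    """Evolve residues along the gene tree.

    Equal-exchangeability process: on an edge of length t, each site
    experiences a substitution event with probability 1 - exp(-r * t) (r its
    gamma-distributed rate, mean 1) and redraws its state from the edge's
    stationary frequencies.  Frequencies are uniform except on edges inside
    the fast clan's subtree, where they are linearly biased toward a fixed
    residue subset by ``comp_shift``.  Optional uniform gap injection
    (``gap_fraction``) supports occupancy tests.
    """
    if not gene_tree.has_branch_lengths():
        raise ValueError("gene tree must have branch lengths")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lo, hi = spec.aln_length
    length = int(rng.integers(lo, hi + 1))
    rates = rng.gamma(spec.gamma_shape, 1.0 / spec.gamma_shape, size=length)
    pi0 = np.full(20, 1.0 / 20.0)
    spike = np.array([1.0 / len(_SHIFT_RESIDUES) if aa in _SHIFT_RESIDUES else 0.0 for aa in AMINO_ACIDS])
    pi_fast = (1.0 - spec.comp_shift) * pi0 + spec.comp_shift * spike
    fast_taxa = frozenset(
        t for t in gene_tree.leaves if spec.clan_of(t) == spec.fast_clan
    )
    below = gene_tree._edges()["below"]

    seqs = {}

    def evolve(node, state):
        if node is not gene_tree._root:
            t = node.length or 0.0
            p_event = 1.0 - np.exp(-rates * t)
            hit = rng.random(length) < p_event
            if hit.any():
                in_fast = bool(fast_taxa) and below[id(node)] <= fast_taxa
                pi = pi_fast if in_fast else pi0
                state = state.copy()
                state[hit] = rng.choice(20, size=int(hit.sum()), p=pi)
        if node.is_leaf:
            seqs[node.label] = state
        else:
            for c in node.children:
                evolve(c, state)

    root_state = rng.choice(20, size=length, p=pi0)
    evolve(gene_tree._root, root_state)
    out = {}
    for taxon in sorted(seqs):
        chars = _AA[seqs[taxon]]
        if spec.gap_fraction > 0:
            gaps = rng.random(length) < spec.gap_fraction
            chars = chars.copy()
            chars[gaps] = b"-"
        out[taxon] = b"".join(chars).decode()
    return Alignment(out)


# --------------------------------------------------------------------------
# Exact-profile construction


class ProfileError(ValueError):
    """A requested per-n profile cannot be realized with the given clans."""


def construct_profile_dataset(
    counts_per_n: Mapping[int, int],
    clans: Sequence[ClanDefinition],
    seed: int | None = None,
) -> dict:
    """Gene trees realizing an exact per-n clan-recovery histogram.

    For each requested n, trees are built that recover exactly n countable
    clans: n randomly chosen clans stay intact as subtrees on a caterpillar
    backbone while the remaining clans' members are interleaved so that no
    single edge can separate them.  Every emitted tree is verified with
    :func:`clan_status` before being returned (hard postcondition).
    """
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    countable = [c for c in clans if c.countable]
    singletons = [c for c in clans if not c.countable]
    m = len(countable)
    for n in counts_per_n:
        if not (0 <= n <= m):
            raise ProfileError(f"cannot recover {n} clans with {m} countable clans")
    trees = {}
    idx = 0
    for n in sorted(counts_per_n, reverse=True):
        for _ in range(counts_per_n[n]):
            idx += 1
            og = f"OG{idx:04d}"
            trees[og] = _profile_tree(n, countable, singletons, rng)
    return trees


def _caterpillar(items: list) -> UnrootedTree:
    """Caterpillar joining subtree items in order, unit branch lengths."""
    tail = items[-1]
    for item in reversed(items[:-1]):
        tail = _Node(None, [item, tail], 1.0, None)
    tail.length = None
    return UnrootedTree(tail)


def _clan_subtree(taxa: Sequence[str]) -> _Node:
    nodes = [_Node(t, None, 1.0, None) for t in taxa]
    if len(nodes) == 1:
        return nodes[0]
    tail = nodes[-1]
    for nd in reversed(nodes[:-1]):
        tail = _Node(None, [nd, tail], 1.0, None)
    return tail


def _profile_tree(
    n: int,
    countable: Sequence[ClanDefinition],
    singletons: Sequence[ClanDefinition],
    rng,
) -> UnrootedTree:
    m = len(countable)
    for _try in range(50):
        order = rng.permutation(m)
        recovered = [countable[k] for k in order[:n]]
        broken = [countable[k] for k in order[n:]]
        block_items = [_clan_subtree(sorted(c.taxa)) for c in recovered]
        block_items += [_Node(t, None, 1.0, None) for c in singletons for t in c.taxa]
        if broken:
            broken_lists = [sorted(c.taxa) for c in broken]
            if len(broken_lists) == 1 and not block_items:
                raise ProfileError(
                    "cannot violate a lone clan with no other taxa present"
                )
            interleaved = _interleave(broken_lists, block_items)
        else:
            interleaved = block_items
        if len(interleaved) < 2:
            raise ProfileError("too few taxa to build a tree")
        tree = _caterpillar(interleaved)
        expect = {c.name: ClanStatus.RECOVERED for c in recovered}
        expect.update({c.name: ClanStatus.VIOLATED for c in broken})
        if all(clan_status(tree, c) is expect[c.name] for c in countable):
            return tree
    raise ProfileError("failed to realize the requested clan profile")


def _interleave(broken_lists: list, block_items: list) -> list:
    """Round-robin the broken clans' members; separate a lone clan with blocks."""
    items = []
    if len(broken_lists) == 1:
        taxa = broken_lists[0]
        items.append(_Node(taxa[0], None, 1.0, None))
        items.extend(block_items)
        items.extend(_Node(t, None, 1.0, None) for t in taxa[1:])
        return items
    k = max(len(lst) for lst in broken_lists)
    for r in range(k):
        for lst in broken_lists:
            if r < len(lst):
                items.append(_Node(lst[r], None, 1.0, None))
    # intact blocks go in the middle so they never touch the caterpillar ends
    mid = len(items) // 2
    return items[:mid] + block_items + items[mid:]


def profile_clans(n_countable: int = 5, clan_size: int = 4) -> list:
    """Generic clan set for profile construction: n countable clans plus a singleton."""
    clans = [
        ClanDefinition(f"Clan{chr(65 + i)}", [f"Clan{chr(65 + i)}_{j + 1}" for j in range(clan_size)])
        for i in range(n_countable)
    ]
    clans.append(ClanDefinition("Singleton", ["Singleton_1"]))
    return clans
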