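"""Clan testing and orthogroup filtering.

A *clan* is the unrooted-tree analogue of a clade: a taxon set that can be
separated from all other leaves by removing a single edge.  Each orthogroup's
gene tree is tested against user-defined "incontestable" clans; a clan is
RECOVERED if the tree realizes it, VIOLATED if it does not, and INSUFFICIENT
if fewer than two of the clan's taxa are present in the tree.  Orthogroups
recovering at least ``min_clans`` clans are retained for supermatrix
construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from orthosignal.treeio import UnrootedTree, _postorder


class ClanConfigError(ValueError):
    """A clan definition is inconsistent with the dataset."""


@dataclass(frozen=True)
class ClanDefinition:
    """A named taxon set whose recovery as a clan is treated as incontestable.

    ``taxa`` is the dataset-wide membership; a clan is *countable* (enters the
    per-orthogroup recovered-clan count) only if it has >= 2 members
    dataset-wide.  A singleton clan (e.g. a phylum represented by one species)
    can never be recovered or violated and is excluded from counts.
    """

    name: str
    taxa: frozenset

    def __init__(self, name: str, taxa: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "taxa", frozenset(taxa))
        if not self.taxa:
            raise ClanConfigError(f"clan {name!r} has no taxa")

    @property
    def countable(self) -> bool:
        return len(self.taxa) >= 2


class ClanStatus(enum.Enum):
    RECOVERED = "recovered"
    VIOLATED = "violated"
    INSUFFICIENT = "insufficient"


def clan_status(
    tree: UnrootedTree,
    clan: ClanDefinition,
    *,
    soft_polytomies: bool = False,
) -> ClanStatus:
    """Status of one clan in one unrooted gene tree.

    Let P be the clan taxa present in the tree and Q the remaining leaves.
    INSUFFICIENT if |P| < 2.  Otherwise RECOVERED iff removing some single
    edge separates exactly P from Q.  If |Q| <= 1 the separation is trivially
    achievable (any single leaf hangs on its own pendant edge), so the status
    is RECOVERED.

    With ``soft_polytomies=True`` a multifurcation is refined in the clan's
    favour: P also counts as recovered if, at some node, P is exactly the
    union of a subset of the subtrees meeting there.  By default an actual
    edge must realize the split, so a polytomy mixing clan and non-clan
    children is VIOLATED.
    """
    present = clan.taxa & tree.leaves
    if len(present) < 2:
        return ClanStatus.INSUFFICIENT
    others = tree.leaves - clan.taxa
    if len(others) <= 1:
        return ClanStatus.RECOVERED
    meta = tree._edges()
    below = meta["below"]
    for node in _postorder(tree._root):
        if node is tree._root:
            continue
        b = below[id(node)]
        # an edge separates P either below it or above it
        if b == present or tree.leaves - b == present:
            return ClanStatus.RECOVERED
    if soft_polytomies:
        # P is a union of components around some node iff every component is
        # inside P or disjoint from it and the inside ones cover P.
        for node in _postorder(tree._root):
            if node.is_leaf:
                continue
            comps = [below[id(c)] for c in node.children]
            if node is not tree._root:
                comps.append(tree.leaves - below[id(node)])
            covered = frozenset()
            ok = True
            for comp in comps:
                inter = comp & present
                if not inter:
                    continue
                if inter != comp:
                    ok = False
                    break
                covered |= comp
            if ok and covered == present:
                return ClanStatus.RECOVERED
    return ClanStatus.VIOLATED


@dataclass
class ClanReport:
    """Per-(orthogroup, clan) statuses plus recovered-clan counts.

    ``n_recovered`` counts RECOVERED statuses over *countable* clans only.
    """

    statuses: dict = field(repr=False)  # (og_id, clan_name) -> ClanStatus
    n_recovered: dict  # og_id -> int
    orthogroups: list
    clans: list  # ClanDefinition, input order

    def histogram(self) -> dict:
        """Number of orthogroups recovering exactly n countable clans."""
        n_countable = sum(1 for c in self.clans if c.countable)
        hist = {n: 0 for n in range(n_countable + 1)}
        for og in self.orthogroups:
            hist[self.n_recovered[og]] += 1
        return hist

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"orthogroup": og, "clan": c.name, "status": self.statuses[(og, c.name)].value}
            for og in self.orthogroups
            for c in self.clans
        ]
        return pd.DataFrame(rows)

    def clan_totals(self) -> pd.DataFrame:
        """Per-clan counts of recovered / violated / insufficient orthogroups."""
        rows = []
        for c in self.clans:
            counts = {s: 0 for s in ClanStatus}
            for og in self.orthogroups:
                counts[self.statuses[(og, c.name)]] += 1
            rows.append(
                {
                    "clan": c.name,
                    "countable": c.countable,
                    "recovered": counts[ClanStatus.RECOVERED],
                    "violated": counts[ClanStatus.VIOLATED],
                    "insufficient": counts[ClanStatus.INSUFFICIENT],
                }
            )
        return pd.DataFrame(rows)


def check_clans(
    trees: Mapping[str, UnrootedTree],
    clans: Sequence[ClanDefinition],
    *,
    soft_polytomies: bool = False,
) -> ClanReport:
    """Test every clan in every gene tree.

    Clans with fewer than two dataset-wide members are still tested and
    reported (they come out INSUFFICIENT everywhere) but never enter the
    per-orthogroup recovered-clan count.
    """
    if not trees:
        raise ValueError("no gene trees supplied")
    if not clans:
        raise ValueError("no clans supplied")
    names = [c.name for c in clans]
    if len(set(names)) != len(names):
        raise ClanConfigError("clan names must be unique")
    dataset_taxa = frozenset().union(*(t.leaves for t in trees.values()))
    for c in clans:
        if not (c.taxa & dataset_taxa):
            raise ClanConfigError(
                f"clan {c.name!r} references no taxon present in the dataset"
            )
    statuses = {}
    n_recovered = {}
    for og, tree in trees.items():
        n = 0
        for c in clans:
            st = clan_status(tree, c, soft_polytomies=soft_polytomies)
            statuses[(og, c.name)] = st
            if c.countable and st is ClanStatus.RECOVERED:
                n += 1
        n_recovered[og] = n
    return ClanReport(statuses, n_recovered, list(trees), list(clans))


def filter_orthogroups(report: ClanReport, min_clans: int = 3) -> list:
    """Orthogroup ids recovering at least ``min_clans`` countable clans.

    The threshold is inclusive; INSUFFICIENT never counts as recovered.
    Input order is preserved.
    """
    if min_clans < 0:
        raise ValueError("min_clans must be >= 0")
    return [og for og in report.orthogroups if report.n_recovered[og] >= min_clans]


# --------------------------------------------------------------------------
# Clan-definition and report I/O


def read_clans(path) -> list:
    """Read clan definitions from a two-column TSV (clan_name<TAB>taxon)."""
    groups: dict[str, set] = {}
    order = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ClanConfigError(f"{path}:{ln}: expected 2 tab-separated fields")
            name, taxon = parts
            if name not in groups:
                groups[name] = set()
                order.append(name)
            groups[name].add(taxon)
    return [ClanDefinition(name, groups[name]) for name in order]


def write_report(report: ClanReport, status_path, histogram_path=None) -> None:
    """Write the orthogroup x clan status TSV and, optionally, the per-n histogram."""
    report.to_frame().to_csv(status_path, sep="\t", index=False)
    if histogram_path is not None:
        hist = report.histogram()
        df = pd.DataFrame(
            {"n_clans_recovered": list(hist), "n_orthogroups": list(hist.values())}
        ).sort_values("n_clans_recovered", ascending=False)
        df.to_csv(histogram_path, sep="\t", index=False)
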