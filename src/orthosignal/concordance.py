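"""Gene and site concordance factors per branch of a species tree.

For a species tree T and a set of gene trees S, the gene concordance factor
(gCF) of a branch x is the percentage of gene trees containing a branch
concordant with x among the gene trees *decisive* for x.  A gene tree is
decisive iff x restricted to that tree's taxa still has >= 2 taxa on each
side; it is concordant iff the restricted bipartition is realized by one of
its own edges.

The site concordance factor (sCF) of x is computed from randomly sampled
quartets around x: one taxon from each of two subtree groups on each side.
A site is decisive for a quartet iff all four residues are present (no gap
or X) and the pattern is parsimony-informative for the quartet (two states,
two-and-two); it is concordant iff the matched pair straddles x as in T.
sCF is the mean over quartets (with >= 1 decisive site) of the per-quartet
concordant-site percentage; sDF1 and sDF2 summarize the two discordant
pairings the same way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from orthosignal.matrix import Supermatrix
from orthosignal.treeio import Bipartition, TreeError, UnrootedTree, edge_decompositions


@dataclass
class BranchConcordance:
    """Concordance summary for one species-tree branch (NaN where undefined)."""

    branch: Bipartition
    gcf: float = math.nan
    gcf_n: int = 0
    gcf_concordant: int = 0
    scf: float = math.nan
    scf_n: int = 0
    sdf1: float = math.nan
    sdf2: float = math.nan


def gene_concordance(T: UnrootedTree, S: list) -> list:
    """gCF per nontrivial branch of ``T`` over the gene-tree set ``S``."""
    if not S:
        raise ValueError("empty gene tree set")
    for g in S:
        extra = g.leaves - T.leaves
        if extra:
            raise TreeError(f"gene tree taxa not in species tree: {sorted(extra)}")
    gene_splits = [(g.leaves, g.bipartitions()) for g in S]
    out = []
    for branch in sorted(T.bipartitions(), key=repr):
        decisive = concordant = 0
        for leaves, splits in gene_splits:
            restricted = branch.restrict(leaves)
            if restricted is None or not restricted.nontrivial:
                continue
            decisive += 1
            if restricted in splits:
                concordant += 1
        bc = BranchConcordance(branch, gcf_n=decisive, gcf_concordant=concordant)
        if decisive > 0:
            bc.gcf = 100.0 * concordant / decisive
        out.append(bc)
    return out


def site_concordance(
    T: UnrootedTree,
    matrix: Supermatrix,
    n_quartets: int = 100,
    seed: int | None = None,
) -> list:
    """sCF per nontrivial branch of ``T`` from ``n_quartets`` sampled quartets.

    Quartets draw one taxon from each of two distinct subtree groups on each
    side of the branch, uniformly with the given seed.  Quartets without any
    decisive site are skipped; a branch where every quartet is skipped (or
    where a side has fewer than two groups with usable taxa) gets NaN.
    """
    if n_quartets < 1:
        raise ValueError("n_quartets must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducible quartet sampling")
    aln = matrix.alignment
    missing = T.leaves - set(aln.taxa)
    if missing:
        raise TreeError(f"matrix lacks species-tree taxa: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    seqs = {t: np.frombuffer(aln[t].encode(), dtype="S1") for t in T.leaves}
    out = []
    decomps = sorted(edge_decompositions(T), key=lambda d: repr(d[0]))
    for branch, below_comps, above_comps in decomps:
        bc = BranchConcordance(branch)
        below_comps = [sorted(c) for c in below_comps if c]
        above_comps = [sorted(c) for c in above_comps if c]
        if len(below_comps) < 2 or len(above_comps) < 2:
            out.append(bc)
            continue
        q_scf, q_sdf1, q_sdf2 = [], [], []
        for _ in range(n_quartets):
            gb = rng.choice(len(below_comps), size=2, replace=False)
            ga = rng.choice(len(above_comps), size=2, replace=False)
            a = below_comps[gb[0]][rng.integers(len(below_comps[gb[0]]))]
            b = below_comps[gb[1]][rng.integers(len(below_comps[gb[1]]))]
            c = above_comps[ga[0]][rng.integers(len(above_comps[ga[0]]))]
            d = above_comps[ga[1]][rng.integers(len(above_comps[ga[1]]))]
            res = _quartet_site_tally(seqs[a], seqs[b], seqs[c], seqs[d])
            if res is None:
                continue
            conc, disc1, disc2, decisive = res
            q_scf.append(100.0 * conc / decisive)
            q_sdf1.append(100.0 * disc1 / decisive)
            q_sdf2.append(100.0 * disc2 / decisive)
        if q_scf:
            bc.scf = float(np.mean(q_scf))
            bc.sdf1 = float(np.mean(q_sdf1))
            bc.sdf2 = float(np.mean(q_sdf2))
            bc.scf_n = len(q_scf)
        out.append(bc)
    return out


def _quartet_site_tally(sa, sb, sc, sd):
    """(concordant, discordant-ac|bd, discordant-ad|bc, decisive) or None."""
    ok = np.ones(len(sa), dtype=bool)
    for s in (sa, sb, sc, sd):
        ok &= (s != b"-") & (s != b"X")
    a, b, c, d = sa[ok], sb[ok], sc[ok], sd[ok]
    # two states, two-and-two -> exactly one of the three pairings matches
    ab = a == b
    cd = c == d
    ac = a == c
    bd = b == d
    ad = a == d
    bc = b == c
    conc = ab & cd & ~ac
    disc1 = ac & bd & ~ab
    disc2 = ad & bc & ~ab & ~ac
    n_conc = int(conc.sum())
    n_d1 = int(disc1.sum())
    n_d2 = int(disc2.sum())
    decisive = n_conc + n_d1 + n_d2
    if decisive == 0:
        return None
    return n_conc, n_d1, n_d2, decisive


def concordance_frame(rows: list) -> pd.DataFrame:
    """TSV-ready frame: one row per species-tree branch."""
    recs = []
    for bc in rows:
        recs.append(
            {
                "branch": repr(bc.branch),
                "gcf": bc.gcf,
                "gcf_n": bc.gcf_n,
                "gcf_concordant": bc.gcf_concordant,
                "scf": bc.scf,
                "scf_n": bc.scf_n,
                "sdf1": bc.sdf1,
                "sdf2": bc.sdf2,
            }
        )
    return pd.DataFrame(recs)
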