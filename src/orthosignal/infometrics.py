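"""Per-orthogroup phylogenetic-information and compositional-bias metrics.

Implements the sequence- and tree-based criteria commonly used to compare
orthogroups that pass or fail a quality filter: alignment length, variable
and parsimony-informative sites, mean bipartition support, long-branch
scores, saturation, treeness / RCV, RCFV, and the chi-square test of
compositional homogeneity, plus a Wilcoxon rank-sum comparison of pass/fail
groups.

Conventions used throughout: gaps and the ambiguity code ``X`` are excluded
from state counts and frequency computations; pairwise p-distances ignore
columns with a gap or ``X`` in either sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from orthosignal.matrix import AMINO_ACIDS, Alignment
from orthosignal.treeio import UnrootedTree

_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")


@dataclass
class OrthogroupMetrics:
    """One orthogroup's information and bias metrics (NaN where undefined)."""

    alignment_length: int
    variable_sites: int
    parsimony_informative_sites: int
    mean_bipartition_support: float
    mean_long_branch_score: float
    upper_decile_long_branch_score: float
    saturation: float
    treeness: float
    rcv: float
    treeness_over_rcv: float
    rcfv: float
    chi2_stat: float
    chi2_df: float
    chi2_p: float


# --------------------------------------------------------------------------
# Site counts


def site_counts(aln: Alignment) -> tuple[int, int, int]:
    """(variable sites, parsimony-informative sites, alignment length).

    A column is variable if it shows >= 2 distinct residues (gaps and X
    excluded); parsimony-informative if >= 2 residues each occur in >= 2
    sequences.
    """
    variable = informative = 0
    for col in aln.columns():
        counts: dict[str, int] = {}
        for ch in col:
            if ch in ("-", "X"):
                continue
            counts[ch] = counts.get(ch, 0) + 1
        if len(counts) >= 2:
            variable += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                informative += 1
    return variable, informative, aln.length


# --------------------------------------------------------------------------
# Composition


def _freq_matrix(aln: Alignment) -> tuple[list, np.ndarray]:
    """Per-taxon residue frequencies over non-gap, non-X sites.

    Taxa with zero countable residues are excluded (with a warning upstream).
    """
    arr = aln.to_array()
    taxa = aln.taxa
    counts = np.stack([(arr == aa).sum(axis=1) for aa in _AA_BYTES], axis=1).astype(float)
    totals = counts.sum(axis=1)
    keep = totals > 0
    kept_taxa = [t for t, k in zip(taxa, keep) if k]
    freqs = counts[keep] / totals[keep, None]
    return kept_taxa, freqs


def rcfv(aln: Alignment) -> float:
    """Relative composition frequency variability.

    RCFV = sum over the 20 states and n taxa of |f_ij - fbar_j| / n, with
    f_ij taxon i's frequency of state j over its non-gap sites and fbar_j the
    across-taxon mean.  Zero iff all rows have identical composition.
    """
    if len(aln.taxa) < 2:
        raise ValueError("rcfv needs >= 2 taxa")
    _, freqs = _freq_matrix(aln)
    mean = freqs.mean(axis=0)
    return float(np.abs(freqs - mean).sum() / freqs.shape[0])


def chi2_homogeneity(aln: Alignment) -> tuple[float, float, float]:
    """Contingency chi-square of per-taxon residue counts vs pooled expectation.

    Returns (stat, df, p); (nan, nan, nan) for degenerate tables (a single
    observed state).  df = (n_taxa - 1)(n_observed_states - 1).
    """
    if len(aln.taxa) < 2:
        raise ValueError("chi2_homogeneity needs >= 2 taxa")
    arr = aln.to_array()
    counts = np.stack([(arr == aa).sum(axis=1) for aa in _AA_BYTES], axis=1).astype(float)
    counts = counts[counts.sum(axis=1) > 0]
    counts = counts[:, counts.sum(axis=0) > 0]
    if counts.shape[1] < 2 or counts.shape[0] < 2:
        return (math.nan, math.nan, math.nan)
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), float(df), float(p)


# --------------------------------------------------------------------------
# Tree-based metrics


def treeness_rcv(tree: UnrootedTree, aln: Alignment) -> tuple[float, float, float]:
    """(treeness, RCV, treeness/RCV).

    treeness = internal branch length / total branch length; RCV is the mean
    absolute deviation of per-taxon residue *counts* from their across-taxon
    mean, scaled by taxon count times alignment length.  The ratio is NaN
    when RCV is zero (identical compositions) and treeness is NaN for a
    zero-length tree.
    """
    total = tree.total_length()
    treeness = tree.internal_length() / total if total > 0 else math.nan
    arr = aln.to_array()
    counts = np.stack([(arr == aa).sum(axis=1) for aa in _AA_BYTES], axis=1).astype(float)
    mean = counts.mean(axis=0)
    n_taxa = len(aln.taxa)
    rcv = float(np.abs(counts - mean).sum() / (n_taxa * aln.length))
    ratio = treeness / rcv if rcv > 0 else math.nan
    return treeness, rcv, ratio


def long_branch_scores(tree: UnrootedTree) -> tuple[dict, float]:
    """Per-taxon long-branch scores and their mean.

    LB_i = 100 * (mean patristic distance from taxon i to all others /
    grand mean pairwise patristic distance - 1).  Values are centred: taxa on
    long branches score positive, the rest slightly negative, and the plain
    mean is ~0 by construction, so the distribution's tail carries the
    signal (see :func:`upper_decile_mean`).
    """
    labels, m = tree.patristic_matrix()
    n = len(labels)
    if n < 2:
        raise ValueError("long branch scores need >= 2 taxa")
    row_means = m.sum(axis=1) / (n - 1)
    grand = m.sum() / (n * (n - 1))
    if grand == 0:
        raise ValueError("zero total tree length")
    per = {lab: 100.0 * (rm / grand - 1.0) for lab, rm in zip(labels, row_means)}
    return per, float(np.mean(list(per.values())))


def upper_decile_mean(scores: dict) -> float:
    """Mean of the top 10% of long-branch scores (at least one taxon)."""
    vals = sorted(scores.values(), reverse=True)
    k = max(1, len(vals) // 10)
    return float(np.mean(vals[:k]))


def _p_distances(aln: Alignment, labels: Sequence[str]) -> np.ndarray:
    """Uncorrected pairwise p-distances; columns with gap/X in either row skipped."""
    arr = {t: np.frombuffer(aln[t].encode(), dtype="S1") for t in labels}
    bad = {t: (arr[t] == b"-") | (arr[t] == b"X") for t in labels}
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(bad[labels[i]] | bad[labels[j]])
            tot = int(ok.sum())
            if tot == 0:
                m[i, j] = m[j, i] = np.nan
                continue
            diff = int((arr[labels[i]][ok] != arr[labels[j]][ok]).sum())
            m[i, j] = m[j, i] = diff / tot
    return m


def saturation(tree: UnrootedTree, aln: Alignment) -> float:
    """Slope of the through-origin regression of p-distance on patristic distance.

    A slope of 1 means no saturation; smaller slopes mean pairwise identity
    has plateaued relative to the inferred amount of change.
    """
    labels, pat = tree.patristic_matrix()
    pdist = _p_distances(aln, labels)
    iu = np.triu_indices(len(labels), k=1)
    x, y = pat[iu], pdist[iu]
    ok = ~np.isnan(y)
    x, y = x[ok], y[ok]
    sxx = float((x * x).sum())
    if sxx == 0:
        return math.nan
    return float((x * y).sum() / sxx)


def mean_bipartition_support(tree: UnrootedTree) -> float:
    """Arithmetic mean of internal-edge support values; NaN if none present."""
    sup = tree.internal_supports()
    if not sup:
        return math.nan
    return float(np.mean(sup))


# --------------------------------------------------------------------------
# Assembly and group comparison


def compute_metrics(aln: Alignment, tree: UnrootedTree) -> OrthogroupMetrics:
    """All metrics for one orthogroup's alignment + gene tree."""
    var, pis, length = site_counts(aln)
    tness, rcv_val, ratio = treeness_rcv(tree, aln)
    try:
        per_lb, mean_lb = long_branch_scores(tree)
        ud_lb = upper_decile_mean(per_lb)
    except ValueError:
        mean_lb = ud_lb = math.nan
    sat = saturation(tree, aln) if tree.has_branch_lengths() else math.nan
    chi_stat, chi_df, chi_p = chi2_homogeneity(aln)
    return OrthogroupMetrics(
        alignment_length=length,
        variable_sites=var,
        parsimony_informative_sites=pis,
        mean_bipartition_support=mean_bipartition_support(tree),
        mean_long_branch_score=mean_lb,
        upper_decile_long_branch_score=ud_lb,
        saturation=sat,
        treeness=tness,
        rcv=rcv_val,
        treeness_over_rcv=ratio,
        rcfv=rcfv(aln),
        chi2_stat=chi_stat,
        chi2_df=chi_df,
        chi2_p=chi_p,
    )


_STAR_THRESHOLDS = [(0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*")]


def significance_stars(p: float) -> str:
    for threshold, stars in _STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return "ns"


def compare_groups(
    passed: Sequence[OrthogroupMetrics], failed: Sequence[OrthogroupMetrics]
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per metric between pass/fail groups.

    Returns one row per metric with group medians, the Mann-Whitney U
    statistic, p-value, and significance stars at the 0.05 / 0.01 / 0.001 /
    0.0001 thresholds.
    """
    if not passed or not failed:
        raise ValueError("both groups must be nonempty")
    dfp = pd.DataFrame([vars(m) for m in passed])
    dff = pd.DataFrame([vars(m) for m in failed])
    rows = []
    for metric in dfp.columns:
        a = dfp[metric].dropna().to_numpy(dtype=float)
        b = dff[metric].dropna().to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            continue
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            stat, p = math.nan, 1.0
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "metric": metric,
                "median_pass": float(np.median(a)),
                "median_fail": float(np.median(b)),
                "statistic": float(stat),
                "p_value": float(p),
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)


def metrics_frame(metrics: dict) -> pd.DataFrame:
    """Wide TSV-ready frame: one row per orthogroup id."""
    rows = []
    for og, m in metrics.items():
        row = {"orthogroup": og}
        row.update(vars(m))
        rows.append(row)
    return pd.DataFrame(rows)
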