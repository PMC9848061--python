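"""Posterior-predictive test statistics and |Z|-score model-adequacy verdicts.

Three alignment statistics are computed internally: mean per-site amino-acid
diversity (DIV) and the maximum / mean per-taxon compositional heterogeneity
(MAX / MEAN).  Observed values are compared with a replicate distribution via
|Z| = |observed - replicate mean| / replicate sd; |Z| < 2 is read as adequate
model fit, |Z| > 5 as strong rejection, anything between as intermediate
(both inequalities strict).

CONV and VAR statistics are accepted only as externally supplied
observed/replicate values (their formulas live in the MCMC software that
produces them), so external posterior-predictive output can be scored with
the same rule.

The built-in replicate generator simulates under a site- and
lineage-homogeneous null (i.i.d. residues at the template's non-gap
positions, pooled state frequencies).  It stands in for model-based
simulation when only the composition-level adequacy of a matrix is being
screened; it is not a substitute for posterior simulation under a fitted
phylogenetic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from orthosignal.matrix import AMINO_ACIDS, Alignment, Supermatrix

_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")


@dataclass
class PPAStatistic:
    """One statistic's observed value, replicate summary, |Z| and verdict."""

    name: str
    observed: float
    sim_mean: float
    sim_sd: float
    z: float
    verdict: str  # adequate | intermediate | rejected


def _residue_mask(arr: np.ndarray) -> np.ndarray:
    return (arr != b"-") & (arr != b"X")


def stat_div(aln: Alignment | np.ndarray) -> float:
    """Mean over columns of the number of distinct residues (gaps/X excluded).

    Ranges from 1 (constant columns) to 20 (every column shows all residues).
    """
    arr = aln.to_array() if isinstance(aln, Alignment) else aln
    if arr.shape[1] == 0:
        raise ValueError("alignment has zero columns")
    present = np.stack([(arr == aa).any(axis=0) for aa in _AA_BYTES])
    counts = present.sum(axis=0)
    informative = counts > 0  # all-gap columns carry no residues
    if not informative.any():
        raise ValueError("no column contains a residue")
    return float(counts[informative].mean())


def stat_comp_hetero(aln: Alignment | np.ndarray) -> tuple[float, float]:
    """(max, mean) per-taxon compositional heterogeneity.

    h_i = sum over the 20 states of |f_ij - fbar_j| with f the non-gap
    residue frequencies; each h_i lies in [0, 2].
    """
    arr = aln.to_array() if isinstance(aln, Alignment) else aln
    if arr.shape[0] < 2:
        raise ValueError("need >= 2 taxa")
    counts = np.stack([(arr == aa).sum(axis=1) for aa in _AA_BYTES], axis=1).astype(float)
    totals = counts.sum(axis=1)
    keep = totals > 0
    freqs = counts[keep] / totals[keep, None]
    mean = freqs.mean(axis=0)
    h = np.abs(freqs - mean).sum(axis=1)
    return float(h.max()), float(h.mean())


def zscore(observed: float, replicates: list, name: str = "STAT") -> PPAStatistic:
    """Score an observed statistic against its replicate distribution.

    The replicate sd uses the n-1 denominator.  Verdict: adequate iff
    |Z| < 2, rejected iff |Z| > 5, else intermediate (strict inequalities).
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 2:
        raise ValueError("need >= 2 replicates")
    mean = float(reps.mean())
    sd = float(reps.std(ddof=1))
    if sd == 0:
        raise ValueError(
            "replicate distribution has zero spread (degenerate simulation)"
        )
    z = abs(observed - mean) / sd
    if z < 2:
        verdict = "adequate"
    elif z > 5:
        verdict = "rejected"
    else:
        verdict = "intermediate"
    return PPAStatistic(name, float(observed), mean, sd, float(z), verdict)


def null_replicates(
    template: Supermatrix | Alignment, n: int, seed: int | None = None
) -> dict:
    """DIV/MAX/MEAN values on ``n`` matrices simulated under the homogeneous null.

    Each replicate keeps the template's gap/X pattern and redraws every
    residue i.i.d. from the template's pooled non-gap state frequencies, so
    any site- or lineage-structure in the observed statistics shows up as a
    large |Z| against these replicates.
    """
    if n < 2:
        raise ValueError("need n >= 2 replicates")
    if seed is None:
        raise ValueError("a seed is required")
    aln = template.alignment if isinstance(template, Supermatrix) else template
    arr = aln.to_array()
    mask = _residue_mask(arr)
    counts = np.array([(arr == aa).sum() for aa in _AA_BYTES], dtype=float)
    if counts.sum() == 0:
        raise ValueError("template contains no residues")
    probs = counts / counts.sum()
    rng = np.random.default_rng(seed)
    out = {"DIV": [], "MAX": [], "MEAN": []}
    for _ in range(n):
        rep = np.full(arr.shape, b"-", dtype="S1")
        k = int(mask.sum())
        rep[mask] = _AA_BYTES[rng.choice(20, size=k, p=probs)]
        out["DIV"].append(stat_div(rep))
        mx, mn = stat_comp_hetero(rep)
        out["MAX"].append(mx)
        out["MEAN"].append(mn)
    return out


def assess_model_fit(
    observed: Supermatrix | Alignment, n_replicates: int = 100, seed: int | None = None
) -> list:
    """Observed DIV/MAX/MEAN scored against homogeneous-null replicates."""
    aln = observed.alignment if isinstance(observed, Supermatrix) else observed
    reps = null_replicates(aln, n_replicates, seed)
    obs_div = stat_div(aln)
    obs_max, obs_mean = stat_comp_hetero(aln)
    return [
        zscore(obs_div, reps["DIV"], "DIV"),
        zscore(obs_max, reps["MAX"], "MAX"),
        zscore(obs_mean, reps["MEAN"], "MEAN"),
    ]


def read_replicate_values(path) -> list:
    """Read one replicate value per line (e.g. exported MCMC posterior-predictive runs)."""
    vals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                vals.append(float(line))
    return vals


def results_frame(stats: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "statistic": s.name,
                "observed": s.observed,
                "sim_mean": s.sim_mean,
                "sim_sd": s.sim_sd,
                "z": s.z,
                "verdict": s.verdict,
            }
            for s in stats
        ]
    )
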