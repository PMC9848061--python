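"""Three-way alignment selection: distance test, column-score tie-break, seeded pick.

Given three candidate alignments of the same sequences (e.g. from three
aligners), all pairwise alignment distances are computed with a
homology-statement metric that accounts for the positional information of
gaps.  If any pair's distance reaches the threshold (default 0.15, strict
agreement requires < threshold) the candidates are judged mutually
discordant and the one with the highest column-based similarity score wins;
otherwise the candidates agree and one is picked uniformly at random with
the given seed.

The distance approximates the positional-gap flavour of published alignment
metrics: it is pluggable, so a strict external implementation can be
substituted.  The column score is a normalized mean sum-of-pairs similarity
under BLOSUM62 and is labelled as such in the rationale output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from orthosignal.matrix import GAP, Alignment

_BLOSUM = substitution_matrices.load("BLOSUM62")
_STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"
_BLO_VALUES = [
    float(_BLOSUM[a, b]) for a in _STANDARD_AAS for b in _STANDARD_AAS
]
_BLO_MIN = min(_BLO_VALUES)
_BLO_MAX = max(_BLO_VALUES)


class AlignmentChoiceError(ValueError):
    pass


@dataclass
class AlignmentChoiceConfig:
    """Parameters of the selection rule.

    ``distance_threshold``: pairwise distance below which two alignments are
    judged to agree (strict; a distance equal to the threshold is discord).
    """

    distance_threshold: float = 0.15
    seed: int | None = None
    distance_metric: str = "pair_homology"
    column_score: str = "normalized_sum_of_pairs"

    def __post_init__(self):
        if not (0.0 < self.distance_threshold < 1.0):
            raise AlignmentChoiceError("distance_threshold must be in (0, 1)")


def _homology_statements(aln: Alignment) -> set:
    """Set of homology statements implied by an alignment.

    For every unordered sequence pair and every column: an aligned
    residue-residue statement identifies the two residues by their ungapped
    indices; a residue-gap statement is tagged with the gap's column index,
    so shifting a gap changes the statement set (the positional-gap
    component of the metric).
    """
    taxa = sorted(aln.taxa)
    cols = {t: np.asarray([c != GAP for c in aln[t]]) for t in taxa}
    # ungapped residue index at each column (valid only where not gap)
    ridx = {t: np.cumsum(cols[t]) - 1 for t in taxa}
    statements = set()
    for i, s in enumerate(taxa):
        for t in taxa[i + 1 :]:
            rs, rt = cols[s], cols[t]
            for j in range(aln.length):
                if rs[j] and rt[j]:
                    statements.add((s, int(ridx[s][j]), t, int(ridx[t][j])))
                elif rs[j]:
                    statements.add((s, int(ridx[s][j]), t, "gap", j))
                elif rt[j]:
                    statements.add((t, int(ridx[t][j]), s, "gap", j))
    return statements


def _check_same_sequences(a: Alignment, b: Alignment) -> None:
    if set(a.taxa) != set(b.taxa):
        raise AlignmentChoiceError("candidate alignments must share taxa")
    for t in a.taxa:
        if a[t].replace(GAP, "") != b[t].replace(GAP, ""):
            raise AlignmentChoiceError(
                f"ungapped sequence of taxon {t!r} differs between candidates"
            )


def alignment_distance(a: Alignment, b: Alignment) -> float:
    """Distance in [0, 1] between two alignments of the same sequences.

    1 - |H_a intersect H_b| / max(|H_a|, |H_b|) over homology-statement
    sets; zero iff the statement sets are identical.
    """
    _check_same_sequences(a, b)
    ha, hb = _homology_statements(a), _homology_statements(b)
    denom = max(len(ha), len(hb))
    if denom == 0:
        return 0.0
    return 1.0 - len(ha & hb) / denom


def column_similarity_score(aln: Alignment) -> float:
    """Mean over columns of normalized sum-of-pairs BLOSUM62 similarity.

    Each residue pair's score is mapped to [0, 1] by the table's min/max;
    pairs involving a gap (or X, absent from the table) score 0.
    """
    taxa = aln.taxa
    if len(taxa) < 2:
        raise AlignmentChoiceError("need >= 2 sequences")
    span = _BLO_MAX - _BLO_MIN
    total = 0.0
    n_pairs = len(taxa) * (len(taxa) - 1) // 2
    for col in aln.columns():
        col_score = 0.0
        for i in range(len(col)):
            if col[i] == GAP:
                continue
            if col[i] not in _STANDARD_AAS:
                continue
            for j in range(i + 1, len(col)):
                if col[j] == GAP or col[j] not in _STANDARD_AAS:
                    continue
                s = float(_BLOSUM[col[i], col[j]])
                col_score += (s - _BLO_MIN) / span
        total += col_score / n_pairs
    return total / aln.length


@dataclass
class ChoiceRationale:
    """Record of the decision: distances, scores, and which rule fired."""

    distances: dict
    rule: str  # "agreement" | "discordance"
    scores: dict = field(default_factory=dict)
    chosen: int = -1


def select_alignment(
    candidates: list, cfg: AlignmentChoiceConfig
) -> tuple[int, ChoiceRationale]:
    """Pick one of exactly three candidate alignments.

    All pairwise distances strictly below the threshold -> seeded uniform
    random choice (agreement).  Otherwise the candidate with the highest
    column similarity score wins, ties broken by input order (discordance).
    """
    if len(candidates) != 3:
        raise AlignmentChoiceError("exactly three candidate alignments expected")
    dists = {}
    for i in range(3):
        for j in range(i + 1, 3):
            dists[(i, j)] = alignment_distance(candidates[i], candidates[j])
    agree = all(d < cfg.distance_threshold for d in dists.values())
    if agree:
        if cfg.seed is None:
            raise AlignmentChoiceError("a seed is required for the agreement branch")
        rng = np.random.default_rng(cfg.seed)
        chosen = int(rng.integers(3))
        rationale = ChoiceRationale(dists, "agreement", {}, chosen)
        return chosen, rationale
    scores = {i: column_similarity_score(candidates[i]) for i in range(3)}
    chosen = max(range(3), key=lambda i: (scores[i], -i))
    rationale = ChoiceRationale(dists, "discordance", scores, chosen)
    return chosen, rationale
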