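"""Alignment I/O, supermatrix concatenation, constant-site removal, subsetting.

Amino-acid alignments only: sequences over the 20 one-letter residue codes
plus the gap character ``-`` and the ambiguity code ``X``.  File I/O (FASTA
and relaxed PHYLIP) goes through biopython; everything downstream operates on
the validated :class:`Alignment` container.

Partition coordinates are 1-based inclusive in files (the RAxML convention)
and 0-based half-open internally; :func:`Supermatrix.partition_slices` is the
single converter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
AMBIGUOUS = "X"
_ALLOWED = frozenset(AMINO_ACIDS + GAP + AMBIGUOUS)


class AlignmentError(ValueError):
    """Structurally invalid alignment input."""


class Alignment:
    """A fixed-length amino-acid multiple sequence alignment.

    Rows are keyed by unique taxon names; all sequences have equal length.
    """

    def __init__(self, sequences: Mapping[str, str], *, strict: bool = True):
        if not sequences:
            raise AlignmentError("alignment has no sequences")
        self._seqs = {t: str(s).upper() for t, s in sequences.items()}
        lengths = {len(s) for s in self._seqs.values()}
        if len(lengths) != 1:
            ragged = [t for t, s in self._seqs.items() if len(s) != len(next(iter(self._seqs.values())))]
            raise AlignmentError(f"unequal sequence lengths (e.g. taxon {ragged[-1]!r})")
        self.length = lengths.pop()
        if self.length < 1:
            raise AlignmentError("alignment length must be >= 1")
        if strict:
            for t, s in self._seqs.items():
                bad = set(s) - _ALLOWED
                if bad:
                    raise AlignmentError(
                        f"illegal characters {sorted(bad)} in sequence of taxon {t!r}"
                    )

    @property
    def taxa(self) -> list:
        return list(self._seqs)

    @property
    def sequences(self) -> dict:
        return dict(self._seqs)

    def __len__(self) -> int:
        return self.length

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._seqs

    def __getitem__(self, taxon: str) -> str:
        return self._seqs[taxon]

    def __eq__(self, other) -> bool:
        return isinstance(other, Alignment) and self._seqs == other._seqs

    def to_array(self) -> np.ndarray:
        """Rows in ``taxa`` order, one byte per residue (``S1`` dtype)."""
        return np.array([list(s) for s in self._seqs.values()], dtype="S1")

    def columns(self) -> Iterable[str]:
        arr = self.to_array()
        for j in range(self.length):
            yield b"".join(arr[:, j]).decode()

    def select_columns(self, keep: Iterable[int]) -> "Alignment":
        keep = list(keep)
        return Alignment(
            {t: "".join(s[j] for j in keep) for t, s in self._seqs.items()}
        )


# --------------------------------------------------------------------------
# I/O


def _from_biopython(msa, *, strict: bool) -> Alignment:
    seqs = {}
    for rec in msa:
        if rec.id in seqs:
            raise AlignmentError(f"duplicate taxon {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return Alignment(seqs, strict=strict)


def read_alignment(path, format: str = "fasta", *, strict: bool = True) -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment file."""
    if format == "fasta":
        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise AlignmentError(f"duplicate taxon {rec.id!r}")
            seqs[rec.id] = str(rec.seq)
        if not seqs:
            raise AlignmentError(f"no sequences found in {path}")
        return Alignment(seqs, strict=strict)
    if format == "phylip":
        msa = AlignIO.read(str(path), "phylip-relaxed")
        return _from_biopython(msa, strict=strict)
    raise ValueError(f"unknown alignment format {format!r}")


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in aln.sequences.items()
    ]
    if format == "fasta":
        SeqIO.write(records, str(path), "fasta")
    elif format == "phylip":
        AlignIO.write(MultipleSeqAlignment(records), str(path), "phylip-relaxed")
    else:
        raise ValueError(f"unknown alignment format {format!r}")


# --------------------------------------------------------------------------
# Supermatrix


@dataclass
class Supermatrix:
    """Concatenated alignment with partition coordinates.

    ``partitions`` holds (name, start, end) with 1-based inclusive
    coordinates tiling 1..length; ``site_map`` (present after constant-site
    removal) maps retained original 0-based columns to new columns.
    """

    alignment: Alignment
    partitions: list
    site_map: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        pos = 1
        for name, start, end in self.partitions:
            if start != pos or end < start - 1:
                raise AlignmentError(
                    f"partitions must tile 1..length; {name!r} starts at {start}, expected {pos}"
                )
            pos = end + 1
        if pos != self.alignment.length + 1:
            raise AlignmentError("partitions do not cover the full alignment")

    def partition_slices(self) -> list:
        """(name, python slice) per partition — the 1-based -> 0-based converter."""
        return [(name, slice(start - 1, end)) for name, start, end in self.partitions]

    @property
    def occupancy(self) -> dict:
        """Fraction of non-gap sites per taxon."""
        return {
            t: 1.0 - s.count(GAP) / self.alignment.length
            for t, s in self.alignment.sequences.items()
        }

    def write_partitions(self, path, model: str = "AUTO") -> None:
        """RAxML-style partition file: ``MODEL, name = start-end``."""
        with open(path, "w") as fh:
            for name, start, end in self.partitions:
                fh.write(f"{model}, {name} = {start}-{end}\n")

    def write_occupancy(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\toccupancy\n")
            for t, v in sorted(self.occupancy.items()):
                fh.write(f"{t}\t{v:.6f}\n")


def concatenate(orthogroups: Mapping[str, Alignment]) -> Supermatrix:
    """Concatenate orthogroup alignments over the union of their taxa.

    A taxon absent from an orthogroup is gap-filled across that partition.
    Each orthogroup must have at most one sequence per taxon (enforced by
    :class:`Alignment`); partition order follows input order.
    """
    if not orthogroups:
        raise AlignmentError("no orthogroups to concatenate")
    taxa: list[str] = []
    seen = set()
    for aln in orthogroups.values():
        for t in aln.taxa:
            if t not in seen:
                seen.add(t)
                taxa.append(t)
    parts = []
    chunks: dict[str, list] = {t: [] for t in taxa}
    pos = 1
    for name, aln in orthogroups.items():
        for t in taxa:
            chunks[t].append(aln[t] if t in aln else GAP * aln.length)
        parts.append((name, pos, pos + aln.length - 1))
        pos += aln.length
    merged = Alignment({t: "".join(chunks[t]) for t in taxa})
    return Supermatrix(merged, parts)


def _is_constant(column: str) -> bool:
    """Gap-insensitive constancy; ``X`` is non-informative.

    A column whose non-gap residues are one state (possibly plus X's), or
    which contains no residue at all, counts as constant.
    """
    states = {ch for ch in column if ch not in (GAP, AMBIGUOUS)}
    return len(states) <= 1


def remove_constant_sites(matrix: Supermatrix) -> Supermatrix:
    """Drop constant columns, re-mapping partition coordinates.

    Partitions emptied entirely are kept with zero width removed -- they
    simply vanish from the coordinate list.  The old->new site map is stored
    on the result.  The operation is idempotent.
    """
    aln = matrix.alignment
    arr = aln.to_array()
    keep = []
    for j in range(aln.length):
        col = b"".join(arr[:, j]).decode()
        if not _is_constant(col):
            keep.append(j)
    if not keep:
        raise AlignmentError("all sites are constant; nothing would remain")
    site_map = {old: new for new, old in enumerate(keep)}
    new_parts = []
    pos = 1
    for name, sl in matrix.partition_slices():
        width = sum(1 for j in keep if sl.start <= j < sl.stop)
        if width:
            new_parts.append((name, pos, pos + width - 1))
            pos += width
    return Supermatrix(aln.select_columns(keep), new_parts, site_map)


def subset_taxa(obj, keep: Iterable[str]):
    """Restrict a Supermatrix, Alignment, or mapping of Alignments to ``keep``.

    Columns are untouched.  For orthogroup mappings, orthogroups whose
    remaining taxa number < 4 (tree-undefined) are returned in the second
    element of the tuple.
    """
    keep = frozenset(keep)
    if not keep:
        raise AlignmentError("keep set is empty")
    if isinstance(obj, Supermatrix):
        sub = subset_taxa(obj.alignment, keep)
        return Supermatrix(sub, list(obj.partitions), obj.site_map)
    if isinstance(obj, Alignment):
        kept = {t: s for t, s in obj.sequences.items() if t in keep}
        if not kept:
            raise AlignmentError("keep set is disjoint from alignment taxa")
        return Alignment(kept)
    # mapping of orthogroup alignments
    out = {}
    flagged = []
    for name, aln in obj.items():
        kept = {t: s for t, s in aln.sequences.items() if t in keep}
        if not kept:
            flagged.append(name)
            continue
        sub = Alignment(kept)
        out[name] = sub
        if len(kept) < 4:
            flagged.append(name)
    if not out:
        raise AlignmentError("keep set is disjoint from all orthogroups")
    return out, flagged
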