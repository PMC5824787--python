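"""Protein family ingest, pairwise identity, and inclusion filtering.

The entry point of the library-design pipeline: read a protein family,
measure global-alignment identity of every member to a designated reference
(here, the engineering target, e.g. human SIRT6's deacetylase domain), and
drop members that are too close, too distant, or truncated.  The identity
band keeps homologs that are informative about the target's history without
being redundant copies of it.

Identity is defined as identical residues divided by aligned columns,
terminal gap columns excluded, taken from one optimal Needleman–Wunsch
global alignment (BLOSUM62, gap open 11, extend 1, by default).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

VALID_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SequenceRecord:
    """An unaligned protein sequence (20-letter alphabet plus 'X')."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FilterConfig:
    """Family inclusion filters.

    min_identity/max_identity bound the identity-to-reference fraction;
    min_length_fraction defines "truncated" (length below this fraction of
    the reference length).
    """

    min_identity: float = 0.45
    max_identity: float = 0.95
    min_length_fraction: float = 0.80

    def __post_init__(self) -> None:
        if not (0 <= self.min_identity < self.max_identity <= 1):
            raise ValueError("need 0 <= min_identity < max_identity <= 1")
        if not (0 < self.min_length_fraction <= 1):
            raise ValueError("need 0 < min_length_fraction <= 1")


@dataclass
class AlignedFamily:
    """An aligned family with a designated reference/target sequence.

    records: (id, aligned sequence) pairs, all the same length, '-' gaps.
    column_to_ref maps 1-based alignment columns to 1-based reference
    residue numbers (columns gapped in the reference are absent).
    """

    ids: list
    sequences: list
    reference_id: str
    column_to_ref: dict = field(init=False)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("aligned sequences have unequal lengths")
        if self.reference_id not in self.ids:
            raise ValueError(f"reference {self.reference_id!r} not in family")
        ref = self.sequences[self.ids.index(self.reference_id)]
        mapping, pos = {}, 0
        for col, aa in enumerate(ref, start=1):
            if aa != "-":
                pos += 1
                mapping[col] = pos
        self.column_to_ref = mapping

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @property
    def reference_sequence(self) -> str:
        return self.sequences[self.ids.index(self.reference_id)]

    def row(self, seq_id: str) -> str:
        return self.sequences[self.ids.index(seq_id)]

    def ref_position_to_column(self, position: int) -> int:
        """Inverse of column_to_ref (1-based reference residue -> column)."""
        for col, pos in self.column_to_ref.items():
            if pos == position:
                return col
        raise KeyError(f"reference position {position} not in alignment")

    def ungapped(self, seq_id: str) -> SequenceRecord:
        return SequenceRecord(seq_id, self.row(seq_id).replace("-", ""))


def _aligner(matrix_name: str = "BLOSUM62", gap_open: float = 11.0,
             gap_extend: float = 1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    matrix = substitution_matrices.load(matrix_name)
    # 'X' scores 0 against everything, including itself
    m = matrix.copy()
    if "X" in m.alphabet:
        for aa in m.alphabet:
            m["X", aa] = 0.0
            m[aa, "X"] = 0.0
    aligner.substitution_matrix = m
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aligner.mode = "global"
    return aligner


def global_identity(a: SequenceRecord, b: SequenceRecord,
                    matrix: str = "BLOSUM62", gap_open: float = 11.0,
                    gap_extend: float = 1.0) -> float:
    """Fraction of identical residues over aligned columns, terminal gaps excluded.

    One optimal global alignment is computed; the first alignment returned by
    the dynamic program is used, which is deterministic for a given input.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a.sequence, b.sequence)[0]
    sa, sb = str(aln[0]), str(aln[1])
    # trim terminal gap columns (gap in either row at either end)
    start = 0
    while start < len(sa) and (sa[start] == "-" or sb[start] == "-"):
        start += 1
    end = len(sa)
    while end > start and (sa[end - 1] == "-" or sb[end - 1] == "-"):
        end -= 1
    if end <= start:
        return 0.0
    cols = end - start
    matches = sum(1 for x, y in zip(sa[start:end], sb[start:end]) if x == y and x != "-")
    return matches / cols


def filter_family(records: list, reference_id: str,
                  cfg: FilterConfig = FilterConfig()) -> tuple:
    """Apply the identity-band and truncation filters against the reference.

    Returns (kept, report): kept is the surviving list of SequenceRecord
    (the reference itself is always kept); report is a DataFrame with one
    row per input sequence (id, identity, length_fraction, kept, reason).
    """
    by_id = {r.id: r for r in records}
    if reference_id not in by_id:
        raise ValueError(f"reference {reference_id!r} missing from input")
    ref = by_id[reference_id]
    kept, rows = [], []
    for rec in records:
        ident = 1.0 if rec.id == reference_id else global_identity(rec, ref)
        length_fraction = len(rec) / len(ref)
        if rec.id == reference_id:
            keep, reason = True, "reference"
        elif length_fraction < cfg.min_length_fraction:
            keep, reason = False, "truncated"
        elif ident < cfg.min_identity:
            keep, reason = False, "identity below min"
        elif ident > cfg.max_identity:
            keep, reason = False, "identity above max"
        else:
            keep, reason = True, "ok"
        if keep:
            kept.append(rec)
        rows.append({"id": rec.id, "identity": ident,
                     "length_fraction": length_fraction,
                     "kept": keep, "reason": reason})
    return kept, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path_or_handle) -> list:
    """Read unaligned protein FASTA into SequenceRecord objects."""
    records = []
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(),
                                      rec.description))
    return records


def write_fasta(records, path_or_handle) -> None:
    close = False
    if isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__"):
        handle = open(path_or_handle, "w")
        close = True
    else:
        handle = path_or_handle
    try:
        for rec in records:
            rec_id = rec.id if hasattr(rec, "id") else rec[0]
            seq = rec.sequence if hasattr(rec, "sequence") else rec[1]
            handle.write(f">{rec_id}\n{seq}\n")
    finally:
        if close:
            handle.close()


def read_aligned_fasta(path_or_handle, reference_id: str) -> AlignedFamily:
    """Read an aligned FASTA ('-' gaps) into an AlignedFamily."""
    ids, seqs = [], []
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return AlignedFamily(ids, seqs, reference_id)


def family_to_fasta_text(family: AlignedFamily) -> str:
    buf = io.StringIO()
    for i, s in zip(family.ids, family.sequences):
        buf.write(f">{i}\n{s}\n")
    return buf.getvalue()
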