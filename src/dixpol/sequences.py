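"""Pairwise global alignment and percent identity for DIX-domain comparisons.

Cross-species structural comparisons (superposing a mouse head-to-tail dimer
on a zebrafish one, pairing CA atoms) need a residue correspondence; this
module produces it from a global alignment of the two sequences.

Scoring defaults: BLOSUM62, gap open -10, gap extend -0.5, computed by
Biopython's PairwiseAligner; the first optimal alignment in its
deterministic enumeration order is used.  Because published identity
percentages rarely state their denominator, :func:`percent_identity`
supports all three common conventions (aligned columns, shorter sequence,
full alignment length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["AlignedPair", "global_align", "percent_identity", "residue_pairing", "read_fasta"]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class AlignedPair:
    seq_a: str
    seq_b: str
    aligned_a: str
    aligned_b: str
    score: float
    pairs: list[tuple[int, int]] = field(default_factory=list)  # 0-based indices

    @property
    def identity(self) -> float:
        return percent_identity(self, denominator="aligned_columns")

    @property
    def n_identical(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-"
        )

    @property
    def n_aligned_columns(self) -> int:
        return sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x != "-" and y != "-"
        )


def _check_sequence(seq: str, label: str) -> str:
    s = seq.strip().upper()
    if not s:
        raise ValueError(f"sequence {label} is empty")
    bad = set(s) - _AA
    if bad:
        raise ValueError(f"sequence {label} has invalid characters: {sorted(bad)}")
    return s


def global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> AlignedPair:
    """Optimal global alignment with affine gaps (Needleman-Wunsch)."""
    sa = _check_sequence(a, "a")
    sb = _check_sequence(b, "b")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(sa, sb)[0]
    ga, gb = str(aln[0]), str(aln[1])

    pairs: list[tuple[int, int]] = []
    ia = ib = 0
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            pairs.append((ia, ib))
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return AlignedPair(
        seq_a=sa, seq_b=sb, aligned_a=ga, aligned_b=gb, score=float(aln.score), pairs=pairs
    )


def percent_identity(pair: AlignedPair, denominator: str = "aligned_columns") -> float:
    """Identity percentage under a chosen denominator convention."""
    n_id = pair.n_identical
    if denominator == "aligned_columns":
        denom = pair.n_aligned_columns
    elif denominator == "shorter_seq":
        denom = min(len(pair.seq_a), len(pair.seq_b))
    elif denominator == "alignment_length":
        denom = len(pair.aligned_a)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * n_id / denom if denom else 0.0


def identity_report(pair: AlignedPair) -> dict[str, float]:
    """Identity under all three denominator conventions."""
    return {
        d: percent_identity(pair, d)
        for d in ("aligned_columns", "shorter_seq", "alignment_length")
    }


def residue_pairing(
    pair: AlignedPair,
    numbering_a: list[int],
    numbering_b: list[int],
) -> dict[int, int]:
    """Author-numbered residue correspondence from the alignment.

    ``numbering_x`` lists the author residue numbers of each sequence
    position (same length as the sequence); gapped columns are absent from
    the mapping.
    """
    if len(numbering_a) != len(pair.seq_a) or len(numbering_b) != len(pair.seq_b):
        raise ValueError("numbering vectors must match sequence lengths")
    return {numbering_a[i]: numbering_b[j] for i, j in pair.pairs}


def read_fasta(path: str) -> dict[str, str]:
    """Minimal FASTA reader returning {record id: sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
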