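"""Pairwise alignment primitives for the comparative-genomics stage.

Protein comparisons use Smith-Waterman local alignment with BLOSUM62 and
BLAST-style affine gaps (open 11, extend 1: a gap of length k costs 11 + k);
gene-level nucleotide comparisons use Needleman-Wunsch global alignment with
match +1 / mismatch -2 and affine gaps (open 4, extend 2). Both are backed by
``Bio.Align.PairwiseAligner``; identity is identical columns over all alignment
columns (gap columns included), coverage is the fraction of a sequence's
residues consumed by the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = set("ACGTN")


def _blosum62_with_neutral_x():
    m = substitution_matrices.load("BLOSUM62")
    for c in m.alphabet:
        m["X", c] = 0.0
        m[c, "X"] = 0.0
    return m


_BLOSUM62X = _blosum62_with_neutral_x()


def protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62X
    aligner.open_gap_score = -12.0  # first gap residue: open 11 + extend 1
    aligner.extend_gap_score = -1.0
    return aligner


def nucleotide_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -6.0  # open 4 + extend 2
    aligner.extend_gap_score = -2.0
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    identity: float          # percent of alignment columns identical
    query_coverage: float    # percent of query residues aligned
    subject_coverage: float  # percent of subject residues aligned


_PROTEIN_ALIGNER = protein_aligner()
_NUC_ALIGNER = nucleotide_aligner()


def _stats(alignment, query: str, subject: str, score: float) -> AlignmentResult:
    q_blocks, s_blocks = alignment.aligned
    identical = 0
    aligned_cols = 0
    q_res = s_res = 0
    prev_q_end = prev_s_end = None
    gap_cols = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        if prev_q_end is not None:
            gap_cols += (qs - prev_q_end) + (ss - prev_s_end)
        for a, b in zip(query[qs:qe], subject[ss:se]):
            if a == b:
                identical += 1
        aligned_cols += qe - qs
        q_res += qe - qs
        s_res += se - ss
        prev_q_end, prev_s_end = qe, se
    columns = aligned_cols + gap_cols
    if columns == 0:
        return AlignmentResult(0.0, 0.0, 0.0, 0.0)
    return AlignmentResult(
        score=score,
        identity=100.0 * identical / columns,
        query_coverage=100.0 * q_res / len(query),
        subject_coverage=100.0 * s_res / len(subject),
    )


def _validate(seq: str, alphabet: set, label: str) -> None:
    if not seq:
        raise ValueError(f"empty {label} sequence")
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"illegal {label} characters: {sorted(bad)}")


def local_align(query: str, subject: str) -> AlignmentResult:
    """Smith-Waterman protein alignment (BLOSUM62, affine 11/1).

    Returns a zero result when no positive-scoring local alignment exists.
    """
    _validate(query, PROTEIN_ALPHABET, "protein")
    _validate(subject, PROTEIN_ALPHABET, "protein")
    score = _PROTEIN_ALIGNER.score(query, subject)
    if score <= 0:
        return AlignmentResult(0.0, 0.0, 0.0, 0.0)
    alignment = _PROTEIN_ALIGNER.align(query, subject)[0]
    return _stats(alignment, query, subject, float(score))


def global_align_nuc(query: str, subject: str) -> AlignmentResult:
    """Needleman-Wunsch nucleotide alignment (match +1, mismatch -2, gaps 4/2)."""
    _validate(query, DNA_ALPHABET, "nucleotide")
    _validate(subject, DNA_ALPHABET, "nucleotide")
    alignment = _NUC_ALIGNER.align(query, subject)[0]
    return _stats(alignment, query, subject, float(alignment.score))


def kmer_set(seq: str, k: int) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def shares_kmers(a: str, b: str, k: int, min_shared: int) -> bool:
    """Cheap seed prefilter before full alignment (MMseqs/BLAST-style)."""
    if len(a) < k or len(b) < k:
        return False
    return len(kmer_set(a, k) & kmer_set(b, k)) >= min_shared
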