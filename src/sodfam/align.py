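"""Pairwise alignment kernels shared by the scanning, classification,
duplication and phylogeny stages.

All alignments run under BLOSUM62 with affine gaps through
:class:`Bio.Align.PairwiseAligner`; a gap of length L costs
``open + (L - 1) * extend``.  The ambiguity letter X is scored as neutral
(0) against everything, so ambiguous residues neither reward nor punish an
alignment.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import PROTEIN_ALPHABET, SodfamError

#: default scoring for local (Smith-Waterman) scans
LOCAL_GAP_OPEN = 11.0
LOCAL_GAP_EXTEND = 1.0
#: default scoring for global (Needleman-Wunsch) mapping
GLOBAL_GAP_OPEN = 10.0
GLOBAL_GAP_EXTEND = 0.5


@functools.lru_cache(maxsize=1)
def blosum62_x_neutral():
    """BLOSUM62 with the X row/column zeroed (neutral ambiguity)."""
    m = substitution_matrices.load("BLOSUM62")
    arr = np.array(m)
    alphabet = m.alphabet
    xi = alphabet.index("X")
    arr[xi, :] = 0.0
    arr[:, xi] = 0.0
    out = substitution_matrices.Array(alphabet=alphabet, dims=2, data=arr)
    return out


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise SodfamError(f"{name}: empty sequence")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise SodfamError(f"{name}: non-amino-acid characters {sorted(bad)}")


def _make_aligner(mode: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = blosum62_x_neutral()
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = mode
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    """Spans are 0-based half-open on each input sequence.  ``n_cols``
    counts aligned (non-gap) column pairs; ``n_ident`` of those are
    identical, ``n_pos`` score positively under BLOSUM62."""

    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    n_cols: int
    n_ident: int
    n_pos: int
    a_blocks: tuple[tuple[int, int], ...]
    b_blocks: tuple[tuple[int, int], ...]

    @property
    def identity(self) -> float:
        return self.n_ident / self.n_cols if self.n_cols else 0.0

    @property
    def positive_fraction(self) -> float:
        return self.n_pos / self.n_cols if self.n_cols else 0.0

    def column_pairs(self):
        """Yield (a_pos, b_pos) for every aligned (non-gap) column."""
        for (a0, a1), (b0, b1) in zip(self.a_blocks, self.b_blocks):
            for k in range(a1 - a0):
                yield a0 + k, b0 + k

    def b_to_a_map(self) -> dict[int, int]:
        """Map positions of sequence b onto sequence a over aligned columns."""
        return {b: a for a, b in self.column_pairs()}


def _summarise(alignment, seq_a: str, seq_b: str) -> AlignmentResult:
    blocks_a, blocks_b = alignment.aligned
    blocks_a = tuple((int(s), int(e)) for s, e in blocks_a)
    blocks_b = tuple((int(s), int(e)) for s, e in blocks_b)
    if not blocks_a:
        return AlignmentResult(float(alignment.score), 0, 0, 0, 0, 0, 0, 0, (), ())
    matrix = blosum62_x_neutral()
    n_cols = n_ident = n_pos = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for k in range(a1 - a0):
            ra, rb = seq_a[a0 + k], seq_b[b0 + k]
            n_cols += 1
            if ra == rb:
                n_ident += 1
            if matrix[ra, rb] > 0:
                n_pos += 1
    return AlignmentResult(
        score=float(alignment.score),
        a_start=blocks_a[0][0],
        a_end=blocks_a[-1][1],
        b_start=blocks_b[0][0],
        b_end=blocks_b[-1][1],
        n_cols=n_cols,
        n_ident=n_ident,
        n_pos=n_pos,
        a_blocks=blocks_a,
        b_blocks=blocks_b,
    )


def local_align(
    a: str,
    b: str,
    gap_open: float = LOCAL_GAP_OPEN,
    gap_extend: float = LOCAL_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of ``a`` against ``b``."""
    _check_protein(a, "local_align query")
    _check_protein(b, "local_align target")
    aligner = _make_aligner("local", gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    return _summarise(aln, a, b)


def global_align(
    a: str,
    b: str,
    gap_open: float = GLOBAL_GAP_OPEN,
    gap_extend: float = GLOBAL_GAP_EXTEND,
) -> AlignmentResult:
    """Needleman-Wunsch global alignment of ``a`` against ``b``."""
    _check_protein(a, "global_align query")
    _check_protein(b, "global_align target")
    aligner = _make_aligner("global", gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    res = _summarise(aln, a, b)
    if res.n_cols == 0:
        raise SodfamError("degenerate global alignment: no aligned columns")
    return res


def glocal_align(
    peptide: str,
    reference: str,
    gap_open: float = GLOBAL_GAP_OPEN,
    gap_extend: float = GLOBAL_GAP_EXTEND,
) -> AlignmentResult:
    """Semi-global alignment threading the whole ``peptide`` into
    ``reference``: end gaps on the reference flanks are free, the peptide
    itself is aligned end to end.  Spans are reported with the reference as
    sequence ``a`` and the peptide as sequence ``b``."""
    _check_protein(peptide, "glocal_align peptide")
    _check_protein(reference, "glocal_align reference")
    aligner = _make_aligner("global", gap_open, gap_extend)
    try:
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.88 naming
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    aln = aligner.align(reference, peptide)[0]
    res = _summarise(aln, reference, peptide)
    if res.n_cols == 0:
        raise SodfamError("degenerate glocal alignment: no aligned columns")
    return res


def self_score(seq: str) -> float:
    """Sum of diagonal substitution scores; the score of aligning a
    sequence to itself without gaps."""
    matrix = blosum62_x_neutral()
    return float(sum(matrix[c, c] for c in seq))
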