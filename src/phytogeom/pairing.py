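"""Residue pairing by Smith-Waterman local alignment, plus sequence-motif search.

Two structures are compared on matched C-alpha positions: their one-letter
sequences are locally aligned (BLOSUM62, affine gaps) and each aligned column
yields one C-alpha pair. Conserved motifs (PASDIP in the GAF domain, PRXSF in
the PHY domain, the chromophore-attachment Cys) are located with a simple
wildcard pattern search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import CalphaTrace

__all__ = ["AlignParams", "ResiduePairing", "MotifHit", "smith_waterman_pair", "find_motif"]


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignParams:
    """Local-alignment scoring. A gap of length g costs open + (g-1)*extend."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise AlignmentError("need gap_open >= gap_extend >= 0")

    def load_matrix(self):
        """Named matrix from biopython's collection, or an NCBI-layout file."""
        p = Path(self.matrix)
        if p.suffix or p.exists():
            return substitution_matrices.read(str(p))
        return substitution_matrices.load(self.matrix)


@dataclass
class ResiduePairing:
    """Matched trace indices from a local alignment; both columns strictly increase."""

    pairs: list[tuple[int, int]]
    score: float
    coverage: float

    def __post_init__(self) -> None:
        ia = [p[0] for p in self.pairs]
        ib = [p[1] for p in self.pairs]
        if sorted(set(ia)) != ia or sorted(set(ib)) != ib:
            raise AlignmentError("pairing indices must be strictly increasing and unique")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class MotifHit:
    name: str
    start_residue: int
    matched: str


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = params.load_matrix()
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def smith_waterman_pair(
    trace_a: CalphaTrace,
    trace_b: CalphaTrace,
    params: AlignParams | None = None,
) -> ResiduePairing:
    """Pair C-alpha positions of two traces by optimal local alignment.

    Gapped columns produce no pair; indices refer to positions within each
    trace. When nothing scores positive the pairing is empty with score 0.
    """
    params = params or AlignParams()
    if len(trace_a) == 0 or len(trace_b) == 0:
        raise AlignmentError("cannot pair an empty trace")
    seq_a = trace_a.residue_codes
    seq_b = trace_b.residue_codes
    aligner = _make_aligner(params)
    alignments = aligner.align(seq_a, seq_b)
    if alignments.score <= 0:
        return ResiduePairing([], 0.0, 0.0)
    aln = alignments[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    coverage = len(pairs) / min(len(trace_a), len(trace_b))
    return ResiduePairing(pairs, float(alignments.score), coverage)


def find_motif(sequence: str, pattern: str, name: str | None = None, start_number: int = 1) -> list[MotifHit]:
    """All left-to-right occurrences of a motif; X in the pattern matches anything.

    ``start_number`` is the author residue number of ``sequence[0]`` so hits
    report residue numbers rather than string offsets.
    """
    if not pattern:
        raise AlignmentError("empty motif pattern")
    name = name or pattern
    hits: list[MotifHit] = []
    m = len(pattern)
    for i in range(len(sequence) - m + 1):
        window = sequence[i : i + m]
        if all(p == "X" or p == c for p, c in zip(pattern, window)):
            hits.append(MotifHit(name, start_number + i, window))
    return hits
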