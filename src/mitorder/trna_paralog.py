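"""Sequence similarity between tRNA paralogs.

High sequence identity between the two leucine tRNAs (trnL1, decoding CUN
codons, and trnL2, decoding UUR codons) is the signature of paralog
remolding: one gene arose as a duplicate of the other and switched identity
by anticodon mutation, so the pair is far more similar than two unrelated
tRNAs of the same genome.  This module quantifies that identity with a
global pairwise alignment.

Scoring: match +1, mismatch -1, gap open -2, gap extend -1, end gaps
penalized.  Identity = matches / alignment columns (gap columns included in
the denominator), reported as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .mtio import MitoGenome

__all__ = ["PairwiseAlignment", "align", "similarity", "paralog_report"]


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment of two sequences."""

    aligned_a: str
    aligned_b: str
    matches: int
    columns: int
    score: float

    @property
    def identity(self) -> float:
        return self.matches / self.columns

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped sequences differ in length")


def align(a: str, b: str) -> PairwiseAlignment:
    """Optimal global alignment of two nucleotide sequences.

    Among co-optimal alignments the aligner's first (deterministic,
    high-road) traceback is used.  The argument pair is canonicalized
    (lexicographically smaller sequence first) before aligning, so the
    reported identity is symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a, b = a.upper(), b.upper()
    swapped = (b, a) < (a, b)
    first, second = (b, a) if swapped else (a, b)
    result = _aligner().align(first, second)
    best = result[0]
    ga, gb = str(best[0]), str(best[1])
    if swapped:
        ga, gb = gb, ga
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return PairwiseAlignment(ga, gb, matches, len(ga), best.score)


def similarity(a: str, b: str) -> int:
    """Percent identity of the optimal global alignment, nearest integer."""
    alignment = align(a, b)
    return round(100 * alignment.identity)


def paralog_report(
    genome: MitoGenome, pair: tuple[str, str] = ("trnL1", "trnL2")
) -> tuple[int, dict[str, tuple[int, int]]]:
    """Percent identity between two annotated genes of one genome.

    Both genes are extracted in coding sense (reverse-complemented for
    '-'-strand annotations) before alignment; returns the identity and the
    spans used.

    Raises ``KeyError`` if either gene is not annotated.
    """
    spans = {}
    seqs = []
    for name in pair:
        ann = genome.annotation(name)
        spans[name] = (ann.start, ann.end)
        seqs.append(genome.feature_sequence(name))
    return similarity(seqs[0], seqs[1]), spans
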