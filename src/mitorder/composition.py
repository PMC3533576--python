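"""Per-genome composition statistics.

Reproduces the descriptive statistics usually tabulated for a newly
sequenced mitogenome: total length, A+T content overall and by gene class,
strand distribution of the protein-coding genes, gene overlaps, and the
noncoding-region inventory with the control region identified as the
largest gap.

The control region is treated as *noncoding*: coverage is computed from
PCG/tRNA/rRNA annotations only, so an explicit CR annotation marks a
position but never covers it.  Overlapping gene spans are unioned, never
double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mtio import CONTROL_REGION, MitoGenome

__all__ = [
    "NoncodingRegion",
    "CompositionReport",
    "at_content",
    "find_overlaps",
    "noncoding_inventory",
    "composition_report",
]


def at_content(segment: str) -> float:
    """Fraction of A/T in a nucleotide string (case-insensitive).

    Ambiguity codes and N count in the denominator only.
    """
    if not segment:
        raise ValueError("empty segment")
    upper = segment.upper()
    return (upper.count("A") + upper.count("T")) / len(upper)


@dataclass(frozen=True)
class NoncodingRegion:
    """A maximal circular interval covered by no gene annotation."""

    start: int
    end: int  # exclusive; may exceed genome length when wrapping the origin
    length: int
    at_content: float
    role: str  # 'control_region' or 'spacer'


@dataclass(frozen=True)
class CompositionReport:
    genome_length: int
    at_overall: float
    at_pcg: float
    at_rrna: float
    at_trna: float
    at_cr: float
    pcg_strand_split: tuple[int, int]  # (+ strand, - strand)
    overlaps: tuple[tuple[str, str, int], ...]
    noncoding_total: int
    regions: tuple[NoncodingRegion, ...]
    trna_length_range: tuple[int, int]

    def to_dict(self) -> dict:
        """Flat dict with A+T percentages at 1 decimal, for tabular export."""
        return {
            "genome_length": self.genome_length,
            "at_overall_pct": round(100 * self.at_overall, 1),
            "at_pcg_pct": round(100 * self.at_pcg, 1),
            "at_rrna_pct": round(100 * self.at_rrna, 1),
            "at_trna_pct": round(100 * self.at_trna, 1),
            "at_cr_pct": round(100 * self.at_cr, 1),
            "pcg_plus_strand": self.pcg_strand_split[0],
            "pcg_minus_strand": self.pcg_strand_split[1],
            "n_overlaps": len(self.overlaps),
            "noncoding_total": self.noncoding_total,
            "n_noncoding_regions": len(self.regions),
            "trna_min_len": self.trna_length_range[0],
            "trna_max_len": self.trna_length_range[1],
        }


def _span_positions(start: int, end: int, n: int) -> np.ndarray:
    """Positions of circular span [start, end) reduced modulo n."""
    return np.arange(start, end) % n


def find_overlaps(genome: MitoGenome) -> list[tuple[str, str, int]]:
    """All gene pairs whose spans intersect on the circle, with shared nt.

    Pairs are reported in circular order of the first gene's start; both
    same-strand and opposite-strand overlaps are included.  The control
    region is excluded (it is noncoding by definition).
    """
    n = len(genome)
    anns = [a for a in genome.annotations if a.name != CONTROL_REGION]
    anns.sort(key=lambda a: a.start)
    overlaps = []
    for i, a in enumerate(anns):
        pos_a = set(_span_positions(a.start, a.end, n).tolist())
        for b in anns[i + 1 :]:
            shared = len(pos_a.intersection(_span_positions(b.start, b.end, n).tolist()))
            if shared:
                overlaps.append((a.name, b.name, shared))
    return overlaps


def noncoding_inventory(genome: MitoGenome) -> list[NoncodingRegion]:
    """Maximal circular intervals covered by no PCG/tRNA/rRNA annotation.

    The longest region is labelled ``control_region``, all others
    ``spacer``.  A tie for longest is broken by higher A+T content, then by
    clockwise proximity to rrnS (the control region is AT-rich and lies by
    rrnS in the ground pattern).  Returns an empty list for a fully covered
    genome.
    """
    n = len(genome)
    covered = np.zeros(n, dtype=bool)
    for a in genome.annotations:
        if a.name == CONTROL_REGION:
            continue
        covered[_span_positions(a.start, a.end, n)] = True
    if covered.all():
        return []
    regions = []
    free = ~covered
    if free.all():
        raise ValueError("genome carries no coding annotation")
    # walk gaps circularly, starting just after a covered position
    start_scan = int(np.flatnonzero(covered)[0])
    i = start_scan
    seen = 0
    while seen < n:
        if free[i]:
            j = i
            length = 0
            while free[j % n]:
                length += 1
                j += 1
            seg = genome.slice(i, i + length)
            regions.append((i, i + length, length, at_content(seg)))
            seen += length
            i = j % n
        else:
            seen += 1
            i = (i + 1) % n
    max_len = max(r[2] for r in regions)
    ties = [r for r in regions if r[2] == max_len]
    if len(ties) > 1:
        best_at = max(r[3] for r in ties)
        ties = [r for r in ties if r[3] == best_at]
    if len(ties) > 1:
        try:
            rrns_end = genome.annotation("rrnS").end % n
        except KeyError:
            rrns_end = 0
        ties.sort(key=lambda r: (r[0] - rrns_end) % n)
    control = ties[0]
    out = [
        NoncodingRegion(s, e, ln, at, "control_region" if (s, e, ln, at) == control else "spacer")
        for (s, e, ln, at) in regions
    ]
    out.sort(key=lambda r: r.start)
    return out


def _class_at(genome: MitoGenome, kind: str) -> float:
    seqs = [genome.feature_sequence(a.name) for a in genome.annotations if a.kind == kind]
    joined = "".join(seqs)
    return at_content(joined) if joined else float("nan")


def composition_report(genome: MitoGenome) -> CompositionReport:
    """Assemble the full composition report for one annotated genome."""
    pcg_plus = sum(1 for a in genome.annotations if a.kind == "PCG" and a.strand == "+")
    pcg_minus = sum(1 for a in genome.annotations if a.kind == "PCG" and a.strand == "-")
    regions = noncoding_inventory(genome)
    cr = next((r for r in regions if r.role == "control_region"), None)
    if cr is not None:
        at_cr = cr.at_content
    else:
        try:
            at_cr = at_content(genome.feature_sequence(CONTROL_REGION))
        except KeyError:
            at_cr = float("nan")
    trna_lengths = [a.length for a in genome.annotations if a.kind == "tRNA"]
    return CompositionReport(
        genome_length=len(genome),
        at_overall=at_content(genome.sequence),
        at_pcg=_class_at(genome, "PCG"),
        at_rrna=_class_at(genome, "rRNA"),
        at_trna=_class_at(genome, "tRNA"),
        at_cr=at_cr,
        pcg_strand_split=(pcg_plus, pcg_minus),
        overlaps=tuple(find_overlaps(genome)),
        noncoding_total=sum(r.length for r in regions),
        regions=tuple(regions),
        trna_length_range=(min(trna_lengths), max(trna_lengths)) if trna_lengths else (0, 0),
    )
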