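"""Concatenated multi-gene matrices for external phylogenetic tools.

Extracts the 13 protein-coding genes from annotated mitogenomes, optionally
strips third codon positions (saturated sites are routinely excluded from
mitochondrial nucleotide phylogenies), translates with the invertebrate
mitochondrial code when an amino-acid matrix is requested, and concatenates
per-gene alignments into a supermatrix with a partition table.  Alignment
itself and tree inference are external by design; this module only prepares
and serializes their inputs (relaxed PHYLIP, FASTA, RAxML-style partition
file).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mtio import PROTEIN_CODING_GENES, MitoGenome

__all__ = [
    "Supermatrix",
    "extract_pcgs",
    "translate_pcg",
    "drop_third_positions",
    "concatenate",
    "write_phylip",
    "read_phylip",
    "write_fasta",
    "write_partitions",
]

INVERTEBRATE_MITO_TABLE = 5


@dataclass(frozen=True)
class Supermatrix:
    """Concatenated per-gene alignments over a shared taxon set.

    ``partitions`` holds per-gene 1-based inclusive column ranges that tile
    the matrix without overlap, in the (alphabetical) concatenation order.
    """

    taxa: tuple[str, ...]
    rows: dict[str, str]
    partitions: tuple[tuple[str, int, int], ...]
    alphabet: str  # 'nt' or 'aa'

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("matrix rows differ in length")
        if self.alphabet not in ("nt", "aa"):
            raise ValueError("alphabet must be 'nt' or 'aa'")
        cursor = 1
        for gene, start, end in self.partitions:
            if start != cursor or end < start:
                raise ValueError(f"partition {gene} does not tile the matrix")
            cursor = end + 1
        if self.rows and cursor != len(next(iter(self.rows.values()))) + 1:
            raise ValueError("partitions do not cover all columns")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def extract_pcgs(genome: MitoGenome) -> dict[str, str]:
    """Coding-sense nucleotide sequences of the 13 protein-coding genes.

    Extraction is circular-safe; '-'-strand genes are reverse-complemented.
    Raises ``ValueError`` naming any missing gene.
    """
    present = {a.name for a in genome.annotations}
    missing = sorted(set(PROTEIN_CODING_GENES) - present)
    if missing:
        raise ValueError(f"genome {genome.identifier} lacks PCG annotations: {missing}")
    return {g: genome.feature_sequence(g) for g in PROTEIN_CODING_GENES}


def translate_pcg(sequence: str, name: str = "") -> str:
    """Translate with the invertebrate mitochondrial code (table 5).

    An incomplete final codon is dropped with a warning; a trailing stop is
    removed.
    """
    tail = len(sequence) % 3
    if tail:
        warnings.warn(f"{name or 'sequence'}: dropping incomplete final codon ({tail} nt)")
        sequence = sequence[: len(sequence) - tail]
    aa = str(Seq(sequence).translate(table=INVERTEBRATE_MITO_TABLE))
    return aa[:-1] if aa.endswith("*") else aa


def drop_third_positions(alignment: dict[str, str], frame: int = 0) -> dict[str, str]:
    """Remove every third column, in frame, from a gapped gene alignment.

    ``frame`` is the offset of the first complete codon.  The coding part
    (after the offset) must be a whole number of codons; anything else is
    an error, never a silent truncation.  Gaps are ordinary columns: kept
    columns keep their gaps.
    """
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows differ in length")
    (length,) = lengths or {0}
    if frame < 0 or frame > 2:
        raise ValueError("frame must be 0, 1 or 2")
    if (length - frame) % 3 != 0:
        raise ValueError(
            f"alignment of {length} columns with frame {frame} is not a whole "
            "number of codons"
        )
    keep = [i for i in range(length) if i < frame or (i - frame) % 3 != 2]
    return {taxon: "".join(s[i] for i in keep) for taxon, s in alignment.items()}


def concatenate(
    per_gene: dict[str, dict[str, str]],
    taxa: list[str] | None = None,
    alphabet: str = "nt",
    permissive: bool = False,
) -> Supermatrix:
    """Concatenate per-gene alignments (gene -> taxon -> gapped sequence).

    Genes are concatenated alphabetically; a partition table records the
    column ranges.  All gene alignments must cover the same taxon set
    unless ``permissive``, in which case missing taxa are padded with gaps.
    """
    if not per_gene:
        raise ValueError("no gene alignments given")
    gene_names = sorted(per_gene)
    if taxa is None:
        taxa = sorted(set().union(*(set(d) for d in per_gene.values())))
    if not taxa:
        raise ValueError("empty taxon set")
    rows = {taxon: [] for taxon in taxa}
    partitions = []
    cursor = 1
    for gene in gene_names:
        table = per_gene[gene]
        lengths = {len(s) for s in table.values()}
        if len(lengths) != 1:
            raise ValueError(f"{gene}: rows differ in length")
        (width,) = lengths
        missing = [t for t in taxa if t not in table]
        if missing and not permissive:
            raise ValueError(f"{gene}: missing taxa {missing} (permissive=False)")
        for taxon in taxa:
            rows[taxon].append(table.get(taxon, "-" * width))
        partitions.append((gene, cursor, cursor + width - 1))
        cursor += width
    return Supermatrix(
        taxa=tuple(taxa),
        rows={t: "".join(parts) for t, parts in rows.items()},
        partitions=tuple(partitions),
        alphabet=alphabet,
    )


def _as_alignment(matrix: Supermatrix) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        [SeqRecord(Seq(matrix.rows[t]), id=t, description="") for t in matrix.taxa]
    )


def write_phylip(matrix: Supermatrix, path: str | Path) -> None:
    AlignIO.write(_as_alignment(matrix), str(path), "phylip-relaxed")


def read_phylip(path: str | Path, alphabet: str = "nt") -> Supermatrix:
    """Read a relaxed PHYLIP matrix back as a single-partition supermatrix."""
    alignment = AlignIO.read(str(path), "phylip-relaxed")
    rows = {rec.id: str(rec.seq) for rec in alignment}
    width = alignment.get_alignment_length()
    return Supermatrix(
        taxa=tuple(rec.id for rec in alignment),
        rows=rows,
        partitions=(("all", 1, width),),
        alphabet=alphabet,
    )


def write_fasta(matrix: Supermatrix, path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(matrix.rows[t]), id=t, description="") for t in matrix.taxa],
        str(path),
        "fasta",
    )


def write_partitions(matrix: Supermatrix, path: str | Path) -> None:
    """RAxML-style partition file mirroring the concatenation order."""
    model = "DNA" if matrix.alphabet == "nt" else "MTART"
    lines = [
        f"{model}, {gene} = {start}-{end}" for gene, start, end in matrix.partitions
    ]
    Path(path).write_text("\n".join(lines) + "\n")
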