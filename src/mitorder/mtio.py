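"""Reading, writing and naming of mitochondrial genomes and gene orders.

The module fixes the canonical 38-token vocabulary (13 protein-coding genes,
22 tRNAs, 2 rRNAs and the control region), maps the many spellings found in
GenBank annotations onto it via a shipped synonym table, converts GenBank
coordinates to an internal 0-based half-open circular convention, and
provides the published signed circular gene orders (the pancrustacean ground
pattern and the two derived mud-shrimp arrangements) as frozen fixtures.

Coordinate convention
---------------------
Positions are 0-based, intervals half-open, and all arithmetic is modulo the
genome length.  A feature spanning the replication origin is stored with
``end > len(sequence)``; the sequence extractor reduces modulo length.  The
'+' strand is the strand carrying ``cox1`` (the H-strand in the usual
mitochondrial sense).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PROTEIN_CODING_GENES",
    "TRNA_GENES",
    "RRNA_GENES",
    "CONTROL_REGION",
    "VOCABULARY",
    "GENE_KIND",
    "GeneAnnotation",
    "MitoGenome",
    "UnknownGeneError",
    "canonical_name",
    "fixture_order",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "read_orders",
    "write_orders",
    "rotate_genome",
]

PROTEIN_CODING_GENES = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
TRNA_GENES = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)
RRNA_GENES = ("rrnL", "rrnS")
CONTROL_REGION = "CR"

VOCABULARY = frozenset(PROTEIN_CODING_GENES + TRNA_GENES + RRNA_GENES + (CONTROL_REGION,))

GENE_KIND = {
    **{g: "PCG" for g in PROTEIN_CODING_GENES},
    **{g: "tRNA" for g in TRNA_GENES},
    **{g: "rRNA" for g in RRNA_GENES},
    CONTROL_REGION: "CR",
}


class UnknownGeneError(ValueError):
    """Raised when an annotation label cannot be mapped to the vocabulary."""


def _normalize(label: str) -> str:
    return re.sub(r"[\s\-_.]+", "", label.strip().lower())


def _load_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}
    text = resources.files("mitorder").joinpath("data/gene_synonyms.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        synonym, canonical = line.split("\t")
        table[synonym] = canonical
    return table


_SYNONYMS = _load_synonyms()

# Leucine/serine tRNAs need a disambiguator: either the codon family the
# paralog decodes (CUN/UUR/AGN/UCN) or the anticodon itself.
_LEU_BASES = {"trnaleu", "trnl", "trnleu", "leu", "l"}
_SER_BASES = {"trnaser", "trns", "trnser", "ser", "s"}
_LEU_SER_CODES = {
    # codon families
    "cun": "trnL1", "uur": "trnL2", "agn": "trnS1", "ucn": "trnS2",
    # anticodons (T and U spellings)
    "uag": "trnL1", "tag": "trnL1",
    "uaa": "trnL2", "taa": "trnL2",
    "gcu": "trnS1", "gct": "trnS1", "ucu": "trnS1", "tcu": "trnS1", "tct": "trnS1",
    "uga": "trnS2", "tga": "trnS2",
}


def canonical_name(raw_label: str, anticodon: str | None = None) -> str:
    """Map a free-text gene label onto the canonical 38-token vocabulary.

    ``anticodon`` (a 3-mer, T or U spelling) disambiguates bare tRNA-Leu /
    tRNA-Ser labels; a codon-family or anticodon suffix embedded in the label
    itself ("tRNA-Leu(CUN)", "trnL(uag)") is used the same way.  The mapping
    is idempotent on canonical tokens.

    Raises
    ------
    UnknownGeneError
        For unmappable labels, or bare tRNA-Leu/Ser with no disambiguator.
    """
    if raw_label.strip() == "tRNA":  # generic type label, not a gene name
        raise UnknownGeneError("bare 'tRNA' label carries no gene identity")
    norm = _normalize(raw_label)
    base, code = norm, None
    m = re.fullmatch(r"(.*?)\(([a-z]{3})\)", norm)
    if m:
        base, code = m.group(1), m.group(2)
    if anticodon is not None:
        code = _normalize(anticodon)
    if base in _LEU_BASES or base in _SER_BASES:
        if code is None:
            raise UnknownGeneError(
                f"ambiguous label {raw_label!r}: tRNA-Leu/tRNA-Ser need an "
                "anticodon or codon family (CUN/UUR/AGN/UCN)"
            )
        try:
            token = _LEU_SER_CODES[code]
        except KeyError:
            raise UnknownGeneError(
                f"unrecognized Leu/Ser disambiguator {code!r} in {raw_label!r}"
            ) from None
        expected_ser = base in _SER_BASES
        if expected_ser != token.startswith("trnS"):
            raise UnknownGeneError(
                f"disambiguator {code!r} contradicts amino acid in {raw_label!r}"
            )
        return token
    for candidate in (norm, base):
        if candidate in _SYNONYMS:
            return _SYNONYMS[candidate]
    raise UnknownGeneError(f"cannot map annotation label {raw_label!r}")


@dataclass
class GeneAnnotation:
    """One annotated feature on the circular genome.

    ``start``/``end`` follow the internal 0-based half-open convention;
    ``end`` may exceed the genome length to encode a wrap across the origin.
    """

    name: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.name not in VOCABULARY:
            raise UnknownGeneError(f"{self.name!r} is not a canonical gene token")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    @property
    def kind(self) -> str:
        return GENE_KIND[self.name]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MitoGenome:
    """A circular mitochondrial genome: sequence plus ordered annotations."""

    identifier: str
    sequence: str
    annotations: list[GeneAnnotation] = field(default_factory=list)
    unmapped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self, complete: bool = True) -> None:
        """Check annotation invariants; ``complete`` requires all 38 tokens."""
        n = len(self.sequence)
        names = [a.name for a in self.annotations]
        dup = {g for g in names if names.count(g) > 1}
        if dup:
            raise ValueError(f"duplicate annotations: {sorted(dup)}")
        for a in self.annotations:
            if a.start >= n:
                raise ValueError(f"{a.name}: start {a.start} beyond genome length {n}")
            if a.length > n:
                raise ValueError(f"{a.name}: span longer than genome")
        if complete and set(names) != VOCABULARY:
            missing = sorted(VOCABULARY - set(names))
            raise ValueError(f"genome lacks canonical genes: {missing}")

    def feature_sequence(self, name: str) -> str:
        """Coding-sense nucleotide sequence of one annotated gene.

        '-'-strand features are reverse-complemented; origin-spanning spans
        are read circularly.
        """
        ann = self.annotation(name)
        raw = self.slice(ann.start, ann.end)
        if ann.strand == "-":
            raw = str(Seq(raw).reverse_complement())
        return raw

    def annotation(self, name: str) -> GeneAnnotation:
        for a in self.annotations:
            if a.name == name:
                return a
        raise KeyError(f"no annotation for {name}")

    def slice(self, start: int, end: int) -> str:
        """Extract [start, end) reading circularly (end may exceed length)."""
        n = len(self.sequence)
        if end <= n:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[: end - n]


def rotate_genome(genome: MitoGenome, offset: int) -> MitoGenome:
    """Rotate the circular origin by ``offset`` nucleotides.

    Annotations are re-expressed relative to the new origin; features that
    then span it get ``end > length``.
    """
    n = len(genome.sequence)
    offset %= n
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    anns = []
    for a in genome.annotations:
        start = (a.start - offset) % n
        anns.append(GeneAnnotation(a.name, start, start + a.length, a.strand))
    anns.sort(key=lambda a: a.start)
    return MitoGenome(genome.identifier, seq, anns, list(genome.unmapped))


# ---------------------------------------------------------------------------
# GenBank / FASTA
# ---------------------------------------------------------------------------

_FEATURE_TYPES = {"CDS", "tRNA", "rRNA", "misc_feature", "D-loop", "gene", "rep_origin"}


def _feature_label(feature: SeqFeature) -> str | None:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    if feature.type == "D-loop":
        return "control region"
    return None


def _feature_anticodon(feature: SeqFeature) -> str | None:
    for value in feature.qualifiers.get("anticodon", []):
        m = re.search(r"seq\s*:\s*([acgtu]{3})", value, re.IGNORECASE)
        if m:
            return m.group(1)
        if re.fullmatch(r"[ACGTUacgtu]{3}", value.strip()):
            return value.strip()
    return None


def read_genbank(path: str | Path, relax: bool = False) -> MitoGenome:
    """Read one circular GenBank record into a :class:`MitoGenome`.

    Feature qualifiers are mapped to canonical tokens via the synonym table;
    features that cannot be mapped are kept in ``genome.unmapped`` and
    reported as a warning, never silently dropped.

    Raises
    ------
    ValueError
        If no feature maps to the vocabulary, or (unless ``relax``) two
        non-identical features map to the same gene.
    """
    record = SeqIO.read(str(path), "genbank")
    n = len(record.seq)
    annotations: dict[str, GeneAnnotation] = {}
    unmapped: list[tuple[str, str]] = []
    for feature in record.features:
        if feature.type not in _FEATURE_TYPES:
            continue
        label = _feature_label(feature)
        if label is None:
            unmapped.append((feature.type, ""))
            continue
        try:
            name = canonical_name(label, _feature_anticodon(feature))
        except UnknownGeneError:
            unmapped.append((feature.type, label))
            continue
        start, end = _location_to_circular(feature.location, n)
        strand = "-" if feature.location.strand == -1 else "+"
        ann = GeneAnnotation(name, start, end, strand)
        if name in annotations:
            prev = annotations[name]
            same_span = prev.start == ann.start and prev.end == ann.end
            if same_span or relax:
                # 'gene' + 'CDS'/'tRNA' pairs annotate the same feature twice
                continue
            raise ValueError(f"two distinct features map to {name} in {path}")
        annotations[name] = ann
    if not annotations:
        raise ValueError(f"no mappable features in {path}")
    if unmapped:
        warnings.warn(
            f"{record.id}: {len(unmapped)} unmappable feature(s): {unmapped[:5]}",
            stacklevel=2,
        )
    genome = MitoGenome(
        record.id or record.name,
        str(record.seq).upper(),
        sorted(annotations.values(), key=lambda a: a.start),
        unmapped,
    )
    return genome


def _location_to_circular(location, n: int) -> tuple[int, int]:
    parts = sorted(location.parts, key=lambda p: int(p.start))
    if len(parts) == 1:
        return int(parts[0].start), int(parts[0].end)
    if len(parts) == 2 and int(parts[1].end) == n and int(parts[0].start) == 0:
        # origin-spanning join(x..n, 1..y)
        return int(parts[1].start), n + int(parts[0].end)
    raise ValueError(f"unsupported compound location {location}")


_KIND_FEATURE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "misc_feature"}


def write_genbank(genome: MitoGenome, path: str | Path) -> None:
    """Write a GenBank flat file that round-trips through :func:`read_genbank`."""
    n = len(genome.sequence)
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.identifier,
        name=re.sub(r"[^A-Za-z0-9_]", "_", genome.identifier)[:16] or "genome",
        description="synthetic circular mitochondrial genome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for ann in genome.annotations:
        strand = -1 if ann.strand == "-" else 1
        if ann.end <= n:
            location = SimpleLocation(ann.start, ann.end, strand)
        else:
            location = CompoundLocation(
                [SimpleLocation(ann.start, n, strand), SimpleLocation(0, ann.end - n, strand)]
            )
        qualifiers = {"gene": [ann.name]}
        if ann.name == CONTROL_REGION:
            qualifiers = {"note": ["control region"]}
        record.features.append(
            SeqFeature(location, type=_KIND_FEATURE[ann.kind], qualifiers=qualifiers)
        )
    SeqIO.write([record], str(path), "genbank")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Plain-text signed gene-order format
# ---------------------------------------------------------------------------

def read_orders(path: str | Path) -> dict[str, "GeneOrder"]:
    """Read the one-genome-per-line signed gene-order format.

    Each line is ``identifier TAB space-separated signed tokens``; '#' lines
    are comments.
    """
    from .gene_order import GeneOrder

    orders: dict[str, GeneOrder] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        identifier, _, rest = line.partition("\t")
        orders[identifier] = GeneOrder.from_string(rest)
    return orders


def write_orders(orders: dict[str, "GeneOrder"], path: str | Path) -> None:
    lines = [f"{name}\t{order}" for name, order in orders.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Published gene-order fixtures
# ---------------------------------------------------------------------------

# Pancrustacean (Crustacea + Hexapoda) ground pattern; also the order of
# T. kelanang.  '+' is the cox1 (H) strand.
_GROUND_PATTERN = (
    "+cox1 +trnL2 +cox2 +trnK +trnD +atp8 +atp6 +cox3 +trnG +nad3 "
    "+trnA +trnR +trnN +trnS1 +trnE -trnF -nad5 -trnH -nad4 -nad4L "
    "+trnT -trnP +nad6 +cob +trnS2 -nad1 -trnL1 -rrnL -trnV -rrnS "
    "+CR +trnI -trnQ +trnM +nad2 +trnW -trnC -trnY"
)

# Shared derived order of the two Gebiidea (A. edulis, U. major): trnL1
# relocated next to trnL2 (H-strand), trnI next to trnS2, trnQ upstream of
# the control region, trnC/trnY between CR and trnM.
_GEBIIDEA = (
    "+cox1 +trnL2 +trnL1 +cox2 +trnK +trnD +atp8 +atp6 +cox3 +trnG "
    "+nad3 +trnA +trnR +trnN +trnS1 +trnE -trnF -nad5 -trnH -nad4 "
    "-nad4L +trnT -trnP +nad6 +cob +trnS2 +trnI -nad1 -rrnL -trnV "
    "-rrnS -trnQ +CR -trnC -trnY +trnM +nad2 +trnW"
)

# Shared derived order of the two Axiidea (N. glyptocercus,
# N. thermophilus): trnL1 between cox1 and trnL2, inverted trnI between
# rrnS and CR, inverted trnV after trnG, trnD upstream of trnM, cox3
# between nad3 and trnA; the two rRNAs are adjacent.
_AXIIDEA = (
    "+cox1 +trnL1 +trnL2 +cox2 +trnK +atp8 +atp6 +trnG +trnV +nad3 "
    "+cox3 +trnA +trnR +trnN +trnS1 +trnE -trnF -nad5 -trnH -nad4 "
    "-nad4L +trnT -trnP +nad6 +cob +trnS2 -nad1 -rrnL -rrnS -trnI "
    "+CR -trnQ +trnD +trnM +nad2 +trnW -trnC -trnY"
)

_FIXTURES = {
    "ground_pattern": _GROUND_PATTERN,
    "thalassina": _GROUND_PATTERN,
    "gebiidea": _GEBIIDEA,
    "axiidea": _AXIIDEA,
}


def fixture_order(key: str) -> "GeneOrder":
    """Return one of the published signed circular gene orders.

    Keys: ``ground_pattern`` (pancrustacean ancestral arrangement),
    ``thalassina`` (identical to the ground pattern), ``gebiidea``
    (A. edulis / U. major) and ``axiidea`` (N. glyptocercus /
    N. thermophilus).
    """
    from .gene_order import GeneOrder

    try:
        literal = _FIXTURES[key]
    except KeyError:
        raise KeyError(
            f"unknown fixture {key!r}; choose from {sorted(_FIXTURES)}"
        ) from None
    order = GeneOrder.from_string(literal)
    assert set(g for g, _ in order.elements) == VOCABULARY
    return order
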