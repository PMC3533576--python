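"""Synthetic mitogenomes and rearrangement histories with known truth.

The generator lays out a circular ~15 kb genome following a given signed
gene order (the pancrustacean ground pattern by default), with AT-biased
i.i.d. sequence (P(A) = P(T) = at_target/2), per-class gene lengths, small
intergenic spacers, the two classic 7-nt reading-frame overlaps
(atp8/atp6 and nad4/nad4L), and the control region as the largest
noncoding region.  Histories are sampled from the mechanistic event
repertoire and replayed onto the ground pattern, so every downstream
operation can be checked against known ground truth.  A paralog-remolding
event copies the donor tRNA sequence into the recipient with a configured
number of point mutations, reproducing the high paralog identity that
remolding leaves behind.

Everything is driven by one seeded generator: identical config, identical
output, byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from . import mtio
from .gene_order import GeneOrder
from .mtio import CONTROL_REGION, GENE_KIND, GeneAnnotation, MitoGenome, fixture_order
from .rearrangement import (
    RearrangementEvent,
    apply_event,
    inversion,
    paralog_remold,
    reverse_transposition,
    tdrl,
    transposition,
)

__all__ = ["SimulationConfig", "SimulatedTruth", "simulate_genome", "simulate_history", "write_outputs"]

_BASES = np.array(list("ATGC"))


def _default_length_ranges() -> dict[str, tuple[int, int]]:
    return {"PCG": (160, 1800), "tRNA": (61, 73), "rRNA": (700, 1400), "CR": (91, 1200)}


def _default_event_mix() -> dict[str, float]:
    # tdrl defaults to 0: the inference vocabulary omits it (see
    # rearrangement.DEFAULT_VOCABULARY) and single-copy moves cover the
    # observed arrangements.
    return {
        "transposition": 0.5,
        "inversion": 0.2,
        "reverse_transposition": 0.2,
        "paralog_remold": 0.1,
        "tdrl": 0.0,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults mirror decapod mitogenomes.

    at_target is the genome-wide A+T fraction (decapod range roughly
    0.66-0.74); gene-length ranges are per gene class in nt; overlap_spec
    forces shared terminal nucleotides between adjacent same-strand pairs;
    remold_mutations is the number of point mutations separating a remolded
    paralog from its donor.
    """

    seed: int = 0
    at_target: float = 0.70
    gene_length_ranges: dict[str, tuple[int, int]] = field(default_factory=_default_length_ranges)
    overlap_spec: tuple[tuple[str, str, int], ...] = (("atp8", "atp6", 7), ("nad4", "nad4L", 7))
    spacer_probability: float = 0.3
    spacer_length_range: tuple[int, int] = (1, 56)
    n_events: int = 0
    event_mix: dict[str, float] = field(default_factory=_default_event_mix)
    remold_mutations: int = 5
    origin_offset: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.at_target <= 1.0:
            raise ValueError("at_target must be a fraction")
        total = sum(self.event_mix.values())
        if self.event_mix and abs(total - 1.0) > 1e-9:
            raise ValueError(f"event_mix probabilities sum to {total}, not 1")
        for kind, (lo, hi) in self.gene_length_ranges.items():
            if lo < 1 or hi < lo:
                raise ValueError(f"empty length range for {kind}")
        for a, b, ov in self.overlap_spec:
            if ov < 1:
                raise ValueError(f"overlap {a}/{b} must be >= 1 nt")


@dataclass(frozen=True)
class SimulatedTruth:
    """Generator output: genome, gene order, event history, true sequences."""

    genome: MitoGenome
    order: GeneOrder
    history: tuple[RearrangementEvent, ...]
    gene_sequences: dict[str, str]
    source: GeneOrder

    def replay(self) -> GeneOrder:
        current = self.source
        for event in self.history:
            current = apply_event(current, event)
        return current


def _sample_seq(rng: np.random.Generator, length: int, at: float) -> str:
    probs = [at / 2, at / 2, (1 - at) / 2, (1 - at) / 2]
    return "".join(rng.choice(_BASES, size=length, p=probs))


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _realize(
    identifier: str,
    order: GeneOrder,
    seqs: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[MitoGenome, dict[str, str]]:
    """Lay the gene order out on a circle; returns genome + effective truth.

    Forced overlaps share terminal nucleotides, so the stored truth
    sequence of the second gene of an overlapping pair is adjusted to the
    realized slice.
    """
    overlap_by_pair = {frozenset((a, b)): ov for a, b, ov in config.overlap_spec}
    elements = order.elements
    chunks: list[str] = []
    total = 0
    annotations: list[GeneAnnotation] = []
    effective = dict(seqs)
    lo_sp, hi_sp = config.spacer_length_range
    for k, (name, sign) in enumerate(elements):
        layout = effective[name] if sign == "+" else _revcomp(effective[name])
        overlap = 0
        if k > 0:
            prev_name, prev_sign = elements[k - 1]
            pair = frozenset((prev_name, name))
            if pair in overlap_by_pair and prev_sign == sign:
                overlap = overlap_by_pair[pair]
                if overlap >= min(len(layout), len(effective[prev_name])):
                    raise ValueError(
                        f"overlap {prev_name}/{name} of {overlap} nt exceeds a gene length"
                    )
            elif (
                name != CONTROL_REGION
                and prev_name != CONTROL_REGION
                and rng.random() < config.spacer_probability
            ):
                spacer = _sample_seq(rng, int(rng.integers(lo_sp, hi_sp + 1)), config.at_target)
                chunks.append(spacer)
                total += len(spacer)
        if overlap:
            tail = chunks[-1][-overlap:]
            layout = tail + layout[overlap:]
            effective[name] = layout if sign == "+" else _revcomp(layout)
            start = total - overlap
            chunks.append(layout[overlap:])
            total += len(layout) - overlap
        else:
            start = total
            chunks.append(layout)
            total += len(layout)
        annotations.append(GeneAnnotation(name, start, start + len(layout), sign))
    genome = MitoGenome(identifier, "".join(chunks), annotations)
    genome.validate(complete=order.genes == mtio.VOCABULARY)
    if config.origin_offset:
        genome = mtio.rotate_genome(genome, config.origin_offset)
    return genome, effective


def _sample_gene_sequences(
    order: GeneOrder, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, str]:
    seqs = {}
    for name, _ in order.elements:
        kind = GENE_KIND.get(name, "PCG")
        lo, hi = config.gene_length_ranges[kind]
        length = int(rng.integers(lo, hi + 1))
        if kind == "PCG":
            length -= length % 3  # protein-coding genes are whole ORFs
        seqs[name] = _sample_seq(rng, length, config.at_target)
    return seqs


def simulate_genome(config: SimulationConfig, order: GeneOrder | None = None) -> SimulatedTruth:
    """Generate one annotated genome realizing ``order`` (default: ground pattern)."""
    rng = np.random.default_rng(config.seed)
    if order is None:
        order = fixture_order("ground_pattern")
    seqs = _sample_gene_sequences(order, config, rng)
    genome, effective = _realize(f"synthetic-{config.seed}", order, seqs, config, rng)
    return SimulatedTruth(genome, order, (), effective, order)


def _mutate(seq: str, k: int, rng: np.random.Generator) -> str:
    positions = rng.choice(len(seq), size=min(k, len(seq)), replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ATGC" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(out)


def _circular_block(elems, i: int, l: int):
    n = len(elems)
    return tuple(elems[(i + k) % n] for k in range(l))


def _sample_event(
    kind: str, order: GeneOrder, rng: np.random.Generator
) -> RearrangementEvent | None:
    elems = order.elements
    n = len(elems)
    if kind in ("transposition", "inversion", "reverse_transposition"):
        l = int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))
        l = min(l, n - 2)
        i = int(rng.integers(0, n))
        block = _circular_block(elems, i, l)
        if kind == "inversion":
            return inversion(block)
        blocked_gaps = {(i - 1) % n} | {(i + k) % n for k in range(l)}
        valid = [g for g in range(n) if g not in blocked_gaps]
        if not valid:
            return None
        t = int(valid[int(rng.integers(0, len(valid)))])
        target = (elems[t], elems[(t + 1) % n])
        maker = transposition if kind == "transposition" else reverse_transposition
        return maker(block, target)
    if kind == "tdrl":
        l = int(rng.integers(2, min(6, n - 1) + 1))
        i = int(rng.integers(0, n))
        region = _circular_block(elems, i, l)
        mask = int(rng.integers(1, 2**l - 1))
        keep = tuple(2 if mask >> k & 1 else 1 for k in range(l))
        return tdrl(region, keep)
    if kind == "paralog_remold":
        present = order.genes
        pairs = [
            (d, r)
            for d, r in (("trnL2", "trnL1"), ("trnL1", "trnL2"), ("trnS2", "trnS1"), ("trnS1", "trnS2"))
            if d in present and r in present
        ]
        if not pairs:
            return None
        donor, recipient = pairs[int(rng.integers(0, len(pairs)))]
        side = ("downstream", "upstream")[int(rng.integers(0, 2))]
        return paralog_remold(donor, recipient, side=side)
    raise ValueError(f"unknown event kind {kind!r}")


def simulate_history(
    config: SimulationConfig, source: GeneOrder | None = None, resample_cap: int = 100
) -> SimulatedTruth:
    """Sample ``config.n_events`` events, apply them, and realize a genome.

    Remolded recipients inherit the donor sequence with
    ``config.remold_mutations`` point mutations.  The returned truth always
    satisfies closure: replaying the history over the source reproduces the
    final order.
    """
    rng = np.random.default_rng(config.seed)
    if source is None:
        source = fixture_order("ground_pattern")
    kinds = sorted(k for k, p in config.event_mix.items() if p > 0)
    probs = np.array([config.event_mix[k] for k in kinds])
    probs = probs / probs.sum()
    order = source
    history: list[RearrangementEvent] = []
    for _ in range(config.n_events):
        for _attempt in range(resample_cap):
            kind = str(rng.choice(kinds, p=probs))
            event = _sample_event(kind, order, rng)
            if event is None:
                continue
            try:
                new_order = apply_event(order, event)
            except ValueError:
                continue
            if new_order == order:
                continue
            order = new_order
            history.append(event)
            break
        else:
            raise RuntimeError(f"no applicable event found in {resample_cap} draws")
    seqs = _sample_gene_sequences(order, config, rng)
    for event in history:
        if event.kind == "paralog_remold":
            seqs[event.recipient] = _mutate(seqs[event.donor], config.remold_mutations, rng)
    genome, effective = _realize(f"synthetic-{config.seed}", order, seqs, config, rng)
    truth = SimulatedTruth(genome, order, tuple(history), effective, source)
    assert truth.replay() == order, "history does not reproduce the simulated order"
    return truth


def write_outputs(truth: SimulatedTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write GenBank, FASTA, gene-order text and a truth JSON to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genbank": out / f"{truth.genome.identifier}.gb",
        "fasta": out / f"{truth.genome.identifier}.fasta",
        "orders": out / "orders.txt",
        "truth": out / "truth.json",
    }
    mtio.write_genbank(truth.genome, paths["genbank"])
    mtio.write_fasta({truth.genome.identifier: truth.genome.sequence}, paths["fasta"])
    mtio.write_orders({truth.genome.identifier: truth.order}, paths["orders"])
    payload = {
        "identifier": truth.genome.identifier,
        "order": str(truth.order),
        "source": str(truth.source),
        "history": [e.describe() for e in truth.history],
        "gene_sequences": truth.gene_sequences,
    }
    paths["truth"].write_text(json.dumps(payload, indent=2) + "\n")
    return paths
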