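"""Signed circular gene orders and their comparison.

A mitochondrial gene arrangement is modelled as a signed circular
permutation: a cyclic sequence of (gene, strand) pairs, where reading the
circle from the other strand (reverse the sequence and flip every sign)
denotes the same molecule.  Two orders are compared through their
orientation-aware adjacency sets: the adjacency ``(a, b)`` is identified
with ``(-b, -a)``.  A *breakpoint* is an adjacency present in one order but
not the reference; the *displaced-gene set* is the minimum set of genes
whose deletion from both orders leaves identical circles — the formal
counterpart of a paper figure's "rearranged genes".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

from . import mtio

__all__ = [
    "GeneOrder",
    "OrderComparison",
    "SearchCapExceeded",
    "breakpoint_distance",
    "displaced_genes",
    "compare",
    "extract_order",
]

Element = tuple[str, str]  # (gene name, '+' or '-')


class SearchCapExceeded(RuntimeError):
    """Raised when the displaced-gene search exceeds its subset-size cap."""


def _flip(sign: str) -> str:
    return "-" if sign == "+" else "+"


class GeneOrder:
    """An immutable signed circular gene order.

    Equality is invariant under rotation and under full reversal with sign
    flip (the same circle read from the other strand).  Orders over
    arbitrary gene alphabets are allowed (small toy circles are used
    throughout the tests); orders built from genome fixtures use the
    canonical 38-token vocabulary.
    """

    __slots__ = ("elements", "_canonical")

    def __init__(self, elements: Iterable[Element], strict: bool = False):
        elems = []
        for name, sign in elements:
            if sign not in "+-":
                raise ValueError(f"bad sign {sign!r} for {name}")
            if name == mtio.CONTROL_REGION:
                sign = "+"  # CR is unstranded; '+' by convention
            elems.append((name, sign))
        names = [g for g, _ in elems]
        if len(set(names)) != len(names):
            dup = sorted({g for g in names if names.count(g) > 1})
            raise ValueError(f"duplicate genes in order: {dup}")
        if not elems:
            raise ValueError("empty gene order")
        if strict:
            unknown = sorted(set(names) - mtio.VOCABULARY)
            if unknown:
                raise mtio.UnknownGeneError(f"non-canonical tokens: {unknown}")
        object.__setattr__(self, "elements", tuple(elems))
        object.__setattr__(self, "_canonical", None)

    def __setattr__(self, *a):  # pragma: no cover - immutability guard
        raise AttributeError("GeneOrder is immutable")

    @classmethod
    def from_string(cls, text: str, strict: bool = False) -> "GeneOrder":
        """Parse space-separated signed tokens; an unsigned token is '+'."""
        elems = []
        for token in text.split():
            if token[0] in "+-":
                elems.append((token[1:], token[0]))
            else:
                elems.append((token, "+"))
        return cls(elems, strict=strict)

    def __str__(self) -> str:
        return " ".join(
            g if (g == mtio.CONTROL_REGION and s == "+") else f"{s}{g}"
            for g, s in self.elements
        )

    def __repr__(self) -> str:
        return f"GeneOrder({self})"

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.elements)

    def reversed_flipped(self) -> "GeneOrder":
        """The same circle read from the opposite strand."""
        return GeneOrder([(g, _flip(s)) for g, s in reversed(self.elements)])

    def rotated(self, offset: int) -> "GeneOrder":
        n = len(self.elements)
        offset %= n
        return GeneOrder(self.elements[offset:] + self.elements[:offset])

    def canonicalize(self) -> "GeneOrder":
        """Deterministic representative of the rotation/reflection class.

        If ``cox1`` is present the order is rotated to start at cox1, after
        reflecting the circle if cox1 sits on '-'.  Otherwise the
        lexicographically least of all rotations of both readings is used.
        """
        return GeneOrder(self._canonical_elements())

    def _canonical_elements(self) -> tuple[Element, ...]:
        cached = self._canonical
        if cached is not None:
            return cached
        elems = self.elements

        def reflect(es):
            # CR keeps its conventional '+' in either reading direction
            return tuple(
                (g, "+" if g == mtio.CONTROL_REGION else _flip(s))
                for g, s in reversed(es)
            )

        n = len(elems)
        if any(g == "cox1" for g, _ in elems):
            idx, sign = next((i, s) for i, (g, s) in enumerate(elems) if g == "cox1")
            if sign == "-":
                elems = reflect(elems)
                idx = next(i for i, (g, _) in enumerate(elems) if g == "cox1")
            result = elems[idx:] + elems[:idx]
        else:
            candidates = []
            for variant in (elems, reflect(elems)):
                for i in range(n):
                    candidates.append(variant[i:] + variant[:i])
            result = min(candidates)
        object.__setattr__(self, "_canonical", result)
        return result

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return self._canonical_elements() == other._canonical_elements()

    def __hash__(self) -> int:
        return hash(self._canonical_elements())

    def adjacencies(self) -> frozenset[tuple[Element, Element]]:
        """Orientation-aware adjacency set; (a, b) is identified with (-b, -a)."""
        n = len(self.elements)
        pairs = set()
        for i in range(n):
            pairs.add(_norm_adjacency(self.elements[i], self.elements[(i + 1) % n]))
        return frozenset(pairs)


def _norm_adjacency(a: Element, b: Element) -> tuple[Element, Element]:
    forward = (a, b)
    backward = ((b[0], _flip(b[1])), (a[0], _flip(a[1])))
    return min(forward, backward)


@dataclass(frozen=True)
class OrderComparison:
    """Summary of one order against a reference."""

    displaced: frozenset[str]
    breakpoints: int
    shared_adjacencies: int


def _check_same_genes(order: GeneOrder, reference: GeneOrder) -> None:
    if order.genes != reference.genes:
        extra = sorted(order.genes ^ reference.genes)
        raise ValueError(f"orders are over different gene sets; differing: {extra}")


def breakpoint_distance(order: GeneOrder, reference: GeneOrder) -> int:
    """Number of adjacencies of ``order`` absent from ``reference``.

    Signed and orientation-aware: ``(a, b)`` matches ``(-b, -a)``.  Zero iff
    the two circles are equal.
    """
    _check_same_genes(order, reference)
    return len(order.adjacencies() - reference.adjacencies())


def _equal_after_deletion(order: GeneOrder, reference: GeneOrder, removed: frozenset[str]) -> bool:
    kept_a = [e for e in order.elements if e[0] not in removed]
    kept_b = [e for e in reference.elements if e[0] not in removed]
    if not kept_a:
        return True
    return GeneOrder(kept_a) == GeneOrder(kept_b)


def displaced_genes(
    order: GeneOrder, reference: GeneOrder, max_size: int = 10
) -> frozenset[str]:
    """Minimum set of genes whose removal makes the two circles identical.

    Exact search by iterative deepening on the set size; candidate genes are
    restricted to those incident to a breakpoint in either order (a gene
    whose two adjacencies both survive in the other order can never be part
    of a minimum deletion set).  Ties are broken lexicographically, with the
    control region ordered last: CR is a position marker rather than a gene,
    so among co-minimal sets the one made of actual genes wins.

    Raises
    ------
    SearchCapExceeded
        If no set of size ``max_size`` or smaller suffices.
    """
    _check_same_genes(order, reference)
    if order == reference:
        return frozenset()
    adj_a, adj_b = order.adjacencies(), reference.adjacencies()
    broken = (adj_a - adj_b) | (adj_b - adj_a)
    incident = {g for pair in broken for (g, _) in pair}
    candidates = sorted(incident, key=lambda g: (g == mtio.CONTROL_REGION, g))
    for k in range(1, min(max_size, len(candidates)) + 1):
        for combo in itertools.combinations(candidates, k):
            removed = frozenset(combo)
            if _equal_after_deletion(order, reference, removed):
                return removed
    raise SearchCapExceeded(
        f"no deletion set of size <= {max_size} reconciles the orders"
    )


def compare(order: GeneOrder, reference: GeneOrder, max_size: int = 10) -> OrderComparison:
    """Displaced genes, breakpoints and shared adjacencies in one report."""
    bp = breakpoint_distance(order, reference)
    displaced = displaced_genes(order, reference, max_size=max_size)
    return OrderComparison(
        displaced=displaced,
        breakpoints=bp,
        shared_adjacencies=len(order) - bp,
    )


def extract_order(genome: "mtio.MitoGenome") -> GeneOrder:
    """Signed circular gene order of an annotated genome, canonicalized.

    Annotations are sorted by circular start position; signs come from
    strands.  If the control region is not annotated it is inferred as the
    largest noncoding gap.
    """
    annotations = list(genome.annotations)
    names = [a.name for a in annotations]
    if len(set(names)) != len(names):
        dup = sorted({g for g in names if names.count(g) > 1})
        raise ValueError(f"duplicate gene annotations: {dup}")
    if mtio.CONTROL_REGION not in names:
        from .composition import noncoding_inventory

        regions = noncoding_inventory(genome)
        cr = next((r for r in regions if r.role == "control_region"), None)
        if cr is not None:
            annotations.append(
                mtio.GeneAnnotation(mtio.CONTROL_REGION, cr.start, cr.end, "+")
            )
    annotations.sort(key=lambda a: a.start)
    return GeneOrder([(a.name, a.strand) for a in annotations]).canonicalize()
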