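"""Mechanistic rearrangement events and scenario inference.

The module models the event repertoire invoked for mitochondrial gene-order
evolution — transposition, inversion, reverse transposition (move plus
strand flip), tandem duplication / random loss (TDRL), and tRNA paralog
remolding by anticodon mutation (duplication of a donor tRNA, identity
switch of one copy, loss of the ancestral gene) — as exact edits on signed
circular gene orders, and infers minimum-length stepwise scenarios
transforming one order into another.

Scenario search is iterative-deepening depth-first over event applications.
Each unit event (other than TDRL) touches at most three adjacencies, so
``ceil(breakpoints / 3)`` is an admissible lower bound on the number of
events still required; nodes whose bound exceeds the remaining depth are
pruned, which both keeps the search tractable and constitutes the proof
that no shorter scenario exists.  With TDRL in the vocabulary (a single
TDRL may repair arbitrarily many adjacencies) the bound degrades to one per
event.  Expansion order is fixed and lexicographic; the search holds no
randomness.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .gene_order import Element, GeneOrder, _flip, breakpoint_distance
from .mtio import GENE_KIND, fixture_order

__all__ = [
    "RearrangementEvent",
    "Scenario",
    "DEFAULT_VOCABULARY",
    "EVENT_KINDS",
    "transposition",
    "inversion",
    "reverse_transposition",
    "tdrl",
    "paralog_remold",
    "apply_event",
    "grouped_steps",
    "paper_scenarios",
    "infer_scenario",
    "remold_support",
    "SearchSpaceExceeded",
]

EVENT_KINDS = ("transposition", "inversion", "reverse_transposition", "tdrl", "paralog_remold")

# TDRL is expressible as transpositions for the arrangements studied here
# and has no admissible distance bound, so it is opt-in for inference.
DEFAULT_VOCABULARY = ("transposition", "inversion", "reverse_transposition", "paralog_remold")

_REMOLD_PAIRS = (("trnL1", "trnL2"), ("trnL2", "trnL1"), ("trnS1", "trnS2"), ("trnS2", "trnS1"))


class SearchSpaceExceeded(RuntimeError):
    """Raised when scenario inference exceeds its node expansion budget."""


@dataclass(frozen=True)
class RearrangementEvent:
    """One mechanistic edit applicable to a :class:`GeneOrder`.

    ``block``/``target`` describe moves and inversions; ``region`` plus
    ``loss_assignment`` (1 = kept in first copy, 2 = kept in second copy,
    parallel to ``region``) describe a TDRL; ``donor``/``recipient``/``side``
    describe a paralog remolding, where the new recipient-named copy takes
    the donor's sign and sits on the chosen side of the donor.
    """

    kind: str
    block: tuple[Element, ...] | None = None
    target: tuple[Element, Element] | None = None
    region: tuple[Element, ...] | None = None
    loss_assignment: tuple[int, ...] | None = None
    donor: str | None = None
    recipient: str | None = None
    side: str = "downstream"

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "tdrl":
            if self.region is None or self.loss_assignment is None:
                raise ValueError("tdrl needs region and loss_assignment")
            if len(self.region) != len(self.loss_assignment):
                raise ValueError("loss_assignment must parallel region")
            if not set(self.loss_assignment) <= {1, 2}:
                raise ValueError("loss_assignment entries must be 1 or 2")
        elif self.kind == "paralog_remold":
            if self.donor is None or self.recipient is None:
                raise ValueError("paralog_remold needs donor and recipient")
            if (self.recipient, self.donor) not in _REMOLD_PAIRS:
                raise ValueError(
                    "remolding is restricted to the trnL1/trnL2 and trnS1/trnS2 pairs"
                )
            if self.side not in ("downstream", "upstream"):
                raise ValueError("side must be 'downstream' or 'upstream'")
        else:
            if self.block is None:
                raise ValueError(f"{self.kind} needs a block")
            if self.kind in ("transposition", "reverse_transposition") and self.target is None:
                raise ValueError(f"{self.kind} needs a target adjacency")

    def describe(self) -> str:
        if self.kind == "paralog_remold":
            return f"paralog_remold({self.donor}->{self.recipient}, {self.side})"
        if self.kind == "tdrl":
            genes = " ".join(f"{s}{g}" for g, s in self.region)
            return f"tdrl([{genes}], keep={self.loss_assignment})"
        genes = " ".join(f"{s}{g}" for g, s in self.block)
        if self.kind == "inversion":
            return f"inversion([{genes}])"
        t = " | ".join(f"{s}{g}" for g, s in self.target)
        return f"{self.kind}([{genes}] -> ({t}))"


def transposition(block, target) -> RearrangementEvent:
    return RearrangementEvent("transposition", block=tuple(block), target=tuple(target))


def inversion(block) -> RearrangementEvent:
    return RearrangementEvent("inversion", block=tuple(block))


def reverse_transposition(block, target) -> RearrangementEvent:
    return RearrangementEvent("reverse_transposition", block=tuple(block), target=tuple(target))


def tdrl(region, loss_assignment) -> RearrangementEvent:
    return RearrangementEvent("tdrl", region=tuple(region), loss_assignment=tuple(loss_assignment))


def paralog_remold(donor: str, recipient: str, side: str = "downstream") -> RearrangementEvent:
    return RearrangementEvent("paralog_remold", donor=donor, recipient=recipient, side=side)


# ---------------------------------------------------------------------------
# Applying events
# ---------------------------------------------------------------------------

def _find_block(elems: tuple[Element, ...], block: tuple[Element, ...]) -> int:
    n, l = len(elems), len(block)
    if l >= n:
        raise ValueError("block must be shorter than the whole circle")
    for i in range(n):
        if all(elems[(i + k) % n] == block[k] for k in range(l)):
            return i
    raise ValueError(f"block {block} not contiguous in order")


def _remove_block(elems: tuple[Element, ...], i: int, l: int) -> list[Element]:
    n = len(elems)
    removed = {(i + k) % n for k in range(l)}
    return [e for idx, e in enumerate(elems) if idx not in removed]


def _insert_at_target(
    rest: list[Element], block: tuple[Element, ...], target: tuple[Element, Element]
) -> list[Element]:
    left, right = target
    for e in block:
        if e in (left, right) or (e[0], _flip(e[1])) in (left, right):
            raise ValueError(f"target {target} lies inside the moved block")
    try:
        li = rest.index(left)
    except ValueError:
        raise ValueError(f"target element {left} absent from order") from None
    if rest[(li + 1) % len(rest)] != right:
        raise ValueError(f"target {target} is not an adjacency of the order")
    return rest[: li + 1] + list(block) + rest[li + 1 :]


def apply_event(order: GeneOrder, event: RearrangementEvent) -> GeneOrder:
    """Apply one event, returning the edited order.

    Raises ``ValueError`` if the event is not applicable (block not
    contiguous, invalid target, missing paralog).
    """
    elems = order.elements
    if event.kind == "transposition":
        i = _find_block(elems, event.block)
        rest = _remove_block(elems, i, len(event.block))
        return GeneOrder(_insert_at_target(rest, event.block, event.target))
    if event.kind == "reverse_transposition":
        i = _find_block(elems, event.block)
        rest = _remove_block(elems, i, len(event.block))
        inverted = tuple((g, _flip(s)) for g, s in reversed(event.block))
        return GeneOrder(_insert_at_target(rest, inverted, event.target))
    if event.kind == "inversion":
        i = _find_block(elems, event.block)
        n, l = len(elems), len(event.block)
        inverted = tuple((g, _flip(s)) for g, s in reversed(event.block))
        out = list(elems)
        for k in range(l):
            out[(i + k) % n] = inverted[k]
        return GeneOrder(out)
    if event.kind == "tdrl":
        i = _find_block(elems, event.region)
        rest = _remove_block(elems, i, len(event.region))
        copy1 = [e for e, w in zip(event.region, event.loss_assignment) if w == 1]
        copy2 = [e for e, w in zip(event.region, event.loss_assignment) if w == 2]
        n = len(elems)
        # re-anchor at the element preceding the region
        pred = elems[(i - 1) % n]
        li = rest.index(pred)
        return GeneOrder(rest[: li + 1] + copy1 + copy2 + rest[li + 1 :])
    if event.kind == "paralog_remold":
        names = [g for g, _ in elems]
        if event.donor not in names or event.recipient not in names:
            raise ValueError(
                f"remold needs both paralogs present ({event.donor}, {event.recipient})"
            )
        rest = [e for e in elems if e[0] != event.recipient]
        di = next(i for i, (g, _) in enumerate(rest) if g == event.donor)
        new = (event.recipient, rest[di][1])
        if event.side == "downstream":
            rest.insert(di + 1, new)
        else:
            rest.insert(di, new)
        return GeneOrder(rest)
    raise ValueError(f"unknown event kind {event.kind!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """An ordered event list transforming ``source`` into ``target``."""

    source: GeneOrder
    events: tuple[RearrangementEvent, ...]
    intermediates: tuple[GeneOrder, ...]
    target: GeneOrder

    @classmethod
    def build(cls, source: GeneOrder, events) -> "Scenario":
        """Fold events over ``source``; validates every application."""
        intermediates = []
        current = source
        for event in events:
            current = apply_event(current, event)
            intermediates.append(current)
        return cls(source, tuple(events), tuple(intermediates), current)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def grouped(self) -> list[list[RearrangementEvent]]:
        return grouped_steps(self.events)

    def to_dict(self) -> dict:
        return {
            "source": str(self.source),
            "target": str(self.target),
            "events": [e.describe() for e in self.events],
            "grouped_steps": [[e.describe() for e in step] for step in self.grouped],
        }


def _is_trna_move(event: RearrangementEvent) -> bool:
    return (
        event.kind in ("transposition", "reverse_transposition")
        and event.block is not None
        and all(GENE_KIND.get(g) == "tRNA" for g, _ in event.block)
    )


def grouped_steps(events) -> list[list[RearrangementEvent]]:
    """Group unit events into mechanism phases.

    Heuristic: consecutive moves (transpositions or reverse transpositions)
    whose blocks consist only of tRNA genes are one phase — the usual
    reading of rearrangement figures, which draw simultaneous tRNA
    translocations as a single step.  Every other event is its own phase.
    """
    steps: list[list[RearrangementEvent]] = []
    for event in events:
        if steps and _is_trna_move(event) and _is_trna_move(steps[-1][-1]):
            steps[-1].append(event)
        else:
            steps.append([event])
    return steps


def paper_scenarios() -> tuple[Scenario, Scenario]:
    """The published stepwise scenarios for the two derived gene orders.

    Both start from the pancrustacean ground pattern.  Gebiidea
    (A. edulis / U. major): transpositions of trnI and of the trnC+trnY
    pair, a duplication/random-loss translocation of trnQ (encoded as a
    TDRL of the CR–trnQ segment), then remolding of trnL1 from a duplicated
    trnL2.  Axiidea (N. glyptocercus / N. thermophilus): reverse
    transposition of trnI, duplication/random-loss translocation of cox3,
    transposition of trnD plus reverse transposition of trnV, then the
    trnL1 remolding.  Grouped step counts are 3 and 4.
    """
    gp = fixture_order("ground_pattern")
    gebiidea_events = (
        transposition([("trnI", "+")], (("trnS2", "+"), ("nad1", "-"))),
        transposition([("trnC", "-"), ("trnY", "-")], (("trnQ", "-"), ("trnM", "+"))),
        tdrl([("CR", "+"), ("trnQ", "-")], (2, 1)),
        paralog_remold("trnL2", "trnL1", side="downstream"),
    )
    axiidea_events = (
        reverse_transposition([("trnI", "+")], (("rrnS", "-"), ("CR", "+"))),
        tdrl([("cox3", "+"), ("trnG", "+"), ("nad3", "+")], (2, 1, 1)),
        transposition([("trnD", "+")], (("trnQ", "-"), ("trnM", "+"))),
        reverse_transposition([("trnV", "-")], (("trnG", "+"), ("nad3", "+"))),
        paralog_remold("trnL2", "trnL1", side="upstream"),
    )
    return Scenario.build(gp, gebiidea_events), Scenario.build(gp, axiidea_events)


def remold_support(pair: tuple[str, str]) -> float:
    """Percent identity between two tRNA sequences (delegates to trna_paralog)."""
    from .trna_paralog import similarity

    return similarity(*pair)


# ---------------------------------------------------------------------------
# Scenario inference
# ---------------------------------------------------------------------------

_KIND_RANK = {k: r for r, k in enumerate(EVENT_KINDS)}


class _IntOrder:
    """Integer encoding of a signed circular order for the search kernel."""

    def __init__(self, genes: list[str]):
        self.genes = sorted(genes)
        self.index = {g: i + 1 for i, g in enumerate(self.genes)}
        try:
            self.anchor = self.index["cox1"]
        except KeyError:
            self.anchor = None

    def encode(self, order: GeneOrder) -> tuple[int, ...]:
        # the raw reading is kept as-is: children stay aligned (up to
        # rotation, which circular block matching tolerates) with the
        # name-level replay in Scenario.build, so decoded events always apply
        return tuple(
            self.index[g] if s == "+" else -self.index[g] for g, s in order.elements
        )

    def decode_elem(self, x: int) -> Element:
        return (self.genes[abs(x) - 1], "+" if x > 0 else "-")


def _adjacency_matrix(ref: tuple[int, ...], m: int, cr: int | None) -> np.ndarray:
    """ok[a+m, b+m] == True iff the adjacency (a, b) ~ (-b, -a) is in ref.

    The control region is sign-blind (it is unstranded by convention), so
    +-cr compare equal on either side of an adjacency.
    """

    def norm(a: int, b: int):
        fix = lambda x: abs(x) if cr is not None and abs(x) == cr else x
        return min((fix(a), fix(b)), (fix(-b), fix(-a)))

    n = len(ref)
    pairs = {norm(ref[i], ref[(i + 1) % n]) for i in range(n)}
    ok = np.zeros((2 * m + 1, 2 * m + 1), dtype=bool)
    for a in range(-m, m + 1):
        if a == 0:
            continue
        for b in range(-m, m + 1):
            if b == 0:
                continue
            if norm(a, b) in pairs:
                ok[a + m, b + m] = True
    return ok


def _move_template(n: int) -> dict[str, np.ndarray]:
    """Index arrays for every (block start i, length l, target gap t).

    Rows are ordered lexicographically by (i, l, t); blocks never wrap the
    linear origin (every circular move has a non-wrapping representative).
    """
    rows_i, rows_l, rows_t = [], [], []
    for i in range(n):
        for l in range(1, n - 1):
            if i + l > n:
                continue
            gl, gr = (i - 1) % n, i + l - 1
            for t in range(n):
                t_rel = (t - gl) % n
                if t_rel <= l:  # block boundary or internal gap
                    continue
                rows_i.append(i)
                rows_l.append(l)
                rows_t.append(t)
    i_arr = np.array(rows_i, dtype=np.int64)
    l_arr = np.array(rows_l, dtype=np.int64)
    t_arr = np.array(rows_t, dtype=np.int64)
    return {
        "i": i_arr,
        "l": l_arr,
        "t": t_arr,
        "gl": (i_arr - 1) % n,
        "gr": i_arr + l_arr - 1,
    }


def _inversion_template(n: int) -> dict[str, np.ndarray]:
    rows_i, rows_l = [], []
    for i in range(n):
        for l in range(1, n):
            if i + l > n:
                continue
            rows_i.append(i)
            rows_l.append(l)
    i_arr = np.array(rows_i, dtype=np.int64)
    l_arr = np.array(rows_l, dtype=np.int64)
    return {"i": i_arr, "l": l_arr, "gl": (i_arr - 1) % n, "gr": i_arr + l_arr - 1}


class _Searcher:
    def __init__(
        self,
        source: GeneOrder,
        target: GeneOrder,
        vocabulary,
        cap: int,
        node_budget: int,
        tdrl_max_region: int,
    ):
        self.enc = _IntOrder(sorted(source.genes))
        self.vocab = tuple(vocabulary)
        self.cap = cap
        self.node_budget = node_budget
        self.nodes = 0
        self.tdrl_max_region = tdrl_max_region
        self.src = self.enc.encode(source)
        self.tgt = self.enc.encode(target)
        self.n = len(self.src)
        self.m = len(self.enc.genes)
        self.cr = self.enc.index.get("CR")
        self.ok = _adjacency_matrix(self.tgt, self.m, self.cr)
        self.moves = _move_template(self.n)
        self.invs = _inversion_template(self.n)
        self.use_tdrl = "tdrl" in self.vocab

    def bound(self, bp: int) -> int:
        if bp == 0:
            return 0
        return 1 if self.use_tdrl else -(-bp // 3)

    def breakpoints(self, t: tuple[int, ...]) -> int:
        m = self.m
        bp = 0
        for i in range(self.n):
            a, b = t[i], t[(i + 1) % self.n]
            if not self.ok[a + m, b + m]:
                bp += 1
        return bp

    def _is_bp_array(self, t: tuple[int, ...]) -> np.ndarray:
        e = np.fromiter(t, dtype=np.int64, count=self.n)
        nxt = np.roll(e, -1)
        return ~self.ok[e + self.m, nxt + self.m]

    def children(self, t: tuple[int, ...], budget: int):
        """Yield (sort key, event, child tuple, child bp) within budget.

        Sorted deterministically by (kind rank, block start, length,
        target); generated lazily per kind to keep expansion cheap.
        """
        n, m = self.n, self.m
        e = np.fromiter(t, dtype=np.int64, count=n)
        is_bp = self._is_bp_array(t)
        bp = int(is_bp.sum())
        out = []
        if "transposition" in self.vocab or "reverse_transposition" in self.vocab:
            mv = self.moves
            i_a, l_a, t_a, gl, gr = mv["i"], mv["l"], mv["t"], mv["gl"], mv["gr"]
            p = e[gl]
            s = e[(gr + 1) % n]
            bs = e[i_a]
            be = e[gr]
            t1 = e[t_a]
            t2 = e[(t_a + 1) % n]
            removed = (
                is_bp[gl].astype(np.int64) + is_bp[gr] + is_bp[t_a]
            )
            close_ok = self.ok[p + m, s + m]
            if "transposition" in self.vocab:
                added = (
                    (~close_ok).astype(np.int64)
                    + ~self.ok[t1 + m, bs + m]
                    + ~self.ok[be + m, t2 + m]
                )
                bp_after = bp - removed + added
                for r in np.flatnonzero(bp_after <= budget):
                    out.append(("transposition", int(i_a[r]), int(l_a[r]), int(t_a[r]), int(bp_after[r])))
            if "reverse_transposition" in self.vocab:
                added = (
                    (~close_ok).astype(np.int64)
                    + ~self.ok[t1 + m, -be + m]
                    + ~self.ok[-bs + m, t2 + m]
                )
                bp_after = bp - removed + added
                for r in np.flatnonzero(bp_after <= budget):
                    out.append(("reverse_transposition", int(i_a[r]), int(l_a[r]), int(t_a[r]), int(bp_after[r])))
        if "inversion" in self.vocab:
            iv = self.invs
            i_a, l_a, gl, gr = iv["i"], iv["l"], iv["gl"], iv["gr"]
            p = e[gl]
            s = e[(gr + 1) % n]
            bs = e[i_a]
            be = e[gr]
            removed = is_bp[gl].astype(np.int64) + is_bp[gr]
            added = (~self.ok[p + m, -be + m]).astype(np.int64) + ~self.ok[-bs + m, s + m]
            bp_after = bp - removed + added
            for r in np.flatnonzero(bp_after <= budget):
                out.append(("inversion", int(i_a[r]), int(l_a[r]), -1, int(bp_after[r])))
        if self.use_tdrl:
            out.extend(self._tdrl_children(t, budget))
        if "paralog_remold" in self.vocab:
            out.extend(self._remold_children(t, budget))
        out.sort(key=lambda c: (_KIND_RANK[c[0]], c[1], c[2], c[3]))
        return out

    def _tdrl_children(self, t: tuple[int, ...], budget: int):
        n = self.n
        out = []
        for i in range(n):
            for l in range(2, min(self.tdrl_max_region, n - 1) + 1):
                if i + l > n:
                    continue
                region = t[i : i + l]
                for mask in range(1, 2**l - 1):
                    keep = tuple(2 if mask >> k & 1 else 1 for k in range(l))
                    copy1 = tuple(x for x, w in zip(region, keep) if w == 1)
                    copy2 = tuple(x for x, w in zip(region, keep) if w == 2)
                    new = t[:i] + copy1 + copy2 + t[i + l :]
                    if new == t:
                        continue
                    bp_after = self.breakpoints(new)
                    if bp_after <= budget:
                        out.append(("tdrl", i, l, mask, bp_after))
        return out

    def _remold_children(self, t: tuple[int, ...], budget: int):
        out = []
        present = {abs(x) for x in t}
        for pi, (recipient, donor) in enumerate(_REMOLD_PAIRS):
            ri = self.enc.index.get(recipient)
            di = self.enc.index.get(donor)
            if ri is None or di is None or ri not in present or di not in present:
                continue
            for si, side in enumerate(("downstream", "upstream")):
                rest = [x for x in t if abs(x) != ri]
                dpos = next(j for j, x in enumerate(rest) if abs(x) == di)
                sign = 1 if rest[dpos] > 0 else -1
                insert_at = dpos + 1 if side == "downstream" else dpos
                new = tuple(rest[:insert_at] + [sign * ri] + rest[insert_at:])
                if new == t:
                    continue
                bp_after = self.breakpoints(new)
                if bp_after <= budget:
                    out.append(("paralog_remold", pi, si, -1, bp_after))
        return out

    def _norm_cr(self, t: tuple[int, ...]) -> tuple[int, ...]:
        # CR is unstranded; keep it positive so decoded events always match
        # the name-level replay, where GeneOrder normalizes CR to '+'
        if self.cr is not None and -self.cr in t:
            return tuple(abs(x) if abs(x) == self.cr else x for x in t)
        return t

    def materialize(self, t: tuple[int, ...], child) -> tuple[RearrangementEvent, tuple[int, ...]]:
        event, new = self._materialize_raw(t, child)
        return event, self._norm_cr(new)

    def _materialize_raw(self, t: tuple[int, ...], child) -> tuple[RearrangementEvent, tuple[int, ...]]:
        kind, a, b, c, _ = child
        dec = self.enc.decode_elem
        n = self.n
        if kind in ("transposition", "reverse_transposition"):
            i, l, tg = a, b, c
            block_ints = t[i : i + l]
            rest = t[:i] + t[i + l :]
            new_idx = tg - l if tg > i + l - 1 else tg
            moved = (
                tuple(-x for x in reversed(block_ints))
                if kind == "reverse_transposition"
                else block_ints
            )
            new = rest[: new_idx + 1] + moved + rest[new_idx + 1 :]
            event = RearrangementEvent(
                kind,
                block=tuple(dec(x) for x in block_ints),
                target=(dec(t[tg]), dec(t[(tg + 1) % n])),
            )
            return event, new
        if kind == "inversion":
            i, l = a, b
            block_ints = t[i : i + l]
            new = t[:i] + tuple(-x for x in reversed(block_ints)) + t[i + l :]
            return RearrangementEvent(kind, block=tuple(dec(x) for x in block_ints)), new
        if kind == "tdrl":
            i, l, mask = a, b, c
            region = t[i : i + l]
            keep = tuple(2 if mask >> k & 1 else 1 for k in range(l))
            copy1 = tuple(x for x, w in zip(region, keep) if w == 1)
            copy2 = tuple(x for x, w in zip(region, keep) if w == 2)
            new = t[:i] + copy1 + copy2 + t[i + l :]
            event = RearrangementEvent(
                "tdrl", region=tuple(dec(x) for x in region), loss_assignment=keep
            )
            return event, new
        if kind == "paralog_remold":
            pi, si = a, b
            recipient, donor = _REMOLD_PAIRS[pi]
            side = ("downstream", "upstream")[si]
            ri, di = self.enc.index[recipient], self.enc.index[donor]
            rest = [x for x in t if abs(x) != ri]
            dpos = next(j for j, x in enumerate(rest) if abs(x) == di)
            sign = 1 if rest[dpos] > 0 else -1
            insert_at = dpos + 1 if side == "downstream" else dpos
            new = tuple(rest[:insert_at] + [sign * ri] + rest[insert_at:])
            event = RearrangementEvent(
                "paralog_remold", donor=donor, recipient=recipient, side=side
            )
            return event, new
        raise AssertionError(kind)  # pragma: no cover

    def search(self, max_events: int) -> list[tuple[RearrangementEvent, ...]]:
        bp0 = self.breakpoints(self.src)
        if bp0 == 0:
            return [()]
        results: list[tuple[RearrangementEvent, ...]] = []
        for limit in range(max(1, self.bound(bp0)), max_events + 1):
            results = []
            self._dfs(self.src, limit, [], results)
            if results:
                break
        return results

    def _dfs(self, t, remaining: int, path, results) -> None:
        if len(results) >= self.cap:
            return
        if remaining == 0:
            return
        self.nodes += 1
        if self.nodes > self.node_budget:
            raise SearchSpaceExceeded(
                f"scenario search exceeded node budget of {self.node_budget}"
            )
        budget = 3 * (remaining - 1) if not self.use_tdrl else (0 if remaining == 1 else 10**9)
        for child in self.children(t, budget):
            if len(results) >= self.cap:
                return
            event, new = self.materialize(t, child)
            if child[4] == 0:
                results.append(tuple(path + [event]))
                continue
            path.append(event)
            self._dfs(new, remaining - 1, path, results)
            path.pop()


def infer_scenario(
    source: GeneOrder,
    target: GeneOrder,
    vocabulary=DEFAULT_VOCABULARY,
    max_events: int = 6,
    cap: int = 10,
    node_budget: int = 500_000,
    tdrl_max_region: int = 6,
) -> list[Scenario]:
    """All minimum-length scenarios from ``source`` to ``target``.

    Iterative deepening guarantees that the returned length is minimal: for
    every depth below it the (pruned but exhaustive) search found nothing.
    Returns at most ``cap`` scenarios in deterministic order, or an empty
    list if no scenario of at most ``max_events`` events exists.

    Raises
    ------
    SearchSpaceExceeded
        If more than ``node_budget`` nodes are expanded.
    ValueError
        If the orders are over different gene sets or the vocabulary is
    unknown.
    """
    if source.genes != target.genes:
        raise ValueError("source and target are over different gene sets")
    unknown = set(vocabulary) - set(EVENT_KINDS)
    if unknown:
        raise ValueError(f"unknown event kinds {sorted(unknown)}")
    if max_events < 0:
        raise ValueError("max_events must be >= 0")
    if source == target:
        return [Scenario.build(source, ())]
    if max_events == 0:
        return []
    searcher = _Searcher(source, target, vocabulary, cap, node_budget, tdrl_max_region)
    event_lists = searcher.search(max_events)
    scenarios = [Scenario.build(source, events) for events in event_lists]
    for scenario in scenarios:
        assert scenario.target == target, "unsound scenario escaped the search"
    return scenarios
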