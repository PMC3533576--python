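"""Event algebra and rearrangement-scenario inference."""

import numpy as np
import pytest

from conftest import oracle_adjacencies, random_signed_order, scramble
from mitorder.gene_order import GeneOrder, breakpoint_distance
from mitorder.rearrangement import (
    apply_event,
    grouped_steps,
    infer_scenario,
    inversion,
    paper_scenarios,
    paralog_remold,
    reverse_transposition,
    tdrl,
    transposition,
)
from mitorder.synthetic_data import SimulationConfig, _sample_event, simulate_history

MOVES_VOCAB = ("transposition", "inversion", "reverse_transposition")


# ---------------------------------------------------------------------------
# Independent brute-force oracle: enumerate every single-event outcome with
# plain list surgery, and BFS for minimal scenario length.
# ---------------------------------------------------------------------------

def _flip(e):
    return (e[0], "-" if e[1] == "+" else "+")


def oracle_children(elems):
    n = len(elems)
    out = []
    for i in range(n):
        for l in range(1, n - 1):
            if i + l > n:
                continue
            block = list(elems[i : i + l])
            rest = list(elems[:i]) + list(elems[i + l :])
            inv = [_flip(e) for e in reversed(block)]
            out.append(tuple(elems[:i]) + tuple(inv) + tuple(elems[i + l :]))  # inversion
            for g in range(len(rest)):
                out.append(tuple(rest[: g + 1]) + tuple(block) + tuple(rest[g + 1 :]))
                out.append(tuple(rest[: g + 1]) + tuple(inv) + tuple(rest[g + 1 :]))
    return out


def oracle_min_events(source, target, max_depth):
    key = lambda elems: frozenset(oracle_adjacencies(tuple(elems)))
    tgt = key(target.elements)
    start = tuple(source.elements)
    if key(start) == tgt:
        return 0
    frontier, seen = [start], {key(start)}
    for depth in range(1, max_depth + 1):
        nxt = []
        for elems in frontier:
            for child in oracle_children(elems):
                k = key(child)
                if k == tgt:
                    return depth
                if k not in seen:
                    seen.add(k)
                    nxt.append(child)
        frontier = nxt
    return None


class TestApplyEvent:
    def test_transposition_moves_trnD_upstream_of_trnM(self, gp):
        event = transposition([("trnD", "+")], (("trnQ", "-"), ("trnM", "+")))
        result = apply_event(gp, event)
        adj = result.adjacencies()
        names = [g for g, _ in result.canonicalize().elements]
        i = names.index("trnD")
        assert names[(i + 1) % len(names)] == "trnM"
        assert names[names.index("trnK") + 1] == "atp8"  # gap closed behind D

    def test_single_gene_inversion_flips_sign_in_place(self):
        order = GeneOrder.from_string("+a +b +c")
        result = apply_event(order, inversion([("b", "+")]))
        assert result == GeneOrder.from_string("+a -b +c")

    def test_reverse_transposition_is_move_plus_flip(self):
        order = GeneOrder.from_string("+a +b +c +d")
        event = reverse_transposition([("b", "+")], (("c", "+"), ("d", "+")))
        assert apply_event(order, event) == GeneOrder.from_string("+a +c -b +d")

    def test_tdrl_keeps_copy1_then_copy2_in_relative_order(self):
        order = GeneOrder.from_string("+a +b +c +d")
        event = tdrl([("a", "+"), ("b", "+"), ("c", "+")], (2, 1, 1))
        assert apply_event(order, event) == GeneOrder.from_string("+b +c +a +d")

    def test_paralog_remold_copies_donor_sign_and_position(self, gp):
        result = apply_event(gp, paralog_remold("trnL2", "trnL1", side="downstream"))
        elems = result.canonicalize().elements
        names = [g for g, _ in elems]
        i = names.index("trnL2")
        assert elems[i + 1] == ("trnL1", "+")  # donor's '+' sign, not ancestral '-'
        assert names.count("trnL1") == 1 and len(elems) == 38

    def test_noncontiguous_block_rejected(self, gp):
        with pytest.raises(ValueError, match="not contiguous"):
            apply_event(gp, inversion([("cox1", "+"), ("cox2", "+")]))

    def test_target_inside_block_rejected(self):
        order = GeneOrder.from_string("+a +b +c +d")
        event = transposition([("b", "+"), ("c", "+")], (("b", "+"), ("c", "+")))
        with pytest.raises(ValueError):
            apply_event(order, event)

    def test_remold_with_missing_paralog_rejected(self, gp):
        smaller = GeneOrder([e for e in gp.elements if e[0] != "trnL1"])
        with pytest.raises(ValueError, match="both paralogs"):
            apply_event(smaller, paralog_remold("trnL2", "trnL1"))

    def test_event_closure_on_random_orders(self):
        # any applicable event yields a valid order over the same gene set
        rng = np.random.default_rng(5)
        kinds = ["transposition", "inversion", "reverse_transposition", "tdrl"]
        for _ in range(60):
            order = random_signed_order(rng, int(rng.integers(4, 12)))
            event = _sample_event(kinds[int(rng.integers(0, 4))], order, rng)
            result = apply_event(order, event)
            assert result.genes == order.genes
            assert len(result) == len(order)


class TestGroupedSteps:
    def test_consecutive_trna_moves_form_one_phase(self, gp):
        events = [
            transposition([("trnI", "+")], (("trnS2", "+"), ("nad1", "-"))),
            transposition([("trnC", "-"), ("trnY", "-")], (("trnQ", "-"), ("trnM", "+"))),
        ]
        assert len(grouped_steps(events)) == 1

    def test_non_trna_moves_break_phases(self, gp):
        events = [
            transposition([("trnI", "+")], (("trnS2", "+"), ("nad1", "-"))),
            transposition([("cox3", "+")], (("nad3", "+"), ("trnA", "+"))),
            transposition([("trnD", "+")], (("trnQ", "-"), ("trnM", "+"))),
        ]
        assert len(grouped_steps(events)) == 3


class TestPaperScenarios:
    def test_folds_hit_the_derived_fixtures(self, gp, gebiidea, axiidea):
        s_geb, s_ax = paper_scenarios()
        assert s_geb.source == gp and s_ax.source == gp
        assert s_geb.target == gebiidea
        assert s_ax.target == axiidea
        for scenario in (s_geb, s_ax):
            current = scenario.source
            for event, intermediate in zip(scenario.events, scenario.intermediates):
                current = apply_event(current, event)
                assert current == intermediate

    def test_grouped_step_counts_are_three_and_four(self):
        s_geb, s_ax = paper_scenarios()
        assert len(s_geb.grouped) == 3
        assert len(s_ax.grouped) == 4
        assert len(s_geb) == 4 and len(s_ax) == 5  # unit events


class TestInferScenario:
    def test_identical_orders_give_single_empty_scenario(self, gp):
        scenarios = infer_scenario(gp, gp)
        assert len(scenarios) == 1 and len(scenarios[0]) == 0

    def test_toy_single_transposition_certified_by_enumeration(self):
        source = GeneOrder.from_string("+a +b +c +d +e")
        target = GeneOrder.from_string("+a +c +b +d +e")
        scenarios = infer_scenario(source, target, vocabulary=MOVES_VOCAB, max_events=3)
        assert scenarios and all(len(s) == 1 for s in scenarios)
        assert oracle_min_events(source, target, 2) == 1
        for s in scenarios:
            assert s.target == target

    def test_tdrl_shortcuts_an_interleaving(self):
        source = GeneOrder.from_string("+a +b +c +d +e +f")
        target = GeneOrder.from_string("+a +c +e +b +d +f")
        with_tdrl = infer_scenario(
            source, target, vocabulary=MOVES_VOCAB + ("tdrl",), max_events=2, cap=3
        )
        assert with_tdrl and len(with_tdrl[0]) == 1
        without = infer_scenario(source, target, vocabulary=MOVES_VOCAB, max_events=3, cap=3)
        assert without and len(without[0]) == 2

    def test_minimality_matches_bfs_oracle_on_toys(self):
        rng = np.random.default_rng(13)
        cases = 0
        while cases < 8:
            n = int(rng.integers(5, 9))
            depth_cap = 3 if n <= 5 else 2
            base = random_signed_order(rng, n)
            derived = scramble(rng, base, int(rng.integers(1, depth_cap + 1)))
            true_min = oracle_min_events(base, derived, depth_cap)
            if true_min is None:
                continue
            scenarios = infer_scenario(
                base, derived, vocabulary=MOVES_VOCAB, max_events=depth_cap, cap=5
            )
            assert scenarios, f"search found nothing though oracle says {true_min}"
            assert len(scenarios[0]) == true_min
            cases += 1

    def test_ground_pattern_to_gebiidea_needs_exactly_four_events(self, gp, gebiidea):
        # the bound ceil(breakpoints/3) proves 3 events cannot suffice
        assert breakpoint_distance(gebiidea, gp) == 10
        assert infer_scenario(gp, gebiidea, max_events=3) == []
        scenarios = infer_scenario(gp, gebiidea, max_events=4, cap=5)
        assert scenarios and all(len(s) == 4 for s in scenarios)
        for s in scenarios:
            assert s.target == gebiidea

    def test_ground_pattern_to_axiidea_needs_exactly_five_events(self, gp, axiidea):
        assert breakpoint_distance(axiidea, gp) == 15
        assert infer_scenario(gp, axiidea, max_events=4) == []
        scenarios = infer_scenario(gp, axiidea, max_events=5, cap=3)
        assert scenarios and all(len(s) == 5 for s in scenarios)

    def test_simulated_histories_never_compress_below_truth(self):
        for seed in range(20):
            k = 1 + seed % 3
            truth = simulate_history(SimulationConfig(seed=500 + seed, n_events=k))
            scenarios = infer_scenario(truth.source, truth.order, max_events=k, cap=1)
            assert scenarios, f"seed {seed}: no scenario within true length {k}"
            assert len(scenarios[0]) <= k

    def test_inversion_sweeping_the_control_region_is_recoverable(self, gp):
        # CR is unstranded; a block inversion spanning it must still be
        # found and replayed (regression: CR sign bookkeeping in the search)
        event = inversion([("rrnS", "-"), ("CR", "+"), ("trnI", "+")])
        target = apply_event(gp, event)
        scenarios = infer_scenario(gp, target, max_events=2, cap=3)
        assert scenarios and len(scenarios[0]) == 1
        for s in scenarios:
            assert s.target == target

    def test_different_gene_sets_rejected(self, gp):
        toy = GeneOrder.from_string("+a +b")
        with pytest.raises(ValueError):
            infer_scenario(gp, toy)
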