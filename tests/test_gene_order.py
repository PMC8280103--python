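"""Signed circular gene orders: breakpoints, event detection, TDRL."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from mitochar.gene_order import (
    GeneOrder,
    apply_events,
    breakpoint_distance,
    detect_events,
    linear_map,
    load_named_orders,
    order_from_annotation,
    rotation_equal,
    tdrl_one_step,
)


@pytest.fixture(scope="module")
def ancestral(named_orders=None):
    return load_named_orders()["ancestral_decapoda"]


class TestGeneOrderBasics:
    def test_string_round_trip(self):
        text = "cox1,cox2,-nad1,trnL2"
        assert GeneOrder.from_string(text).to_string() == text

    def test_normalization_anchors_cox1(self, ancestral):
        rotated = ancestral.rotated(17)
        assert rotated.normalized().tokens[0] == ("cox1", 1)
        assert rotated.normalized().tokens == ancestral.normalized().tokens

    def test_order_from_annotation_reference(self, reference_annotation):
        order = order_from_annotation(reference_annotation).normalized()
        names = order.names
        i = names.index("cox1")
        assert names[i:i + 4] == ("cox1", "cox2", "trnL2", "trnK")

    def test_order_from_annotation_single_feature(self):
        from mitochar.annotation_io import GeneFeature, MitoAnnotation

        ann = MitoAnnotation(100, [GeneFeature("cox1", "PCG", 1, 1, 90)])
        assert order_from_annotation(ann).tokens == (("cox1", 1),)

    def test_synthetic_round_trip(self, synthetic_genome, named_orders):
        order = order_from_annotation(synthetic_genome).normalized()
        assert order.tokens == \
            named_orders["ancestral_decapoda"].normalized().tokens


class TestBreakpointDistance:
    def test_identical_orders_zero(self, ancestral):
        assert breakpoint_distance(ancestral, ancestral) == 0

    def test_rotation_invariance(self, ancestral):
        derived = load_named_orders()["ensirostris"]
        base = breakpoint_distance(derived, ancestral)
        for k in (1, 5, 20):
            assert breakpoint_distance(derived.rotated(k), ancestral) == base
            assert breakpoint_distance(derived, ancestral.rotated(k)) == base

    def test_focal_vs_ancestral_is_three(self, reference_annotation,
                                         named_orders):
        derived = order_from_annotation(reference_annotation)
        assert breakpoint_distance(
            derived, named_orders["ancestral_decapoda"]) == 3

    def test_matches_brute_force_adjacency_enumeration(self,
                                                       reference_annotation,
                                                       named_orders):
        derived = order_from_annotation(reference_annotation)
        ref = named_orders["ancestral_decapoda"]
        d, r = derived.normalized().tokens, ref.normalized().tokens
        d_adj = {(d[i], d[(i + 1) % len(d)]) for i in range(len(d))}
        r_adj = {(r[i], r[(i + 1) % len(r)]) for i in range(len(r))}
        assert breakpoint_distance(derived, ref) == len(d_adj - r_adj)

    def test_single_reversal_on_toy(self):
        ref = GeneOrder.from_string("a,b,c,d,e")
        derived = ref.invert("b")
        assert breakpoint_distance(derived, ref) == 2

    def test_zero_iff_rotation_equal(self):
        rng = random.Random(77)
        names = list("abcdefg")
        for _ in range(100):
            perm = names[:]
            rng.shuffle(perm)
            signs = [rng.choice([1, -1]) for _ in perm]
            derived = GeneOrder(tuple(zip(perm, signs)), anchor="a")
            ref = GeneOrder(tuple((n, 1) for n in names), anchor="a")
            zero = breakpoint_distance(derived, ref) == 0
            assert zero == rotation_equal(derived, ref)

    def test_random_translocations_bounded_by_3k(self, ancestral):
        rng = random.Random(4)
        for k in (1, 2, 3):
            order = ancestral
            movable = [n for n in order.names if n != "cox1"]
            for _ in range(k):
                gene = rng.choice(movable)
                after = rng.choice([n for n in order.names if n != gene])
                order = order.translocate(gene, after)
            assert breakpoint_distance(order, ancestral) <= 3 * k

    def test_disjoint_universes_error(self):
        with pytest.raises(ValueError):
            breakpoint_distance(GeneOrder.from_string("a,b"),
                                GeneOrder.from_string("x,y"))


class TestDetectEvents:
    def test_identity_report_empty(self, ancestral):
        rep = detect_events(ancestral, ancestral)
        assert rep.breakpoints == 0
        assert rep.translocated == rep.inverted == rep.duplicated == ()
        assert rep.tdrl_one_step

    def test_focal_translocation_is_trnL2(self, named_orders):
        rep = detect_events(named_orders["ensirostris"],
                            named_orders["ancestral_decapoda"])
        assert rep.translocated == ("trnL2",)
        assert rep.inverted == ()
        assert rep.duplicated == ()
        assert rep.tdrl_one_step

    def test_alpheid_trnE_moves_and_reverses(self, named_orders):
        rep = detect_events(named_orders["alpheidae"],
                            named_orders["ancestral_decapoda"])
        assert rep.translocated == ("trnE",)
        assert rep.inverted == ("trnE",)
        assert not rep.tdrl_one_step  # inversion rules a single TDRL out

    def test_duplication_detected(self, named_orders):
        rep = detect_events(named_orders["alpheus_lobidens"],
                            named_orders["ancestral_decapoda"])
        assert rep.duplicated == ("trnQ",)

    def test_round_trip_reapplication(self, named_orders):
        ref = named_orders["ancestral_decapoda"]
        for name in ("ensirostris", "alpheidae"):
            derived = named_orders[name]
            rep = detect_events(derived, ref)
            assert not rep.complex
            rebuilt = apply_events(ref, rep)
            shared = set(rebuilt.names) & set(derived.names)
            assert rotation_equal(rebuilt.restrict(shared),
                                  derived.restrict(shared))

    def test_block_move_beyond_max_moved_flagged_complex(self, ancestral):
        # an 8-gene block move (as in Hymenocera picta) exceeds max_moved=3
        block = ["nad1", "trnL1", "rrnL", "trnV", "rrnS", "CR",
                 "trnI", "trnQ"]
        order = ancestral
        for gene in reversed(block):
            order = order.translocate(gene, "nad4l")
        rep = detect_events(order, ancestral, max_moved=3)
        assert rep.complex
        assert rep.translocated == ()
        assert rep.breakpoints > 0


class TestTdrl:
    def test_focal_span_reachable(self, named_orders):
        ok, reason = tdrl_one_step(named_orders["ensirostris"],
                                   named_orders["ancestral_decapoda"],
                                   segment=["cox1", "cox2", "trnL2", "trnK"])
        assert ok and reason == ""

    def test_identity_trivially_reachable(self, ancestral):
        ok, _ = tdrl_one_step(ancestral, ancestral)
        assert ok

    def test_full_reversal_not_reachable(self):
        derived = GeneOrder.from_string("c,b,a")
        ref = GeneOrder.from_string("a,b,c")
        ok, _ = tdrl_one_step(derived, ref)
        assert not ok

    def test_inversion_rules_out_tdrl(self, ancestral):
        derived = ancestral.invert("trnK")
        ok, reason = tdrl_one_step(derived, ancestral)
        assert not ok and "invert" in reason

    def test_agrees_with_duplication_loss_enumeration(self):
        """tdrl_one_step equals brute-force enumeration of every loss
        pattern of a tandem duplication, over 500 seeded random orders of
        length <= 7."""
        rng = random.Random(2024)

        def brute(derived_names, ref_names):
            doubled = ref_names + ref_names
            n = len(ref_names)
            for keep in itertools.product((0, 1), repeat=n):
                # keep[i]=0: first copy of gene ref_names[i], else second
                result = []
                for j, g in enumerate(doubled):
                    i = j % n
                    if (j < n) == (keep[i] == 0):
                        result.append(g)
                if tuple(result) == tuple(derived_names):
                    return True
            return False

        for trial in range(500):
            n = rng.randint(1, 7)
            names = [f"g{i}" for i in range(n)]
            perm = names[:]
            rng.shuffle(perm)
            derived = GeneOrder(tuple((g, 1) for g in perm))
            ref = GeneOrder(tuple((g, 1) for g in names))
            got, _ = tdrl_one_step(derived, ref)
            assert got == brute(tuple(perm), tuple(names)), (perm, names)


def test_linear_map_lists_all_genes(named_orders):
    text = linear_map(named_orders["ensirostris"])
    assert text.startswith("cox1")
    assert "(nad1)" in text  # light strand bracketed
    for name in named_orders["ensirostris"].names:
        assert name in text
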