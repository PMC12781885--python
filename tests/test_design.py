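from itertools import product

import numpy as np
import pytest

from pforge.design import (
    ConstraintMask,
    build_variant_library,
    refine_motif_sequence,
)
from pforge.io import NucSequence
from pforge.pssm import PSSM, score_window
from pforge.sites import InsertionPlan
from pforge.synth import gen_control_promoter


def _plan(motif, position, direction="maximize"):
    return InsertionPlan(motif, position, direction, 0.0, 1.0, True)


def _promoter_with(fragment, at, rng, length=60):
    seq = "".join(rng.choice(list("ACGT"), length))
    idx = length + at
    seq = seq[:idx] + fragment + seq[idx + len(fragment):]
    return NucSequence("p", seq, length)


EMPTY_MASK = ConstraintMask(frozenset())


class TestRefinement:
    def test_consensus_fragment_needs_no_iterations(self, rng):
        motif = PSSM("m", rng.dirichlet([0.5] * 4, 6))
        prom = _promoter_with(motif.consensus, -30, rng)
        plan = _plan(motif, -30)
        refined, trace = refine_motif_sequence(prom, plan, EMPTY_MASK)
        assert refined == motif.consensus
        assert len(trace.steps) == 1  # initial score only
        assert plan.edits == []

    @pytest.mark.parametrize("direction", ["maximize", "minimize"])
    def test_matches_exhaustive_optimum(self, direction, rng):
        for trial in range(10):
            L = int(rng.integers(3, 6))
            motif = PSSM("m", rng.dirichlet([0.6] * 4, L))
            prom = _promoter_with("".join(rng.choice(list("ACGT"), L)), -20, rng)
            plan = _plan(motif, -20, direction)
            refined, trace = refine_motif_sequence(prom, plan, EMPTY_MASK)
            exhaustive = [score_window(motif, "".join(w)) for w in product("ACGT", repeat=L)]
            target = max(exhaustive) if direction == "maximize" else min(exhaustive)
            assert score_window(motif, refined) == pytest.approx(target)

    def test_trace_strictly_monotone_and_bounded(self, rng):
        motif = PSSM("m", rng.dirichlet([0.5] * 4, 8))
        prom = _promoter_with("A" * 8, -40, rng)
        plan = _plan(motif, -40)
        _, trace = refine_motif_sequence(prom, plan, EMPTY_MASK)
        scores = trace.scores
        assert all(b > a for a, b in zip(scores, scores[1:]))
        assert len(scores) - 1 <= 3 * 8

    def test_masked_positions_untouched(self, rng):
        motif = PSSM("m", rng.dirichlet([0.5] * 4, 6))
        prom = _promoter_with("AAAAAA", -30, rng)
        mask = ConstraintMask(frozenset({-30, -29}))
        plan = _plan(motif, -30)
        refined, _ = refine_motif_sequence(prom, plan, mask)
        assert refined[:2] == "AA"
        assert all(c not in mask.coords for c, _, _ in plan.edits)

    def test_fully_masked_fragment_rejected(self, rng):
        motif = PSSM("m", rng.dirichlet([0.5] * 4, 4))
        prom = _promoter_with("AAAA", -20, rng)
        mask = ConstraintMask(frozenset(range(-20, -16)))
        with pytest.raises(ValueError, match="no mutable positions"):
            refine_motif_sequence(prom, _plan(motif, -20), mask)


@pytest.fixture
def refined_plans(rng):
    """3 A-plans and 4 B-plans with disjoint 4-nt edit spans."""
    control = gen_control_promoter(120, np.random.default_rng(3))
    mask = ConstraintMask.default_for(control)
    positions = [-100, -90, -80, -70, -60, -50, -40]
    plans = []
    for k, pos in enumerate(positions):
        freq = np.full((4, 4), 0.01)
        # consensus differs from the control at every position, so each
        # refined plan edits its full 4-nt span
        frag = control.fragment(pos, 4)
        for j in range(4):
            freq[j, ("ACGT".index(frag[j]) + 1) % 4] = 0.97
        motif = PSSM(f"m{k}", freq, direction="over")
        plan = _plan(motif, pos)
        refine_motif_sequence(control, plan, mask)
        assert plan.edits, "fixture requires real edits"
        plans.append(plan)
    return control, mask, plans[:3], plans[3:]


class TestVariantLibrary:
    def test_cartesian_combinatorics(self, refined_plans):
        control, mask, plans_a, plans_b = refined_plans
        variants = build_variant_library(control, plans_a, plans_b, mask)
        assert len(variants) == 3 + 4 + 12

    def test_overlapping_pair_omitted(self, refined_plans):
        control, mask, plans_a, plans_b = refined_plans
        # a B plan whose edit span starts on the last edited base of A plan 0
        pos = plans_a[0].target_position + 3
        freq = np.full((4, 4), 0.01)
        frag = control.fragment(pos, 4)
        for j in range(4):
            freq[j, ("ACGT".index(frag[j]) + 1) % 4] = 0.97
        clash = _plan(PSSM("clash", freq, direction="over"), pos)
        refine_motif_sequence(control, clash, mask)
        variants = build_variant_library(control, plans_a, [clash] + plans_b[1:], mask)
        assert len(variants) == 3 + 4 + 11

    def test_masked_edit_rejected_with_coordinates(self, refined_plans):
        control, mask, plans_a, plans_b = refined_plans
        bad = _plan(plans_a[0].motif, plans_a[0].target_position)
        kpni = control.seq.find("GGTACC") - control.anchor
        bad.edits = [(kpni, control.seq[control.coord_to_index(kpni)], "A")]
        bad.refined_fragment = "AAAA"
        with pytest.raises(ValueError, match=str(kpni)):
            build_variant_library(control, [bad], plans_b, mask)

    def test_every_variant_differs_and_keeps_restriction_sites(self, refined_plans):
        control, mask, plans_a, plans_b = refined_plans
        variants = build_variant_library(control, plans_a, plans_b, mask)
        for v in variants:
            assert v.sequence.seq != control.seq
            assert "GGTACC" in v.sequence.seq
            assert "ATTTAAAT" in v.sequence.seq
            for coord, ref, new in v.edits:
                assert coord not in mask.coords

    def test_unrefined_plan_rejected(self, refined_plans):
        control, mask, plans_a, plans_b = refined_plans
        raw = _plan(plans_a[0].motif, -55)
        with pytest.raises(ValueError, match="refined"):
            build_variant_library(control, [raw], plans_b, mask)


def test_default_mask_covers_restriction_sites():
    control = gen_control_promoter(120, np.random.default_rng(0))
    mask = ConstraintMask.default_for(control)
    kpni = control.seq.find("GGTACC") - control.anchor
    swai = control.seq.find("ATTTAAAT") - control.anchor
    assert all(kpni + i in mask.coords for i in range(6))
    assert all(swai + i in mask.coords for i in range(8))
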