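"""Greedy refinement of motif sites and constrained variant-library assembly.

Refinement hill-climbs the promoter fragment at a motif's chosen site:
each iteration tries every single-base substitution at positions that are
neither constrained (restriction sites, user-marked spans) nor the
position changed in the immediately preceding iteration, applies the one
with the largest strict improvement, and stops when none improves. The
library then contains one variant per accepted plan plus one per
non-overlapping pair of plans taken across the two datasets (Cartesian
pairing), always substitution-in-place so promoter length is preserved.
"""

from __future__ import annotations

import dataclasses
import logging
import re

import numpy as np

from .io import NucSequence
from .pssm import ALPHABET, PSSM, score_window
from .sites import InsertionPlan

logger = logging.getLogger("pforge")

#: restriction sites that delimit the cloning insert and must stay intact
DEFAULT_SITE_PATTERNS = {"KpnI": "GGTACC", "SwaI": "ATTTAAAT"}


@dataclasses.dataclass
class ConstraintMask:
    """Set of immutable start-codon-anchored coordinates."""

    coords: frozenset[int]

    @classmethod
    def from_spans(cls, spans: list[tuple[int, int]]) -> "ConstraintMask":
        """Inclusive coordinate spans -> mask."""
        coords = set()
        for lo, hi in spans:
            coords.update(range(lo, hi + 1))
        return cls(frozenset(coords))

    @classmethod
    def default_for(
        cls, control: NucSequence, extra_spans: list[tuple[int, int]] | None = None
    ) -> "ConstraintMask":
        """Mask every KpnI/SwaI occurrence in the control plus user spans."""
        coords: set[int] = set()
        for pat in DEFAULT_SITE_PATTERNS.values():
            for m in re.finditer(f"(?={pat})", control.seq):
                start = control.index_to_coord(m.start())
                coords.update(range(start, start + len(pat)))
        for lo, hi in extra_spans or []:
            coords.update(range(lo, hi + 1))
        return cls(frozenset(coords))

    def __contains__(self, coord: int) -> bool:
        return coord in self.coords


@dataclasses.dataclass
class RefinementTrace:
    steps: list[tuple[int, int, str, float]]  # (iteration, coordinate, base, score)

    @property
    def scores(self) -> list[float]:
        return [s[3] for s in self.steps]


@dataclasses.dataclass
class VariantDesign:
    variant_id: str
    sequence: NucSequence
    edits: list[tuple[int, str, str]]  # (coordinate, ref base, new base)
    plans_used: list[InsertionPlan]
    dataset_tags: list[str]


def refine_motif_sequence(
    promoter: NucSequence,
    plan: InsertionPlan,
    mask: ConstraintMask,
) -> tuple[str, RefinementTrace]:
    """Hill-climb the fragment at plan.target_position toward the motif's
    extreme score.

    Maximizing drives toward the per-position argmax (consensus) base,
    minimizing toward the argmin; the position changed in one iteration is
    frozen for the next iteration only. The returned trace's scores are
    strictly monotone, and the refined fragment and its per-coordinate
    edits are stored back on the plan.
    """
    motif = plan.motif
    L = len(motif)
    start = plan.target_position
    fragment = list(promoter.fragment(start, L))
    mutable = [i for i in range(L) if (start + i) not in mask]
    if not mutable:
        raise ValueError(
            f"motif {motif.name!r} at {start}: no mutable positions"
        )
    sign = 1.0 if plan.direction == "maximize" else -1.0
    score = score_window(motif, "".join(fragment))
    trace = RefinementTrace(steps=[(0, start, "".join(fragment), score)])
    frozen: int | None = None
    iteration = 0
    while True:
        iteration += 1
        best_gain = 0.0
        best_move: tuple[int, str, float] | None = None
        for i in mutable:
            if i == frozen:
                continue
            current = fragment[i]
            for base in ALPHABET:
                if base == current:
                    continue
                fragment[i] = base
                s = score_window(motif, "".join(fragment))
                gain = sign * (s - score)
                if gain > best_gain or (
                    best_move is not None
                    and gain == best_gain
                    and (i, base) < (best_move[0], best_move[1])
                ):
                    best_gain = gain
                    best_move = (i, base, s)
            fragment[i] = current
        if best_move is None or best_gain <= 0.0:
            break
        i, base, s = best_move
        fragment[i] = base
        score = s
        frozen = i
        trace.steps.append((iteration, start + i, base, score))
    refined = "".join(fragment)
    original = promoter.fragment(start, L)
    plan.refined_fragment = refined
    plan.edits = [
        (start + i, original[i], refined[i])
        for i in range(L)
        if refined[i] != original[i]
    ]
    return refined, trace


def _apply_edits(control: NucSequence, edits, variant_id: str) -> NucSequence:
    seq = list(control.seq)
    for coord, ref, new in edits:
        idx = control.coord_to_index(coord)
        if seq[idx] != ref:
            raise ValueError(
                f"edit at {coord} expects {ref!r} but control has {seq[idx]!r}"
            )
        seq[idx] = new
    return NucSequence(variant_id, "".join(seq), control.anchor)


def _edit_span(plan: InsertionPlan) -> tuple[int, int] | None:
    if not plan.edits:
        return None
    coords = [e[0] for e in plan.edits]
    return (min(coords), max(coords))


def _check_mask(plan: InsertionPlan, mask: ConstraintMask) -> None:
    bad = sorted(c for c, _, _ in (plan.edits or []) if c in mask)
    if bad:
        raise ValueError(
            f"plan for motif {plan.motif.name!r} edits constrained coordinates {bad}"
        )


def build_variant_library(
    control: NucSequence,
    plans_a: list[InsertionPlan],
    plans_b: list[InsertionPlan],
    mask: ConstraintMask,
) -> list[VariantDesign]:
    """Assemble the variant library from refined plans.

    One variant per plan, plus one per (A, B) plan pair whose edited
    coordinate spans do not intersect. Plans must already be refined
    (edits computed); any plan whose edits touch the mask is rejected.
    Variants identical in sequence are deduplicated, and a variant equal
    to the control is dropped.
    """
    for plan in plans_a + plans_b:
        if plan.edits is None:
            raise ValueError(
                f"plan for motif {plan.motif.name!r} has not been refined"
            )
        _check_mask(plan, mask)

    variants: list[VariantDesign] = []
    seen: set[str] = set([control.seq])

    def add(variant_id, plans, tags):
        edits = [e for p in plans for e in p.edits]
        v = _apply_edits(control, edits, variant_id)
        if v.seq in seen:
            logger.warning("variant %s duplicates an earlier sequence; dropped", variant_id)
            return
        seen.add(v.seq)
        variants.append(VariantDesign(variant_id, v, edits, list(plans), tags))

    for i, plan in enumerate(plans_a):
        add(f"A{i+1}_{plan.motif.name}", [plan], ["datasetA"])
    for j, plan in enumerate(plans_b):
        add(f"B{j+1}_{plan.motif.name}", [plan], ["datasetB"])
    for i, pa in enumerate(plans_a):
        sa = _edit_span(pa)
        for j, pb in enumerate(plans_b):
            sb = _edit_span(pb)
            if sa is not None and sb is not None:
                if sa[0] <= sb[1] and sb[0] <= sa[1]:
                    continue  # overlapping edit spans: pair omitted
            add(
                f"A{i+1}B{j+1}_{pa.motif.name}+{pb.motif.name}",
                [pa, pb],
                ["datasetA", "datasetB"],
            )
    return variants


def edit_manifest(variants: list[VariantDesign]) -> list[dict]:
    """JSON-serializable description of every variant's edits."""
    return [
        {
            "variant_id": v.variant_id,
            "edits": [
                {"coordinate": c, "ref": r, "new": n} for c, r, n in v.edits
            ],
            "motifs": [p.motif.name for p in v.plans_used],
            "datasets": v.dataset_tags,
        }
        for v in variants
    ]
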