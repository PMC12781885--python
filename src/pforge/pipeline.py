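"""End-to-end promoter-design pipeline.

Chains the stages: group selection on both datasets, differential motif
discovery in the four target/reference configurations, cross-dataset
motif matching, significant-position scanning and window aggregation,
harmonization, the insert/remove decision, greedy refinement under the
constraint mask, and variant-library assembly.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .design import ConstraintMask, VariantDesign, build_variant_library, refine_motif_sequence
from .discovery import DiscoveryResult, run_four_configurations
from .expression import (
    BinModel,
    ExpressionRecord,
    FlowSeqRecord,
    dataset_a_scores,
    dataset_b_scores,
    select_groups,
)
from .io import NucSequence, RunConfig
from .matching import MotifMatch, match_sets
from .pssm import PSSM, sliding_scores
from .sites import (
    HarmonizedSite,
    InsertionPlan,
    PositionWindow,
    aggregate_windows,
    decide_insertion,
    filter_and_harmonize,
    significant_positions,
)

logger = logging.getLogger("pforge")


@dataclasses.dataclass
class PipelineResult:
    discovery_a: list[DiscoveryResult]
    discovery_b: list[DiscoveryResult]
    matches: list[MotifMatch]
    windows_a: dict[str, PositionWindow]
    windows_b: dict[str, PositionWindow]
    harmonized: list[HarmonizedSite]
    plans: list[InsertionPlan]
    variants: list[VariantDesign]
    motifs: dict[str, PSSM]


def _group_sequences(records, scores, fraction):
    over_ids, under_ids = select_groups(scores, fraction)
    by_id = {r.gene_id if hasattr(r, "gene_id") else r.variant_id: r for r in records}
    over = [by_id[i].promoter for i in over_ids]
    under = [by_id[i].promoter for i in under_ids]
    return over, under


def _motif_windows(
    motifs: list[PSSM],
    promoters_by_direction: dict[str, list[NucSequence]],
    cfg: RunConfig,
    rng: np.random.Generator,
    hits_store: dict,
) -> dict[str, PositionWindow]:
    windows: dict[str, PositionWindow] = {}
    for m in motifs:
        proms = promoters_by_direction.get(m.direction, [])
        hits = []
        for p in proms:
            hits.extend(
                significant_positions(m, p, cfg.n_permutations, cfg.alpha, rng)
            )
        hits_store[m.name] = hits
        _, best = aggregate_windows(hits, cfg.window_radius)
        if best is not None:
            windows[m.name] = best
    return windows


def run_design_pipeline(
    records_a: list[ExpressionRecord],
    records_b: list[FlowSeqRecord],
    bins: BinModel,
    target_promoter: NucSequence,
    cfg: RunConfig | None = None,
    mask: ConstraintMask | None = None,
    max_motifs: int = 5,
    k_range: tuple[int, int] = (6, 10),
    rng: np.random.Generator | None = None,
) -> PipelineResult:
    """Run the full design procedure and return every intermediate product.

    ``max_motifs`` caps the motifs carried forward per discovery
    configuration (keeps the position-scanning stage proportionate).
    """
    cfg = cfg or RunConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    mask = mask or ConstraintMask.default_for(target_promoter)

    # ---- groups
    scores_a = dataset_a_scores(records_a)
    over_a, under_a = _group_sequences(records_a, scores_a, cfg.group_fraction)
    all_a = [r.promoter for r in records_a]

    dnt_records = [r for r in records_b if r.condition == "DNT"]
    scores_b = dataset_b_scores(records_b, bins, "DNT")
    over_b, under_b = _group_sequences(dnt_records, scores_b, cfg.group_fraction)
    seen = set()
    all_b = []
    for r in dnt_records:
        if r.variant_id not in seen:
            seen.add(r.variant_id)
            all_b.append(r.promoter)

    # ---- discovery (four configurations per dataset)
    disc_a = run_four_configurations(
        over_a, under_a, all_a, k_range=k_range, alpha=cfg.alpha,
        rng=rng, max_motifs=max_motifs, source="datasetA",
    )
    disc_b = run_four_configurations(
        over_b, under_b, all_b, k_range=k_range, alpha=cfg.alpha,
        rng=rng, max_motifs=max_motifs, source="datasetB",
    )
    motifs_a = _dedupe([m for r in disc_a for m in r.motifs])
    motifs_b = _dedupe([m for r in disc_b for m in r.motifs])
    if not motifs_a or not motifs_b:
        logger.warning("no motifs discovered in one of the datasets")

    # ---- cross-dataset matching
    matches = (
        match_sets(motifs_a, motifs_b, cfg.n_permutations, cfg.alpha, rng)
        if motifs_a and motifs_b
        else []
    )

    # ---- significant positions and prevalence windows
    groups_a = {"over": over_a, "under": under_a}
    groups_b = {"over": over_b, "under": under_b}
    hits_store: dict = {}
    windows_a = _motif_windows(motifs_a, groups_a, cfg, rng, hits_store)
    windows_b = _motif_windows(motifs_b, groups_b, cfg, rng, hits_store)

    directions = {m.name: m.direction for m in motifs_a + motifs_b}
    harmonized = filter_and_harmonize(
        windows_a, windows_b, matches, directions,
        prevalence=cfg.prevalence_threshold, radius=cfg.cross_dataset_radius,
    )

    # ---- insertion decisions and refinement
    motif_by_name = {m.name: m for m in motifs_a + motifs_b}
    plans: list[InsertionPlan] = []
    plan_dataset: dict[int, str] = {}
    for site in harmonized:
        motif = motif_by_name[site.motif]
        proms = (groups_a if site.dataset == "datasetA" else groups_b)[motif.direction]
        profiles = [sliding_scores(motif, p) for p in proms]
        best_w = (windows_a if site.dataset == "datasetA" else windows_b)[site.motif]
        lo, hi = best_w.span
        hits = hits_store.get(site.motif, [])
        candidates = sorted({h.position for h in hits if lo <= h.position <= hi})
        if site.dataset == "datasetA" and site.position not in candidates:
            candidates.append(site.position)
        direction = "maximize" if motif.direction == "over" else "minimize"
        try:
            plan = decide_insertion(motif, target_promoter, profiles, candidates, direction)
        except ValueError as e:
            logger.info("motif %s skipped: %s", site.motif, e)
            continue
        if not plan.decision:
            continue
        try:
            refine_motif_sequence(target_promoter, plan, mask)
        except ValueError as e:
            logger.info("motif %s not refinable: %s", site.motif, e)
            continue
        if plan.edits:
            plans.append(plan)
            plan_dataset[id(plan)] = site.dataset

    plans_a = [p for p in plans if plan_dataset[id(p)] == "datasetA"]
    plans_b = [p for p in plans if plan_dataset[id(p)] == "datasetB"]
    variants = build_variant_library(target_promoter, plans_a, plans_b, mask)
    return PipelineResult(
        disc_a, disc_b, matches, windows_a, windows_b,
        harmonized, plans, variants, motif_by_name,
    )


def _dedupe(motifs: list[PSSM]) -> list[PSSM]:
    """Drop motifs whose consensus duplicates an earlier one."""
    seen: set[str] = set()
    out = []
    for m in motifs:
        if m.consensus in seen:
            continue
        seen.add(m.consensus)
        out.append(m)
    return out
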