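"""Significant motif positions, prevalence windows, and the insertion decision.

For each (motif, promoter) pair, every sliding-window position is assigned
an empirical p-value against the same position in shuffled copies of the
promoter. Significant positions are pooled across promoters into
candidate windows (center ± radius); each window's prevalence is its
share of all significant-position occurrences, and the most prevalent
window is the motif's preferred site. Positions are then harmonized
across the two datasets through the motif-similarity matches, and the
final insert/remove decision compares the motif's best score in the
target promoter against its best across-promoter average score:
a motif from over-expressed promoters is inserted only where the target
scores *below* its source promoters (room to strengthen), and a motif
from under-expressed promoters is removed only where the target scores
*above* them.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io import NucSequence
from .matching import MotifMatch
from .pssm import (
    PSSM,
    ScoreProfile,
    _sliding_scores_codes,
    encode,
    score_window,
    sliding_scores,
)

logger = logging.getLogger("pforge")


@dataclasses.dataclass
class PositionHit:
    motif: str
    promoter_id: str
    position: int  # start-codon-anchored coordinate of the window start
    score: float
    p: float


@dataclasses.dataclass
class PositionWindow:
    motif: str
    center: int
    radius: int
    X: int  # summed hit occurrences over the span
    percent: float

    @property
    def span(self) -> tuple[int, int]:
        return (self.center - self.radius, self.center + self.radius)


@dataclasses.dataclass
class InsertionPlan:
    motif: PSSM
    target_position: int
    direction: str  # "maximize" (over-motif: insert) or "minimize" (under: remove)
    score_target: float
    score_reference: float
    decision: bool
    edits: list | None = None
    refined_fragment: str | None = None


def significant_positions(
    motif: PSSM,
    promoter: NucSequence,
    n_perm: int = 100,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> list[PositionHit]:
    """Positions where the motif scores higher than in shuffled promoters.

    The null preserves mononucleotide composition (uniform shuffle) and is
    compared position-by-position: p at position i is the fraction of
    shuffled promoters whose score *at position i* is >= the observed
    score (ties inclusive).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    profile = sliding_scores(motif, promoter)
    lo = motif.log_odds()
    codes = encode(promoter.seq)
    L = len(motif)
    # batch of composition-preserving shuffles, scored at every position
    perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    windows = np.lib.stride_tricks.sliding_window_view(perms, L, axis=1)
    null = lo[np.arange(L)[None, None, :], windows].sum(axis=-1)
    p = (null >= profile.scores[None, :]).mean(axis=0)
    hits = [
        PositionHit(motif.name, promoter.id, int(pos), float(s), float(pv))
        for pos, s, pv in zip(profile.positions, profile.scores, p)
        if pv <= alpha
    ]
    return hits


def aggregate_windows(
    hits: list[PositionHit], radius: int = 4
) -> tuple[list[PositionWindow], PositionWindow | None]:
    """Pool hits across promoters into prevalence windows.

    x_i counts the promoters with a hit starting at coordinate i. One
    candidate window is placed at every distinct significant coordinate;
    its occurrence sum X_j adds x_i over center ± radius and its percent
    is X_j over the total hit count. Returns (all windows, maximal window)
    with ties broken toward the smallest |center| and then the smallest
    center.
    """
    if not hits:
        return [], None
    x: dict[int, int] = {}
    for h in hits:
        x[h.position] = x.get(h.position, 0) + 1
    total = sum(x.values())
    motif = hits[0].motif
    windows = []
    for center in sorted(x):
        X = sum(v for i, v in x.items() if abs(i - center) <= radius)
        windows.append(
            PositionWindow(motif, center, radius, X, 100.0 * X / total)
        )
    best = max(windows, key=lambda w: (w.percent, -abs(w.center), -w.center))
    return windows, best


@dataclasses.dataclass
class HarmonizedSite:
    motif: str
    dataset: str  # which dataset the motif came from
    position: int  # consensus coordinate to target in the promoter
    partner: str | None  # matched motif in the other dataset, if any
    direction: str


def filter_and_harmonize(
    windows_a: dict[str, PositionWindow],
    windows_b: dict[str, PositionWindow],
    matches: list[MotifMatch],
    directions: dict[str, str],
    prevalence: float = 6.5,
    radius: int = 20,
) -> list[HarmonizedSite]:
    """Keep B motifs above the prevalence cut and A motifs whose matched B
    window lies within ± radius nt; the A-motif site is the midpoint of the
    two centers, rounded toward the A center.

    ``windows_a``/``windows_b`` map motif name -> maximal PositionWindow;
    ``directions`` maps motif name -> over/under.
    """
    out: list[HarmonizedSite] = []
    kept_b = {
        name: w for name, w in windows_b.items() if w.percent > prevalence
    }
    for name, w in kept_b.items():
        out.append(
            HarmonizedSite(name, "datasetB", w.center, None, directions.get(name, "neutral"))
        )
    match_of = {m.motif_a: m.motif_b for m in matches}
    for name, wa in windows_a.items():
        partner = match_of.get(name)
        if partner is None or partner not in kept_b:
            continue
        wb = kept_b[partner]
        if abs(wa.center - wb.center) > radius:
            continue
        mid = (wa.center + wb.center) / 2.0
        consensus = int(np.ceil(mid)) if wa.center > mid else int(np.floor(mid))
        out.append(
            HarmonizedSite(name, "datasetA", consensus, partner, directions.get(name, "neutral"))
        )
    return out


def decide_insertion(
    motif: PSSM,
    target_promoter: NucSequence,
    promoter_profiles: list[ScoreProfile],
    candidate_positions: list[int],
    direction: str = "maximize",
) -> InsertionPlan:
    """Insert/remove decision at the motif's candidate positions.

    score_target is the motif's maximum score over the candidate positions
    in the target promoter; score_reference is the maximum, over those
    positions, of the motif's mean score across the source promoters that
    cover the position. An over-motif (direction "maximize") is inserted
    only if score_target < score_reference (strict); an under-motif
    ("minimize") is removed only if score_target > score_reference.
    """
    if not candidate_positions:
        raise ValueError(f"motif {motif.name!r}: no candidate positions")
    if direction not in ("maximize", "minimize"):
        raise ValueError(f"unknown direction {direction!r}")
    L = len(motif)
    target_scores = {}
    for pos in candidate_positions:
        try:
            frag = target_promoter.fragment(pos, L)
        except IndexError:
            continue
        target_scores[pos] = score_window(motif, frag)
    if not target_scores:
        raise ValueError(
            f"motif {motif.name!r}: no candidate position fits in the target promoter"
        )
    ref_means = {}
    for pos in candidate_positions:
        vals = []
        for prof in promoter_profiles:
            idx = np.nonzero(prof.positions == pos)[0]
            if idx.size:
                vals.append(prof.scores[idx[0]])
        if vals:
            ref_means[pos] = float(np.mean(vals))
    if not ref_means:
        raise ValueError(
            f"motif {motif.name!r}: candidate positions absent from all source promoters"
        )
    score_target = max(target_scores.values())
    score_reference = max(ref_means.values())
    if direction == "maximize":
        decision = score_target < score_reference
        # insert where the source promoters say the motif works best
        pos = max(ref_means, key=lambda k: (ref_means[k], -abs(k)))
    else:
        decision = score_target > score_reference
        # remove the strongest existing site in the target
        pos = max(target_scores, key=lambda k: (target_scores[k], -abs(k)))
    return InsertionPlan(
        motif=motif,
        target_position=pos,
        direction=direction,
        score_target=float(score_target),
        score_reference=float(score_reference),
        decision=bool(decision),
    )


def hits_table(hits: list[PositionHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif": [h.motif for h in hits],
            "promoter_id": [h.promoter_id for h in hits],
            "position": [h.position for h in hits],
            "score": [h.score for h in hits],
            "p": [h.p for h in hits],
        }
    )


def windows_table(windows: list[PositionWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif": [w.motif for w in windows],
            "center": [w.center for w in windows],
            "span_lo": [w.span[0] for w in windows],
            "span_hi": [w.span[1] for w in windows],
            "X": [w.X for w in windows],
            "percent": [w.percent for w in windows],
        }
    )
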