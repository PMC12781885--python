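"""Differential motif discovery between a target and a reference promoter set.

The scheme is seed-based: every k-mer (k = 6..10 by default) present in the
target set is screened for enrichment of exact per-sequence presence in the
target versus the reference with a one-sided hypergeometric test; the top
screened seeds are then re-tested counting near-exact presence (at most one
mismatch for k >= 7, where a single mismatch still leaves the background
rate low), Bonferroni-corrected over every k-mer tested. Significant seeds,
from most to least enriched, are each assembled into a PSSM from their best
(<=1 mismatch) occurrence per target sequence; seeds explained by an
already-accepted motif (same sequence up to a shift with at most one
mismatch in the overlap) are absorbed rather than reported again.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import NucSequence
from .pssm import ALPHABET, PSSM, build_pssm, encode


@dataclasses.dataclass
class DiscoveryResult:
    """Motifs discovered for one target/reference pairing."""

    motifs: list[PSSM]
    pvalues: dict[str, float]
    configuration: str
    direction: str


def _kmer_ids(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer ids of all k-mers of a coded sequence (base-4 reading)."""
    if codes.shape[0] < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows.astype(np.int64) @ powers


def _presence_counts(seqs: list[np.ndarray], k: int) -> dict[int, np.ndarray]:
    """Per-k-mer number of sequences containing it (presence, not occurrences)."""
    counts = np.zeros(4**k, dtype=np.int32)
    for codes in seqs:
        ids = _kmer_ids(codes, k)
        if ids.size:
            counts[np.unique(ids)] += 1
    return counts


def _id_to_kmer(kid: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(ALPHABET[kid % 4])
        kid //= 4
    return "".join(reversed(out))


def _redundant(a: str, b: str, max_mismatch: int = 1) -> bool:
    """True if the two seed strings align (any shift, overlap >= min length - 2)
    with at most ``max_mismatch`` mismatches in the overlap."""
    la, lb = len(a), len(b)
    min_overlap = max(4, min(la, lb) - 2)
    for shift in range(-(lb - 1), la):
        lo = max(0, shift)
        hi = min(la, shift + lb)
        if hi - lo < min_overlap:
            continue
        mism = sum(1 for i in range(lo, hi) if a[i] != b[i - shift])
        if mism <= max_mismatch:
            return True
    return False


def _seed_mismatch_allowance(k: int) -> int:
    """Mismatches tolerated when counting a seed's presence: 1 for k >= 7
    (background presence stays well below saturation in a few-hundred-nt
    promoter), 0 for shorter seeds."""
    return 1 if k >= 7 else 0


def _approx_presence(
    seed_codes: np.ndarray, windows: np.ndarray, bounds: np.ndarray, max_mismatch: int
) -> int:
    """Number of sequences containing the seed with <= max_mismatch
    mismatches. ``windows`` stacks every sequence's k-windows; ``bounds``
    gives the start offset of each sequence's block (len = n_seqs + 1)."""
    return int(
        _approx_presence_batch(seed_codes[None, :], windows, bounds, max_mismatch)[0]
    )


def _approx_presence_batch(
    seeds: np.ndarray, windows: np.ndarray, bounds: np.ndarray, max_mismatch: int
) -> np.ndarray:
    """Vectorized `_approx_presence` for a (S, k) block of seeds.

    Match counts are computed as a one-hot matrix product so the whole
    seed block costs one BLAS call per window stack.
    """
    S, k = seeds.shape
    W = windows.shape[0]
    win_oh = np.zeros((W, k, 4), dtype=np.float32)
    idx = np.arange(k)
    win_oh[np.arange(W)[:, None], idx[None, :], windows] = 1.0
    seed_oh = np.zeros((S, k, 4), dtype=np.float32)
    seed_oh[np.arange(S)[:, None], idx[None, :], seeds] = 1.0
    matches = win_oh.reshape(W, 4 * k) @ seed_oh.reshape(S, 4 * k).T
    best = np.maximum.reduceat(matches, bounds[:-1], axis=0)
    return (best >= k - max_mismatch).sum(axis=0).astype(int)


def _window_stack(seqs: list[np.ndarray], k: int) -> tuple[np.ndarray, np.ndarray]:
    blocks = []
    bounds = [0]
    for codes in seqs:
        if codes.shape[0] >= k:
            blocks.append(np.lib.stride_tricks.sliding_window_view(codes, k))
            bounds.append(bounds[-1] + blocks[-1].shape[0])
    return np.concatenate(blocks, axis=0), np.array(bounds)


def _trim_edges(m: PSSM, min_ic: float = 0.25, min_len: int = 4) -> PSSM:
    """Drop uninformative (< min_ic bits) columns from both motif edges."""
    p = np.clip(m.freq, 1e-12, 1.0)
    ic = 2.0 + (p * np.log2(p)).sum(axis=1)
    lo, hi = 0, len(ic)
    while hi - lo > min_len and ic[lo] < min_ic:
        lo += 1
    while hi - lo > min_len and ic[hi - 1] < min_ic:
        hi -= 1
    if (lo, hi) == (0, len(ic)):
        return m
    return PSSM(m.name, m.freq[lo:hi], m.source, m.direction)


def _best_occurrences(seed: str, seqs: list[np.ndarray], max_mismatch: int = 1) -> list[str]:
    """Best (fewest-mismatch) window per sequence, kept if <= max_mismatch."""
    k = len(seed)
    seed_codes = encode(seed)
    sites: list[str] = []
    for codes in seqs:
        if codes.shape[0] < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        mism = (windows != seed_codes).sum(axis=1)
        j = int(mism.argmin())
        if mism[j] <= max_mismatch:
            sites.append("".join(ALPHABET[c] for c in windows[j]))
    return sites


def discover_motifs(
    target: list[NucSequence],
    reference: list[NucSequence],
    k_range: tuple[int, int] = (6, 10),
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    max_motifs: int = 50,
    configuration: str = "custom",
    direction: str = "neutral",
    pseudocount: float = 0.1,
) -> DiscoveryResult:
    """Enriched-k-mer motif discovery (target vs reference presence).

    Returns at most ``max_motifs`` PSSMs ordered by enrichment p-value
    (Bonferroni-adjusted over every k-mer present in the target set).
    The result is invariant to the order of the input sequences.
    """
    if not target or not reference:
        raise ValueError("target and reference sets must be non-empty")
    k_lo, k_hi = k_range
    min_len = min(len(s) for s in list(target) + list(reference))
    if k_lo > min_len:
        raise ValueError(f"k_range {k_range} exceeds shortest sequence ({min_len})")
    k_hi = min(k_hi, min_len)

    t_codes = sorted((encode(s.seq) for s in target), key=lambda c: c.tobytes())
    r_codes = [encode(s.seq) for s in reference]
    n_t, n_r = len(t_codes), len(r_codes)
    # when the reference contains the target (e.g. over vs all), the
    # reference alone is the sampling population; otherwise the two sets
    # together form it
    target_in_reference = {s.id for s in target} <= {s.id for s in reference}
    N = n_r if target_in_reference else n_t + n_r

    # total k-mers tested (present in target) across all k: Bonferroni factor
    per_k = {}
    m_total = 0
    for k in range(k_lo, k_hi + 1):
        ct = _presence_counts(t_codes, k)
        per_k[k] = ct
        m_total += int((ct > 0).sum())

    candidates: list[tuple[float, str]] = []
    max_stage2 = 25  # screened seeds per k re-tested with mismatch-tolerant presence
    for k in range(k_lo, k_hi + 1):
        ct = per_k[k]
        # minimal target presence that could matter even with zero reference
        # carriers — exact prefilter against the screening threshold
        xs = np.arange(1, n_t + 1)
        best_p = hypergeom.sf(xs - 1, N, xs, n_t)
        viable = xs[best_p <= alpha]
        if viable.size == 0:
            continue
        x_min = int(viable[0])
        kmer_ids = np.nonzero(ct >= x_min)[0]
        if kmer_ids.size == 0:
            continue
        cr = _presence_counts(r_codes, k)
        x = ct[kmer_ids].astype(int)
        K = cr[kmer_ids].astype(int) if target_in_reference else x + cr[kmer_ids].astype(int)
        p_screen = hypergeom.sf(x - 1, N, K, n_t)
        keep = np.nonzero(p_screen <= alpha)[0]
        if keep.size == 0:
            continue
        keep = keep[np.argsort(p_screen[keep], kind="stable")][:max_stage2]

        mm = _seed_mismatch_allowance(k)
        if mm == 0:
            # exact presence is the final statistic for short seeds
            p_final = p_screen[keep] * m_total
            for pos, pv in zip(keep, p_final):
                if pv <= alpha:
                    candidates.append((float(pv), _id_to_kmer(int(kmer_ids[pos]), k)))
            continue
        tw, tb = _window_stack(t_codes, k)
        rw, rb = _window_stack(r_codes, k)
        seeds = [_id_to_kmer(int(kmer_ids[pos]), k) for pos in keep]
        seed_block = np.stack([encode(s) for s in seeds])
        xt = _approx_presence_batch(seed_block, tw, tb, mm)
        xr = _approx_presence_batch(seed_block, rw, rb, mm)
        K2 = xr if target_in_reference else xt + xr
        pv = hypergeom.sf(xt - 1, N, K2, n_t) * m_total
        for seed, p_adj in zip(seeds, pv):
            if p_adj <= alpha:
                candidates.append((float(p_adj), seed))

    # most enriched first; p-ties prefer the shorter (more parsimonious) seed
    candidates.sort(key=lambda t: (t[0], len(t[1]), t[1]))

    motifs: list[PSSM] = []
    pvalues: dict[str, float] = {}
    accepted_seeds: list[str] = []
    for pv, seed in candidates:
        if len(motifs) >= max_motifs:
            break
        if any(_redundant(seed, s) for s in accepted_seeds):
            continue
        sites = _best_occurrences(seed, t_codes)
        if not sites:
            continue
        name = f"{configuration}_{seed}"
        m = build_pssm(sites, pseudocount=pseudocount, name=name, direction=direction)
        m = _trim_edges(m)
        motifs.append(m)
        pvalues[name] = min(pv, 1.0)
        accepted_seeds.append(seed)

    return DiscoveryResult(motifs, pvalues, configuration, direction)


def run_four_configurations(
    over: list[NucSequence],
    under: list[NucSequence],
    all_seqs: list[NucSequence],
    k_range: tuple[int, int] = (6, 10),
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    max_motifs: int = 50,
    source: str = "datasetA",
) -> list[DiscoveryResult]:
    """The four target/reference pairings run on one dataset's groups.

    1. over vs all, 2. over vs under, 3. under vs all, 4. under vs over —
    direction tags (over, over, under, under) follow the target set.
    """
    over_ids = {s.id for s in over}
    under_ids = {s.id for s in under}
    if over_ids & under_ids:
        raise ValueError("over and under groups overlap")
    pairings = [
        ("over_vs_all", over, all_seqs, "over"),
        ("over_vs_under", over, under, "over"),
        ("under_vs_all", under, all_seqs, "under"),
        ("under_vs_over", under, over, "under"),
    ]
    results = []
    for tag, tgt, ref, direction in pairings:
        res = discover_motifs(
            tgt, ref, k_range=k_range, alpha=alpha, rng=rng,
            max_motifs=max_motifs, configuration=tag, direction=direction,
        )
        for m in res.motifs:
            m.source = source
        results.append(res)
    return results


def discovery_table(results: list[DiscoveryResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for m in res.motifs:
            rows.append(
                {
                    "motif": m.name,
                    "consensus": m.consensus,
                    "configuration": res.configuration,
                    "p": res.pvalues[m.name],
                    "direction": res.direction,
                }
            )
    return pd.DataFrame(rows, columns=["motif", "consensus", "configuration", "p", "direction"])
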