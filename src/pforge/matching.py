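"""PSSM-vs-PSSM similarity with uniform edge padding and permutation nulls.

Two motifs are compared column-by-column at every relative alignment
offset. For each aligned column pair the score contrasts the observed
squared difference between the two probability vectors with the squared
difference expected if base identities were unrelated:

    Obs_i  = sum_j -(f1_ij - f2_ij)^2
    Exp_i  = sum_j sum_k -(f1_ij - f2_ik)^2 / 4
    s_i    = (Exp_i - Obs_i) / Exp_i        (1 when Exp_i = 0)

so identical columns score 1 and the score never exceeds 1. Shorter
motifs are padded with uniform (0.25) columns across the union span of
each alignment configuration, the configuration score is the mean of s_i
over that span, and the similarity is the maximum over all
L1 + L2 - 1 configurations. Significance comes from an empirical p-value
against row-permuted versions of the second motif.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .pssm import PSSM, empirical_pvalue, permute_pssm_rows


@dataclasses.dataclass
class MotifMatch:
    motif_a: str
    motif_b: str
    similarity: float
    offset: int
    p: float = float("nan")


def column_score(col1: np.ndarray, col2: np.ndarray) -> float:
    """Similarity contribution of one aligned column pair."""
    a = np.asarray(col1, dtype=float)
    b = np.asarray(col2, dtype=float)
    for c in (a, b):
        if c.shape != (4,) or abs(c.sum() - 1.0) > 1e-6 or (c < 0).any():
            raise ValueError(f"column is not a probability vector: {c}")
    obs = -float(((a - b) ** 2).sum())
    exp = -float(((a[:, None] - b[None, :]) ** 2).sum()) / 4.0
    if exp == 0.0:
        return 1.0
    return (exp - obs) / exp


def _config_scores(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized per-column scores for two already-padded (S, 4) matrices."""
    obs = -((a - b) ** 2).sum(axis=1)
    # closed form of the double sum for stochastic columns
    exp = -(
        (a**2).sum(axis=1) + (b**2).sum(axis=1)
        - 0.5 * a.sum(axis=1) * b.sum(axis=1)
    )
    out = np.ones_like(obs)
    nz = exp != 0.0
    out[nz] = (exp[nz] - obs[nz]) / exp[nz]
    return out


def similarity_score(p1: PSSM, p2: PSSM, padding: float = 0.25) -> MotifMatch:
    """Maximum mean column score over all relative alignment offsets.

    The returned offset is the start of ``p2`` relative to the start of
    ``p1`` (negative: p2 begins upstream of p1).
    """
    f1, f2 = p1.freq, p2.freq
    L1, L2 = f1.shape[0], f2.shape[0]
    best = -np.inf
    best_off = 0
    for off in range(-(L2 - 1), L1):
        lo = min(0, off)
        hi = max(L1, off + L2)
        span = hi - lo
        a = np.full((span, 4), padding)
        b = np.full((span, 4), padding)
        a[-lo : -lo + L1] = f1
        b[off - lo : off - lo + L2] = f2
        score = float(_config_scores(a, b).mean())
        if score > best:
            best = score
            best_off = off
    return MotifMatch(p1.name, p2.name, best, best_off)


def match_sets(
    set_a: list[PSSM],
    set_b: list[PSSM],
    n_perm: int = 100,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    keep_all: bool = False,
) -> list[MotifMatch]:
    """Best match in set B for every motif in set A, with permutation p-values.

    The null permutes the nucleotide rows of the selected B motif ``n_perm``
    times and recomputes the similarity; p is the fraction of null
    similarities >= the real one. By default only matches with p <= alpha
    are returned.
    """
    if not set_a or not set_b:
        raise ValueError("both motif sets must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(0)
    matches: list[MotifMatch] = []
    for a in set_a:
        best: MotifMatch | None = None
        best_b: PSSM | None = None
        for b in set_b:
            m = similarity_score(a, b)
            if best is None or m.similarity > best.similarity:
                best, best_b = m, b
        assert best is not None and best_b is not None
        nulls = np.empty(n_perm)
        for t in range(n_perm):
            nulls[t] = similarity_score(a, permute_pssm_rows(best_b, rng)).similarity
        best.p = empirical_pvalue(best.similarity, nulls)
        if keep_all or best.p <= alpha:
            matches.append(best)
    return matches


def match_table(matches: list[MotifMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif_a": [m.motif_a for m in matches],
            "motif_b": [m.motif_b for m in matches],
            "similarity": [m.similarity for m in matches],
            "offset": [m.offset for m in matches],
            "p": [m.p for m in matches],
        }
    )
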