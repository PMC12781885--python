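"""Transcription-factor motif scanning with shuffle nulls and the
top-vs-bottom Wilcoxon comparison.

Each TF matrix is slid along the promoter; the statistic is the maximum
score and its position. Significance compares that maximum against the
maxima obtained on composition-preserving shuffles of the same promoter.
To ask whether a TF's site strength tracks reporter output, the variants
are ranked by a response value and the TF scores of the top and bottom
20% are compared with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import NucSequence
from .pssm import PSSM, _sliding_scores_codes, empirical_pvalue, encode, shuffle_sequence

logger = logging.getLogger("pforge")


@dataclasses.dataclass
class TFScanResult:
    tf: str
    max_score: float
    position: int  # anchored coordinate of the best window start
    p: float


def scan_tf(
    promoter: NucSequence,
    tf_pssms: list[PSSM],
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
) -> list[TFScanResult]:
    """Max sliding score, its position, and a shuffle-null empirical p-value
    for every TF matrix. Matrices longer than the promoter are skipped
    with a warning. Results are independent of catalog order."""
    rng = rng if rng is not None else np.random.default_rng(0)
    codes = encode(promoter.seq)
    shuffles = [encode(shuffle_sequence(promoter.seq, rng)) for _ in range(n_perm)]
    out: list[TFScanResult] = []
    for m in tf_pssms:
        if len(m) > len(promoter.seq):
            logger.warning("TF motif %s longer than promoter %s; skipped", m.name, promoter.id)
            continue
        lo = m.log_odds()
        scores = _sliding_scores_codes(lo, codes)
        j = int(scores.argmax())
        null = np.array([_sliding_scores_codes(lo, s).max() for s in shuffles])
        out.append(
            TFScanResult(
                tf=m.name,
                max_score=float(scores[j]),
                position=promoter.index_to_coord(j),
                p=empirical_pvalue(float(scores[j]), null),
            )
        )
    return out


def compare_extreme_groups(
    scores: dict[str, float],
    ranking: dict[str, float],
    fraction: float = 0.20,
) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum test between the TF scores of the top and
    bottom ``fraction`` of variants ranked by ``ranking``.

    Returns (p, flag); flag is "all-tied" (p forced to 1) when every score
    is identical. Invariant under any monotone transform of the ranking.
    """
    ids = [k for k in ranking if k in scores]
    n = len(ids)
    k = max(1, int(np.floor(fraction * n)))
    if k < 5:
        raise ValueError(f"need >= 5 variants per group, got {k}")
    order = sorted(ids, key=lambda i: (ranking[i], i))
    bottom = [scores[i] for i in order[:k]]
    top = [scores[i] for i in order[-k:]]
    if len(set(top) | set(bottom)) == 1:
        return 1.0, "all-tied"
    if k <= 12 and len(set(top + bottom)) == len(top + bottom):
        res = stats.mannwhitneyu(top, bottom, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(top, bottom, alternative="two-sided", method="asymptotic")
    return float(res.pvalue), ""


def scan_table(results: list[TFScanResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tf": [r.tf for r in results],
            "max_score": [r.max_score for r in results],
            "position": [r.position for r in results],
            "p": [r.p for r in results],
        }
    )
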