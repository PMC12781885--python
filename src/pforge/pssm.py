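"""Position-specific scoring matrices: construction, scoring and permutation nulls.

A motif is a matrix of per-position nucleotide probabilities. Scores are
log-odds (base 2) of a window against a uniform background, with a small
pseudo-probability so that zero-probability bases stay finite. Statistical
significance of any score-like statistic is assessed with empirical
permutation p-values: the fraction of null statistics at least as large as
the observed one (ties count against significance).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: pseudo-probability added to both numerator and background in log-odds scores
SCORE_EPS = 1e-3


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int8 array (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if (out < 0).any():
        bad = seq[int(np.argmax(out < 0))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return out


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


@dataclasses.dataclass
class PSSM:
    """A nucleotide motif as per-position base probabilities.

    Parameters
    ----------
    name : str
        Motif identifier.
    freq : ndarray, shape (L, 4)
        ``freq[i, j]`` is the probability of base ``ACGT[j]`` at motif
        position ``i``. Every row sums to 1 (within 1e-6 after
        renormalization on construction).
    source : str
        Provenance tag: ``datasetA``, ``datasetB`` or ``external``.
    direction : str
        ``over`` (from over-expressed promoters; to be strengthened),
        ``under`` (to be weakened) or ``neutral``.
    """

    name: str
    freq: np.ndarray
    source: str = "external"
    direction: str = "neutral"

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[1] != 4:
            raise ValueError(
                f"motif {self.name!r}: freq must be (L, 4), got {self.freq.shape}"
            )
        if self.freq.shape[0] < 1:
            raise ValueError(f"motif {self.name!r}: zero-length matrix")
        if (self.freq < 0).any():
            raise ValueError(f"motif {self.name!r}: negative probabilities")
        sums = self.freq.sum(axis=1)
        if (sums <= 0).any():
            raise ValueError(f"motif {self.name!r}: all-zero column")
        self.freq = self.freq / sums[:, None]

    def __len__(self) -> int:
        return self.freq.shape[0]

    @property
    def consensus(self) -> str:
        """Per-position most probable base (ties break alphabetically)."""
        return decode(self.freq.argmax(axis=1))

    def log_odds(self, eps: float = SCORE_EPS) -> np.ndarray:
        """(L, 4) matrix of log2((p + eps) / (0.25 + eps))."""
        return np.log2((self.freq + eps) / (0.25 + eps))

    def information_content(self) -> float:
        """Total information content in bits (2 - entropy summed over positions)."""
        p = np.clip(self.freq, 1e-12, 1.0)
        return float((2.0 + (p * np.log2(p)).sum(axis=1)).sum())


@dataclasses.dataclass
class ScoreProfile:
    """Sliding-window PSSM scores along a promoter.

    ``positions`` are start-codon-anchored coordinates of each window's
    first base; ``scores[k]`` is the motif's log-odds score at
    ``positions[k]``.
    """

    promoter_id: str
    positions: np.ndarray
    scores: np.ndarray
    window_len: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.positions.shape != self.scores.shape:
            raise ValueError("positions and scores length mismatch")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")


def score_window(pssm: PSSM, window: str | np.ndarray) -> float:
    """Log-odds score of a single window of length ``len(pssm)``."""
    codes = encode(window) if isinstance(window, str) else np.asarray(window)
    if codes.shape[0] != len(pssm):
        raise ValueError(
            f"window length {codes.shape[0]} != motif length {len(pssm)}"
        )
    lo = pssm.log_odds()
    return float(lo[np.arange(len(pssm)), codes].sum())


def sliding_scores(pssm: PSSM, promoter) -> ScoreProfile:
    """Score every forward-strand window of the promoter.

    ``promoter`` is a NucSequence (or anything with ``.seq``, ``.id`` and
    ``.anchor``). One score per valid start; positions are anchored
    coordinates of the window's first base.
    """
    codes = encode(promoter.seq)
    L = len(pssm)
    n = codes.shape[0] - L + 1
    if n < 1:
        raise ValueError(
            f"promoter {promoter.id!r} shorter ({codes.shape[0]}) than motif ({L})"
        )
    scores = _sliding_scores_codes(pssm.log_odds(), codes)
    starts = np.arange(n) - promoter.anchor
    return ScoreProfile(promoter.id, starts, scores, L)


def _sliding_scores_codes(log_odds: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Vectorized sliding scores for pre-encoded sequence codes."""
    L = log_odds.shape[0]
    n = codes.shape[0] - L + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return log_odds[np.arange(L)[None, :], windows].sum(axis=1)[:n]


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """Uniform permutation of the bases: preserves mononucleotide counts
    (hence GC content) exactly."""
    chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    rng.shuffle(chars)
    return chars.tobytes().decode("ascii")


def permute_pssm_rows(pssm: PSSM, rng: np.random.Generator) -> PSSM:
    """Randomly reorder the four nucleotide rows of the matrix.

    Position-wise probability mass is preserved (each position still sums
    to 1), but base identities are scrambled — the null used for motif
    similarity significance.
    """
    perm = rng.permutation(4)
    return PSSM(pssm.name + "_perm", pssm.freq[:, perm], pssm.source, pssm.direction)


def empirical_pvalue(real: float, randoms: Sequence[float] | np.ndarray) -> float:
    """Fraction of null statistics >= the observed one (ties inclusive)."""
    randoms = np.asarray(randoms, dtype=float)
    if randoms.size == 0:
        raise ValueError("empty null distribution")
    return float((randoms >= real).sum() / randoms.size)


def build_pssm(
    aligned_sites: Iterable[str],
    pseudocount: float = 0.0,
    name: str = "motif",
    source: str = "external",
    direction: str = "neutral",
) -> PSSM:
    """Build a PSSM from equal-length aligned occurrences.

    freq[i, j] = (count[i, j] + pseudocount) / (n + 4 * pseudocount).
    """
    sites = list(aligned_sites)
    if not sites:
        raise ValueError("need at least one site")
    lengths = {len(s) for s in sites}
    if len(lengths) != 1:
        raise ValueError(f"ragged site lengths: {sorted(lengths)}")
    L = lengths.pop()
    counts = np.zeros((L, 4), dtype=float)
    for s in sites:
        codes = encode(s)
        counts[np.arange(L), codes] += 1.0
    freq = (counts + pseudocount) / (len(sites) + 4.0 * pseudocount)
    return PSSM(name, freq, source, direction)
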