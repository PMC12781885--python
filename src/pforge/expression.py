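"""Expression datasets and over/under-expressed group selection.

Two kinds of input are supported: an endogenous promoter set with paired
expression values measured with and without the inducer ("dataset A"), and
a flow-seq variant library whose per-variant expression is estimated as
the bin-count-weighted mean fluorescence over 16 logarithmic sorting bins
("dataset B").
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io import NucSequence

logger = logging.getLogger("pforge")

N_BINS = 16


@dataclasses.dataclass
class ExpressionRecord:
    """One endogenous gene: its promoter and expression under both conditions."""

    gene_id: str
    promoter: NucSequence
    expr_dnt: float
    expr_ctrl: float

    @property
    def delta(self) -> float:
        return self.expr_dnt - self.expr_ctrl

    @property
    def log_ratio(self) -> float:
        return float(np.log2((self.expr_dnt + 1e-9) / (self.expr_ctrl + 1e-9)))


@dataclasses.dataclass
class FlowSeqRecord:
    """One library variant: promoter plus read counts in the 16 sorting bins."""

    variant_id: str
    promoter: NucSequence
    counts: np.ndarray
    condition: str = "DNT"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_BINS,):
            raise ValueError(
                f"variant {self.variant_id!r}: expected {N_BINS} bins, "
                f"got {self.counts.shape}"
            )
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)) or (self.counts < 0).any():
                raise ValueError(
                    f"variant {self.variant_id!r}: counts must be non-negative integers"
                )
            self.counts = self.counts.astype(np.int64)


@dataclasses.dataclass
class BinModel:
    """Mean fluorescence of each sorting bin (strictly increasing)."""

    bin_means: np.ndarray

    def __post_init__(self) -> None:
        self.bin_means = np.asarray(self.bin_means, dtype=float)
        if self.bin_means.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bin means")
        if not (np.diff(self.bin_means) > 0).all():
            raise ValueError("bin means must be strictly increasing")


def weighted_fluorescence(record: FlowSeqRecord, bins: BinModel) -> float:
    """Bin-weighted mean fluorescence of one variant.

    F = sum_i b_i * n_i / sum_i n_i, with b_i the mean fluorescence of bin i
    and n_i the variant's read count in bin i. Returns NaN (and logs a
    warning) for a variant with no reads, which callers exclude.
    """
    total = record.counts.sum()
    if total == 0:
        logger.warning(
            "variant %s has zero total counts; excluded", record.variant_id
        )
        return float("nan")
    return float((bins.bin_means * record.counts).sum() / total)


def select_groups(
    values: dict[str, float], fraction: float = 0.10
) -> tuple[list[str], list[str]]:
    """Split ids into the top and bottom ``fraction`` by score.

    Group size is ceil(fraction * n); ties at a boundary break by
    lexicographic id so the split is reproducible. Returns
    (over, under) — always disjoint.
    """
    ids = [k for k, v in values.items() if np.isfinite(v)]
    n = len(ids)
    k = int(np.ceil(fraction * n))
    if n < 2 * k or k == 0:
        raise ValueError(
            f"{n} records cannot form two disjoint groups of {k}"
        )
    order = sorted(ids, key=lambda i: (-values[i], i))
    over = order[:k]
    under_order = sorted(ids, key=lambda i: (values[i], i))
    under = [i for i in under_order if i not in set(over)][:k]
    return over, under


def dataset_a_scores(records: list[ExpressionRecord], how: str = "delta") -> dict[str, float]:
    """Ranking score per gene: expression disparity with vs without inducer."""
    if how == "delta":
        return {r.gene_id: r.delta for r in records}
    if how == "log_ratio":
        return {r.gene_id: r.log_ratio for r in records}
    raise ValueError(f"unknown ranking {how!r}")


def dataset_b_scores(
    records: list[FlowSeqRecord],
    bins: BinModel,
    condition: str = "DNT",
) -> dict[str, float]:
    """Weighted mean fluorescence per variant under one condition."""
    out: dict[str, float] = {}
    for r in records:
        if r.condition != condition:
            continue
        f = weighted_fluorescence(r, bins)
        if np.isfinite(f):
            out[r.variant_id] = f
    return out


def dataset_b_contrast(
    records: list[FlowSeqRecord], bins: BinModel
) -> dict[str, float]:
    """Alternative ranking: induced / uninduced fluorescence ratio."""
    dnt = dataset_b_scores(records, bins, "DNT")
    ctrl = dataset_b_scores(records, bins, "control")
    return {
        k: dnt[k] / ctrl[k] for k in dnt if k in ctrl and ctrl[k] > 0
    }


def expression_table(records: list[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "expr_dnt": [r.expr_dnt for r in records],
            "expr_ctrl": [r.expr_ctrl for r in records],
        }
    )


def bincount_table(records: list[FlowSeqRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"variant_id": r.variant_id, "condition": r.condition}
        row.update({f"n_{i+1}": int(c) for i, c in enumerate(r.counts)})
        rows.append(row)
    return pd.DataFrame(rows)
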