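"""Sequence features of promoter variants.

Feature families: sliding-window and whole-sequence minimum free energy of
folding (nearest-neighbor thermodynamics via ViennaRNA, applied to the
promoter sequence); per-position mutation indicators against the control;
the ChimeraARS average-repetitive-substring index against a reference
promoter set; maximum PSSM scores for inserted, discovered and external
motif catalogs; position-wise promoter strength from a 4 x 41 energy
matrix (k_BT) spanning coordinates -41..-1 relative to the transcription
start site; nucleotide composition; and per-window hybridization energy
against the anti-Shine-Dalgarno core as a ribosome-binding proxy.

Two redundancy-reduction rules follow the extraction: folding windows
whose profiles are Spearman-correlated above a cutoff collapse to one
representative, and mutation indicators at adjacent positions are
averaged into a single profile feature.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

import RNA

from .io import NucSequence
from .pssm import PSSM, sliding_scores

logger = logging.getLogger("pforge")

CATEGORIES = (
    "folding", "mutation", "chimera", "motif_pssm", "strength", "composition", "rbs",
)

#: anti-Shine-Dalgarno core used for RBS hybridization energies
DEFAULT_ASD = "ACCUCCUUA"


@dataclasses.dataclass
class FeatureTable:
    """Variant x feature matrix with a category tag per feature."""

    values: pd.DataFrame
    categories: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"missing values in features {bad[:5]}")
        unknown = set(self.categories.values()) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown feature categories {unknown}")
        missing = set(self.values.columns) - set(self.categories)
        if missing:
            raise ValueError(f"features without category: {sorted(missing)[:5]}")

    def of_category(self, category: str) -> list[str]:
        return [f for f in self.values.columns if self.categories[f] == category]


@dataclasses.dataclass
class EnergyMatrix:
    """Promoter-strength energy matrix: 4 rows (A,C,G,T) x 41 positions,
    covering coordinates -41..-1 relative to the transcription start site,
    in units of k_BT."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4, 41):
            raise ValueError(f"energy matrix must be 4 x 41, got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("energy matrix has non-finite entries")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EnergyMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.loc[list("ACGT")].to_numpy())

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.values, index=list("ACGT"),
            columns=[str(c) for c in range(-41, 0)],
        )
        df.to_csv(path, sep="\t")


_BASE_ROW = {b: i for i, b in enumerate("ACGT")}


def _mfe(seq: str) -> float:
    return float(RNA.fold(seq)[1])


def folding_profile(
    seq: NucSequence, window: int = 40, step: int = 1
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Sliding-window MFE profile plus its average and the whole-sequence MFE.

    Returns (window start coordinates, per-window MFE, average, total).
    Windows are indexed by their first base. A sequence shorter than the
    window yields no windows but still a whole-sequence value.
    """
    total = _mfe(seq.seq)
    n = len(seq.seq) - window + 1
    if n < 1:
        logger.warning("sequence %s shorter than fold window; windows skipped", seq.id)
        return np.empty(0, dtype=int), np.empty(0), float("nan"), total
    starts = np.arange(0, n, step)
    vals = np.array([_mfe(seq.seq[s : s + window]) for s in starts])
    coords = starts - seq.anchor
    return coords, vals, float(vals.mean()), total


def mutation_features(
    variant: NucSequence, control: NucSequence
) -> tuple[np.ndarray, int]:
    """Per-position mutation indicator vs the control, and the total count."""
    if len(variant.seq) != len(control.seq):
        raise ValueError(
            f"variant {variant.id!r} length {len(variant.seq)} != control {len(control.seq)}"
        )
    vec = np.array(
        [1 if a != b else 0 for a, b in zip(variant.seq, control.seq)], dtype=int
    )
    return vec, int(vec.sum())


def chimera_ars(seq: NucSequence | str, reference: list[NucSequence | str]) -> float:
    """ChimeraARS index: mean, over start positions, of the longest substring
    starting there that occurs anywhere in the reference set (0 if none)."""
    if not reference:
        raise ValueError("reference set must be non-empty")
    s = seq.seq if hasattr(seq, "seq") else seq
    hay = "#".join(r.seq if hasattr(r, "seq") else r for r in reference)
    n = len(s)
    lengths = np.zeros(n, dtype=int)
    l = 0
    for p in range(n):
        l = max(0, l - 1)  # longest match can shrink by at most 1 per shift
        while p + l < n and s[p : p + l + 1] in hay:
            l += 1
        lengths[p] = l
    return float(lengths.mean())


def motif_score_features(
    seq: NucSequence, motifs: list[PSSM]
) -> dict[str, float]:
    """Maximum sliding PSSM score per motif (motifs longer than the sequence
    are omitted with a warning)."""
    out: dict[str, float] = {}
    for m in motifs:
        if len(m) > len(seq.seq):
            logger.warning("motif %s longer than %s; feature omitted", m.name, seq.id)
            continue
        out[m.name] = float(sliding_scores(m, seq).scores.max())
    return out


def promoter_strength(
    seq: NucSequence, matrix: EnergyMatrix, tss: int = 0
) -> tuple[np.ndarray, float, float]:
    """Per-position strength contributions over tss-41..tss-1, their sum, and
    their mean. ``tss`` is the start-codon-anchored coordinate of the
    transcription start site."""
    coords = np.arange(tss - 41, tss)
    try:
        bases = [seq.seq[seq.coord_to_index(c)] for c in coords]
    except IndexError as e:
        raise ValueError(f"strength window out of range for {seq.id!r}: {e}") from e
    contrib = np.array(
        [matrix.values[_BASE_ROW[b], k] for k, b in enumerate(bases)]
    )
    return contrib, float(contrib.sum()), float(contrib.mean())


def composition_and_rbs(
    seq: NucSequence, asd: str = DEFAULT_ASD, rbs_window: int = 6
) -> tuple[dict[str, float], dict[int, float]]:
    """Nucleotide-composition features and per-window RBS hybridization energies.

    Composition: mono- and dinucleotide counts and frequencies plus GC
    content. RBS: for every 6-nt window, the duplex free energy of the
    window (as RNA) against the anti-Shine-Dalgarno core; more negative =
    stronger predicted ribosome binding.
    """
    s = seq.seq
    if len(s) < rbs_window:
        raise ValueError("sequence shorter than the RBS window")
    comp: dict[str, float] = {}
    n = len(s)
    for b in "ACGT":
        c = s.count(b)
        comp[f"count_{b}"] = c
        comp[f"freq_{b}"] = c / n
    for b1 in "ACGT":
        for b2 in "ACGT":
            c = sum(1 for i in range(n - 1) if s[i] == b1 and s[i + 1] == b2)
            comp[f"count_{b1}{b2}"] = c
            comp[f"freq_{b1}{b2}"] = c / (n - 1)
    comp["gc_content"] = (s.count("G") + s.count("C")) / n
    rbs: dict[int, float] = {}
    rna = s.replace("T", "U")
    for i in range(n - rbs_window + 1):
        window = rna[i : i + rbs_window]
        duplex = RNA.duplexfold(window, asd)
        rbs[seq.index_to_coord(i)] = float(duplex.energy)
    return comp, rbs


def extract_features(
    variants: list[NucSequence],
    control: NucSequence,
    motifs: list[PSSM] | None = None,
    energy_matrix: EnergyMatrix | None = None,
    tss: int = 0,
    chimera_reference: list[NucSequence] | None = None,
    fold_window: int = 40,
    fold_step: int = 1,
    include: tuple[str, ...] = CATEGORIES,
) -> FeatureTable:
    """Extract all requested feature families for a set of variants.

    Pure function of its inputs: identical inputs yield a bit-identical
    table. ``include`` restricts the families computed.
    """
    rows: dict[str, dict[str, float]] = {v.id: {} for v in variants}
    categories: dict[str, str] = {}

    for v in variants:
        feats = rows[v.id]
        if "folding" in include:
            coords, vals, avg, total = folding_profile(v, fold_window, fold_step)
            for c, val in zip(coords, vals):
                name = f"fold_win_{c}"
                feats[name] = val
                categories[name] = "folding"
            feats["fold_avg"] = avg
            feats["fold_total"] = total
            categories["fold_avg"] = categories["fold_total"] = "folding"
        if "mutation" in include:
            vec, count = mutation_features(v, control)
            for i, val in enumerate(vec):
                coord = control.index_to_coord(i)
                name = f"mut_{coord}"
                feats[name] = float(val)
                categories[name] = "mutation"
            feats["mut_count"] = float(count)
            categories["mut_count"] = "mutation"
        if "chimera" in include and chimera_reference:
            feats["chimera_ars"] = chimera_ars(v, chimera_reference)
            categories["chimera_ars"] = "chimera"
        if "motif_pssm" in include and motifs:
            for name, val in motif_score_features(v, motifs).items():
                fname = f"pssm_{name}"
                feats[fname] = val
                categories[fname] = "motif_pssm"
        if "strength" in include and energy_matrix is not None:
            contrib, total_s, avg_s = promoter_strength(v, energy_matrix, tss)
            for k, val in enumerate(contrib):
                name = f"strength_{tss - 41 + k}"
                feats[name] = val
                categories[name] = "strength"
            feats["strength_total"] = total_s
            feats["strength_avg"] = avg_s
            categories["strength_total"] = categories["strength_avg"] = "strength"
        if "composition" in include or "rbs" in include:
            comp, rbs = composition_and_rbs(v)
            if "composition" in include:
                for name, val in comp.items():
                    feats[name] = val
                    categories[name] = "composition"
            if "rbs" in include:
                for coord, val in rbs.items():
                    name = f"rbs_{coord}"
                    feats[name] = val
                    categories[name] = "rbs"

    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df[[c for c in df.columns]]  # keep insertion order
    return FeatureTable(df, categories)


def reduce_features(
    table: FeatureTable, spearman_cutoff: float = 0.99, mutation_radius: int = 1
) -> FeatureTable:
    """Collapse redundant features.

    Folding windows are greedily grouped by |Spearman rho| > cutoff along
    increasing window position and only the first of each group kept;
    mutation indicators at coordinates within ``mutation_radius`` of each
    other are averaged into one profile feature. Constant features (rho
    undefined) are kept and flagged in the log.
    """
    if table.values.shape[0] < 2:
        raise ValueError("need at least two variants to reduce features")
    df = table.values
    cats = dict(table.categories)

    fold = [f for f in df.columns if cats[f] == "folding" and f.startswith("fold_win_")]
    drop: set[str] = set()
    kept_folds: list[str] = []
    for f in fold:  # column order follows window position
        col = df[f].to_numpy()
        if np.all(col == col[0]):
            logger.warning("constant folding feature %s kept, correlation undefined", f)
            kept_folds.append(f)
            continue
        redundant = False
        for g in kept_folds:
            other = df[g].to_numpy()
            if np.all(other == other[0]):
                continue
            rho = spearmanr(col, other).statistic
            if np.isfinite(rho) and abs(rho) > spearman_cutoff:
                redundant = True
                break
        if redundant:
            drop.add(f)
        else:
            kept_folds.append(f)

    muts = sorted(
        (int(f.split("_")[1]), f)
        for f in df.columns
        if cats[f] == "mutation" and f.startswith("mut_") and f != "mut_count"
    )
    new_cols: dict[str, np.ndarray] = {}
    group: list[tuple[int, str]] = []

    def flush():
        if not group:
            return
        names = [f for _, f in group]
        if len(names) == 1:
            return
        merged = df[names].mean(axis=1).to_numpy()
        lo, hi = group[0][0], group[-1][0]
        new_cols[f"mut_{lo}_{hi}"] = merged
        drop.update(names)

    for coord, f in muts:
        if group and coord - group[-1][0] > mutation_radius:
            flush()
            group = []
        group.append((coord, f))
    flush()

    out = df.drop(columns=sorted(drop))
    for name, col in new_cols.items():
        out[name] = col
        cats[name] = "mutation"
    cats = {k: v for k, v in cats.items() if k in out.columns}
    return FeatureTable(out, cats)


def toy_energy_matrix() -> EnergyMatrix:
    """Synthetic promoter-strength matrix for tests and examples.

    Not fitted to any measured promoter data: a smooth, documented stand-in
    with two strongly informative columns (-35 and -10 region anchors) over
    a small random-free background.
    """
    vals = np.zeros((4, 41))
    # mild periodic background, deterministic
    pos = np.arange(41)
    for b in range(4):
        vals[b] = 0.05 * np.sin(2 * np.pi * (pos + 3 * b) / 10.5)
    # informative columns: coordinate -35 -> index 6, coordinate -10 -> index 31
    vals[:, 6] = [-1.2, 0.4, 0.5, 0.3]   # A favored at -35
    vals[:, 31] = [0.3, 0.5, 0.4, -1.5]  # T favored at -10
    return EnergyMatrix(vals)
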