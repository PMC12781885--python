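"""Seeded synthetic-data generators with planted ground truth.

Every pipeline input can be generated here: an endogenous promoter set
with differential expression and a planted responsive motif ("dataset A"),
a mutagenized single-promoter flow-seq library sorted into 16 logarithmic
fluorescence bins ("dataset B"), a control promoter flanked by the KpnI /
SwaI cloning sites, motif catalogs, and luminescence time courses whose
amplitudes are a linear function of designated sequence features. Each
generator is a pure function of its parameters and seed, and the planted
truth is returned alongside the data so recovery can be scored.

The defaults mirror the study conditions the pipeline targets: 400-nt
promoters, a 10% over/under group fraction, 147 mutable sites in the
variant library, 16 sorting bins, hourly readings over 10 h with two
replicates, and a sigmoidal induction curve with a ~2.5 h onset.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import BinModel, ExpressionRecord, FlowSeqRecord, N_BINS
from .features import FeatureTable
from .io import NucSequence
from .pssm import ALPHABET, PSSM, encode
from .response import LuminescenceSeries

BASES = np.array(list(ALPHABET))


@dataclasses.dataclass
class PlantedMotif:
    consensus: str
    position: int          # anchored coordinate of the first base
    effect: float          # expression effect of carrying the motif
    prevalence: float      # fraction of the responsive group carrying it
    sub_rate: float        # per-base substitution noise when planting
    direction: str = "over"

    def pssm(self, name: str = "planted") -> PSSM:
        """The true per-position base distribution implied by the planting
        noise model (consensus base with prob 1 - sub_rate, others equal)."""
        L = len(self.consensus)
        freq = np.full((L, 4), self.sub_rate / 3.0)
        codes = encode(self.consensus)
        freq[np.arange(L), codes] = 1.0 - self.sub_rate
        return PSSM(name, freq, direction=self.direction)


@dataclasses.dataclass
class GroundTruth:
    motifs: list[PlantedMotif]
    feature_weights: dict[str, float]
    noise: dict[str, float]
    seed: int
    #: per-entity latent quantities (e.g. true log10 fluorescence per variant)
    values: dict[str, dict[str, float]] = dataclasses.field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, payload: str | Path) -> "GroundTruth":
        text = Path(payload).read_text() if isinstance(payload, Path) else payload
        d = json.loads(text)
        d["motifs"] = [PlantedMotif(**m) for m in d["motifs"]]
        return cls(**d)


def _random_promoter(length: int, rng: np.random.Generator, composition: np.ndarray) -> str:
    return "".join(rng.choice(BASES, size=length, p=composition))


def _plant(seq: str, motif: PlantedMotif, anchor: int, rng: np.random.Generator) -> str:
    idx = anchor + motif.position
    if not (0 <= idx <= len(seq) - len(motif.consensus)):
        raise ValueError(
            f"planted position {motif.position} outside promoter of length {len(seq)}"
        )
    site = list(motif.consensus)
    for i in range(len(site)):
        if rng.random() < motif.sub_rate:
            site[i] = rng.choice([b for b in ALPHABET if b != site[i]])
    return seq[:idx] + "".join(site) + seq[idx + len(site):]


def composition_vector(kind: str = "uniform") -> np.ndarray:
    """Background base composition: uniform, or an AT-rich E. coli-like mix
    (A = T = 0.30, C = G = 0.20)."""
    if kind == "uniform":
        return np.full(4, 0.25)
    if kind == "at_rich":
        return np.array([0.30, 0.20, 0.20, 0.30])
    raise ValueError(f"unknown composition {kind!r}")


def gen_dataset_a(
    n_genes: int = 500,
    promoter_len: int = 400,
    consensus: str = "TGACCGGA",
    position: int = -120,
    effect: float = 3.0,
    prevalence: float = 0.8,
    reference_prevalence: float = 0.05,
    sub_rate: float = 0.1,
    group_fraction: float = 0.10,
    baseline: float = 10.0,
    noise_sd: float = 1.0,
    composition: str = "uniform",
    consensus_under: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ExpressionRecord], GroundTruth]:
    """Endogenous-style promoter set with a planted inducer-responsive motif.

    A ``group_fraction`` share of genes are responders (expression shift
    ``effect`` in noise-sd units under the inducer); ``prevalence`` of them
    carry the motif (with substitution noise) at the planted coordinate,
    and ``reference_prevalence`` of the remaining genes carry it without
    any expression effect. If ``consensus_under`` is given, a disjoint
    group of the same size responds negatively and carries that motif.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    comp = composition_vector(composition)
    n_resp = int(np.ceil(group_fraction * n_genes))
    motif = PlantedMotif(consensus, position, effect, prevalence, sub_rate, "over")
    motifs = [motif]
    under_motif = None
    if consensus_under is not None:
        under_motif = PlantedMotif(
            consensus_under, position, -effect, prevalence, sub_rate, "under"
        )
        motifs.append(under_motif)

    records = []
    for g in range(n_genes):
        seq = _random_promoter(promoter_len, rng, comp)
        anchor = promoter_len
        is_over = g < n_resp
        is_under = under_motif is not None and n_resp <= g < 2 * n_resp
        mean = 0.0
        if is_over:
            mean = effect
            if rng.random() < prevalence:
                seq = _plant(seq, motif, anchor, rng)
        elif is_under:
            mean = -effect
            if rng.random() < prevalence:
                seq = _plant(seq, under_motif, anchor, rng)
        else:
            if rng.random() < reference_prevalence:
                seq = _plant(seq, dataclasses.replace(motif, effect=0.0), anchor, rng)
        # paired design: baseline variation is shared between conditions, so
        # noise_sd is the sd of the disparity and `effect` is in those units
        expr_ctrl = baseline + rng.normal(0.0, noise_sd)
        expr_dnt = expr_ctrl + mean + rng.normal(0.0, noise_sd)
        records.append(
            ExpressionRecord(
                gene_id=f"gene{g:04d}",
                promoter=NucSequence(f"gene{g:04d}", seq, anchor),
                expr_dnt=expr_dnt,
                expr_ctrl=expr_ctrl,
            )
        )
    truth = GroundTruth(
        motifs=motifs,
        feature_weights={},
        noise={"noise_sd": noise_sd, "baseline": baseline},
        seed=int(rng.bit_generator.seed_seq.entropy or 0) if hasattr(rng.bit_generator, "seed_seq") else 0,
    )
    return records, truth


def default_bin_model(lo: float = 1e2, hi: float = 10**5.5) -> BinModel:
    """16 logarithmically spaced bin mean fluorescences (instrument grid)."""
    return BinModel(np.geomspace(lo, hi, N_BINS))


def gen_dataset_b(
    base_promoter: NucSequence | None = None,
    n_variants: int = 2000,
    n_sites: int = 147,
    max_order: int = 3,
    depth: int = 200,
    consensus: str = "TGACCGGA",
    position: int = -120,
    carrier_fraction: float = 0.10,
    dnt_multiplier: float = 4.0,
    sub_rate: float = 0.05,
    site_effect_sd: float = 0.15,
    noise_sd: float = 0.10,
    base_log10_f: float = 3.5,
    sort_sd: float = 0.15,
    promoter_len: int = 400,
    rng: np.random.Generator | None = None,
) -> tuple[list[FlowSeqRecord], BinModel, GroundTruth]:
    """Mutagenized flow-seq library around one base promoter.

    Non-carrier variants mutate 1..max_order of ``n_sites`` designated
    positions; ``carrier_fraction`` of variants instead receive the planted
    consensus at the planted coordinate. log10 fluorescence is additive in
    per-site effects plus noise; carriers gain log10(dnt_multiplier) under
    the inducer only. Reads are multinomial over 16 log bins with a
    Gaussian sorting kernel (sd ``sort_sd`` in log10 units) around each
    variant's fluorescence, ``depth`` reads per variant per condition.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if depth <= 0:
        raise ValueError("depth must be positive")
    if base_promoter is None:
        base_promoter = NucSequence(
            "base", _random_promoter(promoter_len, rng, composition_vector()), promoter_len
        )
    L = len(base_promoter.seq)
    anchor = base_promoter.anchor
    sites = np.sort(rng.choice(L, size=min(n_sites, L), replace=False))
    site_effects = rng.normal(0.0, site_effect_sd, size=sites.size)
    motif = PlantedMotif(
        consensus, position, float(np.log10(dnt_multiplier)), carrier_fraction, sub_rate, "over"
    )
    bins = default_bin_model()
    log_bins = np.log10(bins.bin_means)

    records: list[FlowSeqRecord] = []
    true_logf: dict[str, dict[str, float]] = {"log10_f_dnt": {}, "log10_f_ctrl": {}}
    n_carriers = int(np.round(carrier_fraction * n_variants))
    for v in range(n_variants):
        carrier = v < n_carriers
        seq = base_promoter.seq
        effect_sum = 0.0
        if carrier:
            seq = _plant(seq, motif, anchor, rng)
        else:
            order = int(rng.integers(1, max_order + 1))
            chosen = rng.choice(sites.size, size=order, replace=False)
            chars = list(seq)
            for si in chosen:
                pos = int(sites[si])
                chars[pos] = rng.choice([b for b in ALPHABET if b != chars[pos]])
                effect_sum += site_effects[si]
            seq = "".join(chars)
        log_f_ctrl = base_log10_f + effect_sum + rng.normal(0.0, noise_sd)
        log_f_dnt = log_f_ctrl + (np.log10(dnt_multiplier) if carrier else 0.0)
        promoter = NucSequence(f"var{v:05d}", seq, anchor)
        true_logf["log10_f_dnt"][promoter.id] = float(log_f_dnt)
        true_logf["log10_f_ctrl"][promoter.id] = float(log_f_ctrl)
        for cond, log_f in (("DNT", log_f_dnt), ("control", log_f_ctrl)):
            w = np.exp(-0.5 * ((log_bins - log_f) / sort_sd) ** 2)
            w = w / w.sum()
            counts = rng.multinomial(depth, w)
            records.append(FlowSeqRecord(promoter.id, promoter, counts, cond))
    truth = GroundTruth(
        motifs=[motif],
        feature_weights={},
        noise={"noise_sd": noise_sd, "site_effect_sd": site_effect_sd, "sort_sd": sort_sd},
        seed=0,
        values=true_logf,
    )
    return records, bins, truth


def gen_control_promoter(
    length: int = 400, rng: np.random.Generator | None = None
) -> NucSequence:
    """Control promoter with the KpnI site at its 5' edge and the SwaI site
    immediately before the start codon, as in the cloning backbone."""
    rng = rng if rng is not None else np.random.default_rng(0)
    core = _random_promoter(length - 14, rng, composition_vector())
    seq = "GGTACC" + core + "ATTTAAAT"
    return NucSequence("control", seq, length)


def gen_motif_catalog(
    n: int, length_range: tuple[int, int] = (6, 12),
    concentration: float = 0.5,
    rng: np.random.Generator | None = None,
    prefix: str = "tf",
) -> list[PSSM]:
    """Random Dirichlet-column PSSM catalog (stand-in for an external TF
    motif collection; synthetic, carries no biological annotation)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    out = []
    for i in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        freq = rng.dirichlet(np.full(4, concentration), size=L)
        out.append(PSSM(f"{prefix}{i:03d}", freq))
    return out


def logistic_curve(t: np.ndarray, onset: float = 2.5, rate: float = 1.5) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-rate * (t - onset)))


def gen_luminescence(
    table: FeatureTable,
    weights: dict[str, float],
    control_id: str,
    timegrid: np.ndarray | None = None,
    base_amplitude: float = 1000.0,
    amplitude_sd: float = 100.0,
    meas_noise_sd: float = 20.0,
    onset: float = 2.5,
    rate: float = 1.5,
    n_replicates: int = 2,
    rng: np.random.Generator | None = None,
) -> tuple[list[LuminescenceSeries], GroundTruth]:
    """Luminescence time courses whose induction amplitude is linear in the
    designated (standardized) features.

    Delta(t) = amplitude * logistic(t; onset, rate) + noise; the control
    row's amplitude comes from the same linear model, so differences from
    the control reflect the planted feature effects. The uninduced channel
    is a slowly rising background common to all variants.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    t = np.asarray(timegrid if timegrid is not None else np.arange(0.0, 10.5, 1.0))
    df = table.values
    missing = [f for f in weights if f not in df.columns]
    if missing:
        raise ValueError(f"weight features absent from table: {missing}")
    z = (df - df.mean()) / df.std().replace(0.0, 1.0)
    amp = pd.Series(base_amplitude, index=df.index, dtype=float)
    for f, w in weights.items():
        amp = amp + w * z[f]
    if control_id not in df.index:
        raise ValueError(f"control {control_id!r} not in the feature table")
    shape = logistic_curve(t, onset, rate)
    series = []
    for vid in df.index:
        for rep in range(n_replicates):
            a = amp[vid] + rng.normal(0.0, amplitude_sd)
            ctrl = 100.0 * (1.0 + 0.05 * t) + rng.normal(0.0, meas_noise_sd, size=t.size)
            delta = a * shape + rng.normal(0.0, meas_noise_sd, size=t.size)
            series.append(
                LuminescenceSeries(vid, t, ctrl + delta, ctrl, replicate=rep)
            )
    truth = GroundTruth(
        motifs=[],
        feature_weights=dict(weights),
        noise={
            "amplitude_sd": amplitude_sd,
            "meas_noise_sd": meas_noise_sd,
            "onset": onset,
            "rate": rate,
            "base_amplitude": base_amplitude,
        },
        seed=0,
    )
    return series, truth
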