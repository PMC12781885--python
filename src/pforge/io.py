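"""Readers and writers for the pipeline's external formats.

Sequences travel as FASTA, motifs as MEME minimal format, tables as TSV
with a mandatory header. Coordinates shown to users are start-codon
anchored signed integers (-1 = the base immediately upstream of the ATG);
internally sequences are 0-based.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pssm import ALPHABET, PSSM

logger = logging.getLogger("pforge")

_VALID = re.compile(r"^[ACGT]+$")


@dataclasses.dataclass
class NucSequence:
    """A named DNA sequence with a start-codon anchor.

    ``anchor`` is the 0-based index of the first base of the start codon
    within ``seq``; bases upstream of it carry negative user-facing
    coordinates. For a bare promoter whose start codon immediately follows
    the sequence, ``anchor == len(seq)`` and the coordinates run
    ``-len(seq) .. -1``.
    """

    id: str
    seq: str
    anchor: int = 0

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if not _VALID.match(self.seq):
            bad = sorted(set(self.seq) - set(ALPHABET))
            raise ValueError(
                f"record {self.id!r}: non-ACGT characters {bad}"
            )
        if not (0 <= self.anchor <= len(self.seq)):
            raise ValueError(
                f"record {self.id!r}: anchor {self.anchor} outside [0, {len(self.seq)}]"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def coord_to_index(self, coord: int) -> int:
        """Map a start-codon-anchored coordinate to a 0-based index."""
        idx = self.anchor + coord
        if not (0 <= idx < len(self.seq)):
            raise IndexError(f"coordinate {coord} outside {self.id!r}")
        return idx

    def index_to_coord(self, idx: int) -> int:
        return idx - self.anchor

    def fragment(self, coord: int, length: int) -> str:
        i = self.coord_to_index(coord)
        if i + length > len(self.seq):
            raise IndexError(f"fragment {coord}+{length} overruns {self.id!r}")
        return self.seq[i : i + length]


def read_sequences(path: str | Path, anchor_rule: str = "end") -> list[NucSequence]:
    """Read a FASTA file into NucSequences.

    anchor_rule "end": the start codon immediately follows the sequence
    (promoter-only records); "start": anchor at index 0.
    """
    records: list[NucSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if anchor_rule == "end":
            anchor = len(seq)
        elif anchor_rule == "start":
            anchor = 0
        else:
            raise ValueError(f"unknown anchor_rule {anchor_rule!r}")
        records.append(NucSequence(rec.id, seq, anchor))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_sequences(path: str | Path, seqs: Iterable[NucSequence]) -> None:
    recs = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    SeqIO.write(recs, str(path), "fasta")


def read_motifs(path: str | Path) -> list[PSSM]:
    """Parse MEME minimal motif format into PSSMs.

    Each position's probabilities are renormalized to sum to 1; a deviation
    beyond 1e-6 is logged as a warning rather than rejected.
    """
    motifs: list[PSSM] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: MOTIF line without a name: {line!r}")
            name = parts[1]
            # seek the letter-probability header
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise ValueError(f"{path}: motif {name!r} has no matrix")
                i += 1
            if i >= len(lines):
                raise ValueError(f"{path}: motif {name!r} has no matrix")
            header = lines[i]
            m = re.search(r"w=\s*(\d+)", header)
            width = int(m.group(1)) if m else None
            i += 1
            rows: list[list[float]] = []
            while i < len(lines):
                s = lines[i].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                vals = [float(x) for x in s.split()]
                if len(vals) != 4:
                    raise ValueError(
                        f"{path}: motif {name!r}: expected 4 probabilities per row, "
                        f"got {len(vals)}"
                    )
                rows.append(vals)
                i += 1
            if width is not None and len(rows) != width:
                raise ValueError(
                    f"{path}: motif {name!r}: w={width} but {len(rows)} rows"
                )
            freq = np.array(rows, dtype=float)
            if (freq < 0).any():
                raise ValueError(f"{path}: motif {name!r}: negative entries")
            sums = freq.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-6:
                logger.warning(
                    "motif %s: rows renormalized (max deviation %.3g)",
                    name,
                    float(np.abs(sums - 1.0).max()),
                )
            motifs.append(PSSM(name, freq))
        else:
            i += 1
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs


def write_motifs(path: str | Path, motifs: Iterable[PSSM]) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(m)} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.freq:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


_CONFIG_DEFAULTS = {
    "seed": 0,
    "n_permutations": 100,
    "alpha": 0.05,
    "padding_value": 0.25,
    "window_radius": 4,
    "prevalence_threshold": 6.5,
    "cross_dataset_radius": 20,
    "fold_window": 40,
    "fold_step": 1,
    "group_fraction": 0.10,
    "spearman_cutoff": 0.99,
    "cv_repeats": 10,
}


@dataclasses.dataclass
class RunConfig:
    """Pipeline-wide parameters; defaults are the published procedure's.

    group_fraction is the top/bottom share defining over/under-expressed
    groups (10%); prevalence_threshold is the window-prevalence cut in
    percent (strictly greater than 6.5 keeps a motif); cross_dataset_radius
    is the ±nt tolerance for harmonizing positions between datasets.
    """

    seed: int = 0
    n_permutations: int = 100
    alpha: float = 0.05
    padding_value: float = 0.25
    window_radius: int = 4
    prevalence_threshold: float = 6.5
    cross_dataset_radius: int = 20
    fold_window: int = 40
    fold_step: int = 1
    group_fraction: float = 0.10
    spearman_cutoff: float = 0.99
    cv_repeats: int = 10

    def __post_init__(self) -> None:
        for key in ("alpha", "group_fraction"):
            v = getattr(self, key)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{key}={v} must lie in (0, 1)")
        if not (0.0 <= self.padding_value <= 1.0):
            raise ValueError("padding_value must be a probability")
        for key in ("n_permutations", "window_radius", "cross_dataset_radius",
                    "fold_window", "fold_step", "cv_repeats"):
            v = getattr(self, key)
            if int(v) != v or v <= 0:
                raise ValueError(f"{key}={v} must be a positive integer")
            setattr(self, key, int(v))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML key-value config; unset keys take the printed defaults.

    Unknown keys are an error (no silent ignore). The resolved config is
    echoed to the log.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        data = raw
    unknown = set(data) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**{**_CONFIG_DEFAULTS, **data})
    logger.info("resolved config: %s", dataclasses.asdict(cfg))
    return cfg


def read_table(path: str | Path):
    """TSV with mandatory header; empty fields are missing values."""
    import pandas as pd

    return pd.read_csv(path, sep="\t")


def write_table(path: str | Path, df) -> None:
    df.to_csv(path, sep="\t", index=False)
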