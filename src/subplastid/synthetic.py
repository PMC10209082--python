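"""Synthetic plastid-protein generator.

Emulates the signal structure that origin/localization prediction exploits,
so the whole pipeline is testable without downloading curated sequence sets:

* nuclear-encoded classes carry an N-terminal transit-peptide-like region,
  enriched in Ser/Thr and depleted in Asp/Glu;
* thylakoid-lumen classes carry a Sec- or Tat-style bipartite signal — a
  short polar n-region, a hydrophobic h-region, and a polar c-region — with
  the Tat signal bearing the twin-arginine (RR) dipeptide at the start of
  the hydrophobic stretch;
* membrane classes contain one or more transmembrane-like runs of >=15
  residues from the hydrophobic alphabet {A,I,L,V,F,M};
* plastid-encoded classes draw their mature region from a globally shifted
  amino-acid composition relative to nuclear-encoded ones;
* classes that real predictors separate through class-specific targeting or
  retention signals (e.g. the DPLG motif of light-harvesting proteins in the
  thylakoid membrane) carry a short signature motif with high probability.

The generator aims at separability with realistic signal *types*, not at
reproducing natural sequence statistics; see the methods note for what this
does and does not imply about performance on real proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .seq_data import (
    AMINO_ACIDS,
    FINE_CLASSES,
    ClassLabel,
    LabeledDataset,
    ProteinRecord,
)

__all__ = ["GeneratorConfig", "generate_dataset", "generate_signal_msa"]

HYDROPHOBIC = "AILVFM"
_POLAR_N = "ASTGNQK"  # n-region alphabet (no R: Sec signals must lack RR)
_POLAR_C = "ASTGNQ"  # c-region alphabet

_N_REGION_LEN_TAT = 4  # followed by the RR dipeptide -> 6 columns total
_N_REGION_LEN_SEC = 6
_C_REGION_LEN = 6


@dataclass
class GeneratorConfig:
    """Defaults define the study conditions for every synthetic experiment.

    ``length_range`` bounds the mature-region length; transit peptides use
    ``tp_length_range`` (shorter ``lumen_tp_length_range`` for the two
    thylakoid-lumen classes, whose twin-arginine motif must sit close to the
    N-terminus).  ``shift_delta`` is added to the background frequency of
    each residue in ``shift_residues`` for plastid-encoded classes, followed
    by renormalization.
    """

    n_per_class: int = 60
    seed: int = 0
    length_range: tuple[int, int] = (60, 140)
    tp_length_range: tuple[int, int] = (30, 80)
    lumen_tp_length_range: tuple[int, int] = (20, 32)
    tp_st_prob: float = 0.30  # total probability of S+T inside transit peptide
    tp_de_prob: float = 0.02  # total probability of D+E inside transit peptide
    shift_delta: float = 0.02
    shift_residues: str = "FIL"
    tm_run_length_range: tuple[int, int] = (18, 25)
    tm_runs: dict = field(
        default_factory=lambda: {
            "N_E_IM": 2,
            "N_E_OM": 1,
            "N_TM": 2,
            "P_IM": 2,
            "P_TM": 3,
        }
    )
    h_region_length: int = 12
    motif_prob: float = 0.9
    class_motifs: dict = field(
        default_factory=lambda: {
            "N_TM": "DPLG",  # LHCP-style cpSRP43-interaction motif
            "P_IM": "WNCK",  # synthetic inner-envelope signature
            "P_TM": "WQCD",  # synthetic plastid-TM signature
            "N_E_OM": "YGNW",  # synthetic outer-membrane signature
        }
    )

    def __post_init__(self):
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if self.length_range[0] < 30:
            raise ValueError("minimum mature-region length must be >= 30")
        if not 0 <= self.tp_st_prob + self.tp_de_prob <= 1:
            raise ValueError("transit-peptide composition probabilities invalid")
        if self.shift_delta < 0:
            raise ValueError("shift_delta must be non-negative")

    # -- composition tables -------------------------------------------------

    @property
    def nuclear_background(self) -> np.ndarray:
        """Uniform 1/20 background for nuclear-encoded mature regions."""
        return np.full(20, 1.0 / 20)

    @property
    def plastid_background(self) -> np.ndarray:
        """Nuclear background with +delta on the shifted residues, renormalized."""
        p = self.nuclear_background.copy()
        for aa in self.shift_residues:
            p[AMINO_ACIDS.index(aa)] += self.shift_delta
        return p / p.sum()

    @property
    def transit_peptide_composition(self) -> np.ndarray:
        p = np.zeros(20)
        p[AMINO_ACIDS.index("S")] = self.tp_st_prob / 2
        p[AMINO_ACIDS.index("T")] = self.tp_st_prob / 2
        p[AMINO_ACIDS.index("D")] = self.tp_de_prob / 2
        p[AMINO_ACIDS.index("E")] = self.tp_de_prob / 2
        rest = [i for i, aa in enumerate(AMINO_ACIDS) if aa not in "STDE"]
        p[rest] = (1.0 - self.tp_st_prob - self.tp_de_prob) / len(rest)
        return p

    @property
    def expected_shift(self) -> float:
        """Theoretical per-residue plastid-minus-nuclear frequency difference
        for each shifted residue (after renormalization)."""
        k = len(self.shift_residues)
        shifted = (1.0 / 20 + self.shift_delta) / (1.0 + k * self.shift_delta)
        return shifted - 1.0 / 20


def _draw(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    idx = rng.choice(20, size=n, p=probs)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _draw_alphabet(rng: np.random.Generator, n: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def _signal_region(rng: np.random.Generator, kind: str, cfg: GeneratorConfig) -> str:
    """A Sec- or Tat-style lumenal targeting signal (fixed 24 columns)."""
    if kind == "Tat":
        n_region = _draw_alphabet(rng, _N_REGION_LEN_TAT, _POLAR_N) + "RR"
    elif kind == "Sec":
        n_region = _draw_alphabet(rng, _N_REGION_LEN_SEC, _POLAR_N)
    else:
        raise ValueError(f"signal kind must be 'Sec' or 'Tat', got {kind!r}")
    h_region = _draw_alphabet(rng, cfg.h_region_length, HYDROPHOBIC)
    c_region = _draw_alphabet(rng, _C_REGION_LEN, _POLAR_C)
    return n_region + h_region + c_region


def _mature(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    background: np.ndarray,
    n_runs: int = 0,
    motif: Optional[str] = None,
) -> str:
    """Mature region: background draw with transmembrane-like runs and an
    optional signature motif spliced in at cut points of the base sequence
    (pieces never interrupt each other)."""
    lo, hi = cfg.length_range
    base = _draw(rng, int(rng.integers(lo, hi + 1)), background)
    pieces = [
        _draw_alphabet(rng, int(rng.integers(*cfg.tm_run_length_range)), HYDROPHOBIC)
        for _ in range(n_runs)
    ]
    if motif is not None and rng.random() < cfg.motif_prob:
        pieces.append(motif)
    if not pieces:
        return base
    rng.shuffle(pieces)
    cuts = np.sort(rng.integers(0, len(base) + 1, size=len(pieces)))
    out, prev = [], 0
    for cut, piece in zip(cuts, pieces):
        out.append(base[prev:cut])
        out.append(piece)
        prev = cut
    out.append(base[prev:])
    return "".join(out)


def _transit_peptide(
    rng: np.random.Generator, cfg: GeneratorConfig, lumen: bool = False
) -> str:
    lo, hi = cfg.lumen_tp_length_range if lumen else cfg.tp_length_range
    return _draw(rng, int(rng.integers(lo, hi + 1)), cfg.transit_peptide_composition)


def _make_record(
    rng: np.random.Generator, cfg: GeneratorConfig, fine: str, side: Optional[str]
) -> tuple[str, int]:
    """Return (sequence, transit-peptide length) for one record."""
    nuc_bg, pla_bg = cfg.nuclear_background, cfg.plastid_background
    motifs, runs = cfg.class_motifs, cfg.tm_runs
    if fine == "N_S":
        tp = _transit_peptide(rng, cfg)
        return tp + _mature(rng, cfg, nuc_bg), len(tp)
    if fine == "N_E":
        tp = _transit_peptide(rng, cfg)
        key = f"N_E_{side}"
        body = _mature(rng, cfg, nuc_bg, runs[key], motifs.get(key))
        return tp + body, len(tp)
    if fine == "N_TM":
        tp = _transit_peptide(rng, cfg)
        body = _mature(rng, cfg, nuc_bg, runs["N_TM"], motifs.get("N_TM"))
        return tp + body, len(tp)
    if fine in ("N_TL_SEC", "N_TL_TAT"):
        tp = _transit_peptide(rng, cfg, lumen=True)
        kind = "Tat" if fine == "N_TL_TAT" else "Sec"
        signal = _signal_region(rng, kind, cfg)
        return tp + signal + _mature(rng, cfg, nuc_bg), len(tp)
    if fine == "P_S":
        return _mature(rng, cfg, pla_bg), 0
    if fine == "P_IM":
        return _mature(rng, cfg, pla_bg, runs["P_IM"], motifs.get("P_IM")), 0
    if fine == "P_TM":
        return _mature(rng, cfg, pla_bg, runs["P_TM"], motifs.get("P_TM")), 0
    raise ValueError(f"unknown fine class {fine!r}")


def generate_dataset(
    config: GeneratorConfig, return_annotations: bool = False
):
    """Generate ``n_per_class`` labeled records for each of the 8 classes.

    Reproducible for a fixed config (a single seeded generator drives all
    randomness).  Nuclear-encoded envelope records alternate between the
    inner (IM) and outer (OM) membrane side.  With
    ``return_annotations=True`` also returns a DataFrame with the
    transit-peptide length of every record (0 for plastid-encoded classes),
    which tests use to dissect regions.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    annot: list[dict] = []
    for fine in FINE_CLASSES:
        for i in range(config.n_per_class):
            side = None
            if fine == "N_E":
                side = "IM" if i % 2 == 0 else "OM"
            seq, tp_len = _make_record(rng, config, fine, side)
            rec_id = f"{fine}_{i:04d}"
            records.append(
                ProteinRecord(rec_id, seq, ClassLabel(fine, envelope_side=side))
            )
            annot.append(
                {"id": rec_id, "class": fine, "tp_len": tp_len, "side": side}
            )
    dataset = LabeledDataset(records)
    if return_annotations:
        return dataset, pd.DataFrame(annot)
    return dataset


def generate_signal_msa(kind: str, n: int, seed: int) -> list[tuple[str, str]]:
    """Generate an aligned (gapless, equal-length) set of signal regions.

    Stands in for a curated alignment of Sec or Tat signal peptides: every
    row is a fresh draw from the signal model, so all rows share the fixed
    n/h/c-region column layout and the alignment needs no gap columns.  The
    Tat alignment has two fully conserved arginine columns at the start of
    the hydrophobic stretch.
    """
    if n < 2:
        raise ValueError("an alignment needs at least 2 rows")
    cfg = GeneratorConfig(n_per_class=1, seed=seed)
    rng = np.random.default_rng(seed)
    return [
        (f"{kind.lower()}_{i:03d}", _signal_region(rng, kind, cfg))
        for i in range(n)
    ]
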