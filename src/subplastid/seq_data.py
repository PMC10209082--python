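"""Sequence and label handling for plastid proteins.

Plastid proteomes mix proteins encoded in the nuclear genome (imported
post-translationally via an N-terminal transit peptide) and in the plastid
genome (synthesised in the stroma).  Each protein additionally resides in one
of four subplastid compartments: the envelope, the stroma, the thylakoid
membrane, or the thylakoid lumen.  Thylakoid-lumen proteins arrive through
one of two translocation routes, Sec or Tat.  This module defines the
eight-class taxonomy that combines origin, compartment and (for the lumen)
import pathway, plus FASTA/TSV I/O and alphabet validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "AMINO_ACIDS",
    "FINE_CLASSES",
    "ClassLabel",
    "ProteinRecord",
    "LabeledDataset",
    "FastaParseError",
    "map_generalized",
    "read_fasta",
    "write_fasta",
    "read_labels_tsv",
    "write_labels_tsv",
    "validate_standard",
]

#: The 20 standard amino-acid one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Fine class labels: origin prefix (N = nuclear-encoded, P = plastid-encoded)
#: followed by compartment (E envelope, S stroma, TM thylakoid membrane,
#: TL thylakoid lumen with Sec/Tat import pathway).
FINE_CLASSES = (
    "N_E",
    "N_TM",
    "N_S",
    "N_TL_SEC",
    "N_TL_TAT",
    "P_IM",
    "P_TM",
    "P_S",
)

_GENERALIZED = {
    "N_E": "envelope",
    "P_IM": "envelope",
    "N_S": "stroma",
    "P_S": "stroma",
    "N_TM": "thylakoid_membrane",
    "P_TM": "thylakoid_membrane",
    "N_TL_SEC": "thylakoid_lumen",
    "N_TL_TAT": "thylakoid_lumen",
}

_PATHWAY = {"N_TL_SEC": "Sec", "N_TL_TAT": "Tat"}


class FastaParseError(ValueError):
    """Raised on malformed FASTA input; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def map_generalized(fine: str) -> tuple[str, str]:
    """Map a fine class to its (origin, generalized localization) pair.

    The mapping is the fixed partition of the eight fine classes:
    {N_E, P_IM} -> envelope, {N_S, P_S} -> stroma, {N_TM, P_TM} ->
    thylakoid_membrane, {N_TL_SEC, N_TL_TAT} -> thylakoid_lumen; origin is
    nuclear iff the label starts with ``N_``.
    """
    if fine not in _GENERALIZED:
        raise ValueError(f"unknown fine class: {fine!r}")
    origin = "nuclear" if fine.startswith("N_") else "plastid"
    return origin, _GENERALIZED[fine]


@dataclass(frozen=True)
class ClassLabel:
    """Fine class plus the derived origin/localization taxonomy.

    ``envelope_side`` distinguishes the outer (OM) from the inner (IM)
    envelope membrane and is meaningful only for nuclear-encoded envelope
    proteins (N_E).
    """

    fine: str
    envelope_side: Optional[str] = None

    def __post_init__(self):
        if self.fine not in FINE_CLASSES:
            raise ValueError(f"unknown fine class: {self.fine!r}")
        if self.envelope_side is not None:
            if self.fine != "N_E":
                raise ValueError("envelope_side is only valid for N_E")
            if self.envelope_side not in ("IM", "OM"):
                raise ValueError("envelope_side must be 'IM' or 'OM'")

    @property
    def origin(self) -> str:
        return map_generalized(self.fine)[0]

    @property
    def generalized(self) -> str:
        return map_generalized(self.fine)[1]

    @property
    def pathway(self) -> Optional[str]:
        return _PATHWAY.get(self.fine)


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence with an optional class label."""

    id: str
    sequence: str
    label: Optional[ClassLabel] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")

    @property
    def fine(self) -> Optional[str]:
        return self.label.fine if self.label is not None else None


@dataclass
class LabeledDataset:
    """An ordered collection of protein records with unique ids."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id: {rec.id!r}")
            seen.add(rec.id)
        short = [r.id for r in self.records if len(r.sequence) < 10]
        if short:
            warnings.warn(
                f"{len(short)} sequence(s) shorter than 10 residues "
                f"(e.g. {short[0]!r}); kept",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, idx):
        return self.records[idx]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> list[Optional[str]]:
        return [r.fine for r in self.records]

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in FINE_CLASSES}
        for rec in self.records:
            if rec.fine is not None:
                counts[rec.fine] += 1
        return counts

    def subset(self, ids: Iterable[str]) -> "LabeledDataset":
        """Records for the given ids, in the given order (unknown ids ignored)."""
        by_id = {r.id: r for r in self.records}
        return LabeledDataset([by_id[i] for i in ids if i in by_id])

    def with_labels(self, labels: Mapping[str, object]) -> "LabeledDataset":
        """Return a copy with labels attached from an id -> class map
        (values may be fine-class strings or :class:`ClassLabel`)."""
        out = []
        for rec in self.records:
            if rec.id in labels:
                value = labels[rec.id]
                label = value if isinstance(value, ClassLabel) else ClassLabel(value)
                out.append(ProteinRecord(rec.id, rec.sequence, label))
            else:
                out.append(rec)
        return LabeledDataset(out)


def _parse_header(header: str) -> tuple[str, Optional[str]]:
    """Split a FASTA header into (id, optional fine class after '|')."""
    token = header.split()[0] if header.split() else header
    if "|" in token:
        rec_id, _, fine = token.partition("|")
        return rec_id, (fine if fine in FINE_CLASSES else None)
    return token, None


def read_fasta(
    path,
    labels: Optional[Mapping[str, str]] = None,
) -> LabeledDataset:
    """Read a (multi-record) FASTA file into a :class:`LabeledDataset`.

    Sequences are upper-cased and record order is preserved.  Labels may be
    encoded in the header after a ``|`` separator or supplied through the
    ``labels`` map (typically from :func:`read_labels_tsv`); the explicit map
    wins on conflict.  Gap characters and other non-alphabetic symbols are a
    parse error — use :func:`validate_standard` to *filter* sequences that
    merely contain non-standard amino-acid codes.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []
    seen: set[str] = set()

    def flush(line_no: int):
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FastaParseError(f"entry {header!r} has no sequence", header_line)
        for ch in seq:
            if not ch.isalpha():
                raise FastaParseError(
                    f"entry {header!r}: illegal character {ch!r} in sequence",
                    header_line,
                )
        rec_id, inline_label = _parse_header(header)
        if rec_id in seen:
            raise FastaParseError(f"duplicate id {rec_id!r}", header_line)
        seen.add(rec_id)
        value = None
        if labels is not None and rec_id in labels:
            value = labels[rec_id]
        elif inline_label is not None:
            value = inline_label
        if value is None:
            label = None
        elif isinstance(value, ClassLabel):
            label = value
        else:
            label = ClassLabel(value)
        records.append(ProteinRecord(rec_id, seq, label))
        header, chunks = None, []

    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].strip()
                header_line = line_no
                if not header:
                    raise FastaParseError("empty FASTA header", line_no)
            else:
                if header is None:
                    raise FastaParseError(
                        "sequence data before first '>' header", line_no
                    )
                chunks.append(line)
        flush(line_no if records or header else 0)
    return LabeledDataset(records)


def write_fasta(dataset: LabeledDataset, path, width: int = 60) -> None:
    """Write a dataset as FASTA; labels are encoded after '|' in headers."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in dataset:
            header = rec.id if rec.fine is None else f"{rec.id}|{rec.fine}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_labels_tsv(path) -> dict[str, ClassLabel]:
    """Read a sidecar label table: ``id<TAB>class[<TAB>envelope_side]``.

    The optional third column carries the inner/outer envelope membrane
    side (IM/OM) of N_E records.
    """
    labels: dict[str, ClassLabel] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["id", "class"]:
            raise ValueError("labels TSV must start with header 'id\\tclass'")
        for line_no, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"labels TSV line {line_no}: expected 2 columns")
            rec_id, fine = parts[0], parts[1]
            if fine not in FINE_CLASSES:
                raise ValueError(
                    f"labels TSV line {line_no}: unknown class {fine!r}"
                )
            side = parts[2] if len(parts) > 2 and parts[2] else None
            labels[rec_id] = ClassLabel(fine, envelope_side=side)
    return labels


def write_labels_tsv(dataset: LabeledDataset, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tclass\tenvelope_side\n")
        for rec in dataset:
            if rec.fine is not None:
                side = rec.label.envelope_side or ""
                fh.write(f"{rec.id}\t{rec.fine}\t{side}\n")


def validate_standard(
    dataset: LabeledDataset,
) -> tuple[LabeledDataset, list[tuple[str, str]]]:
    """Filter out sequences containing non-standard amino acids.

    Returns the retained dataset and a list of (id, offending character)
    pairs for every removed record.  Ambiguity codes (B, J, O, U, X, Z) are
    not part of the 20-letter standard alphabet and are rejected.
    """
    kept: list[ProteinRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in dataset:
        bad = next((ch for ch in rec.sequence if ch not in _AA_SET), None)
        if bad is None:
            kept.append(rec)
        else:
            rejected.append((rec.id, bad))
    return LabeledDataset(kept), rejected
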