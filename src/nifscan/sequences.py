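"""Protein sequence I/O: FASTA reading/writing, validation, filtering, tables.

Sequences are modelled as immutable records over the 20-letter standard
amino-acid alphabet. Reading is deliberately permissive (raw read, uppercase,
terminal ``*`` stop symbol stripped); alphabet validation happens in
:func:`filter_standard` so that a caller can report exactly which records of
a real proteome were dropped and why.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .alphabet import is_standard

logger = logging.getLogger(__name__)


class FastaParseError(ValueError):
    """Malformed FASTA input (e.g. sequence data before the first header)."""


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence.

    ``residues`` is stored uppercase; after :func:`filter_standard` every
    character is one of the 20 standard amino acids.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be non-empty without whitespace, got {self.id!r}")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has an empty body")

    @property
    def length(self) -> int:
        return len(self.residues)

    def is_standard(self) -> bool:
        return is_standard(self.residues)


@dataclass(frozen=True)
class FilterReport:
    """Accounting of a filtering pass: every input is kept or listed removed."""

    n_input: int
    n_kept: int
    removed_nonstandard: tuple[str, ...] = ()
    removed_duplicates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_input != self.n_kept + len(self.removed_nonstandard) + len(self.removed_duplicates):
            raise ValueError("filter report does not conserve sequence count")


@dataclass(frozen=True)
class LabeledDataset:
    """Sequences with one class label each, drawn from a declared label set."""

    sequences: tuple[ProteinSequence, ...]
    labels: tuple[str, ...]
    label_set: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        declared = set(self.label_set)
        stray = sorted(set(self.labels) - declared)
        if stray:
            raise ValueError(f"labels outside the declared label set: {stray}")

    def __len__(self) -> int:
        return len(self.sequences)

    def by_label(self) -> dict[str, list[ProteinSequence]]:
        out: dict[str, list[ProteinSequence]] = {lab: [] for lab in self.label_set}
        for seq, lab in zip(self.sequences, self.labels):
            out[lab].append(seq)
        return out


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a protein FASTA file.

    One record per ``>`` header, in file order. Bodies are uppercased and a
    single terminal ``*`` (stop symbol) is stripped; no alphabet validation
    is applied here. The record id is the header token before the first
    whitespace; the remainder becomes the description.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith(">"):
                break
            raise FastaParseError(
                f"{path.name} line {lineno}: expected '>' header, got {line.strip()[:40]!r}"
            )
        else:
            raise ValueError(f"no records in FASTA file {path}")

    records: list[ProteinSequence] = []
    with open(path) as fh:
        for title, body in SimpleFastaParser(fh):
            parts = title.split(None, 1)
            if not parts:
                raise FastaParseError(f"{path.name}: record {len(records) + 1} has an empty header")
            seq_id = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            body = body.upper()
            if body.endswith("*"):
                body = body[:-1]
            if not body:
                raise ValueError(f"record {seq_id!r} has an empty sequence body")
            records.append(ProteinSequence(id=seq_id, residues=body, description=desc))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA with bodies wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for seq in seqs:
            header = f">{seq.id}" + (f" {seq.description}" if seq.description else "")
            fh.write(header + "\n")
            for i in range(0, seq.length, width):
                fh.write(seq.residues[i : i + width] + "\n")


def filter_standard(
    seqs: Sequence[ProteinSequence],
) -> tuple[list[ProteinSequence], FilterReport]:
    """Keep only sequences composed entirely of the 20 standard amino acids.

    Order is preserved; removed ids are listed in the report. Idempotent.
    """
    kept, removed = [], []
    for seq in seqs:
        (kept if seq.is_standard() else removed).append(seq)
    report = FilterReport(
        n_input=len(seqs),
        n_kept=len(kept),
        removed_nonstandard=tuple(s.id for s in removed),
    )
    if removed:
        logger.info("filter_standard removed %d of %d sequences", len(removed), len(seqs))
    return kept, report


def deduplicate(
    seqs: Sequence[ProteinSequence],
) -> tuple[list[ProteinSequence], FilterReport]:
    """Remove exact residue-string duplicates (case-insensitive), keeping the
    first occurrence of each distinct sequence in input order."""
    seen: set[str] = set()
    kept, removed = [], []
    for seq in seqs:
        key = seq.residues.upper()
        if key in seen:
            removed.append(seq)
        else:
            seen.add(key)
            kept.append(seq)
    report = FilterReport(
        n_input=len(seqs),
        n_kept=len(kept),
        removed_duplicates=tuple(s.id for s in removed),
    )
    return kept, report


def clean(seqs: Sequence[ProteinSequence]) -> tuple[list[ProteinSequence], FilterReport]:
    """Standard-alphabet filtering followed by exact deduplication, with one
    combined report."""
    std, rep1 = filter_standard(seqs)
    uniq, rep2 = deduplicate(std)
    return uniq, FilterReport(
        n_input=len(seqs),
        n_kept=len(uniq),
        removed_nonstandard=rep1.removed_nonstandard,
        removed_duplicates=rep2.removed_duplicates,
    )


def write_prediction_table(records: Sequence, path: str | Path) -> None:
    """Write prediction results as a four-column TSV.

    Columns: 1-based serial number, sequence identifier, predicted nif
    category (or the literal tokens ``non-nif`` / ``unassigned``), and the
    probability of that call to six decimal places. Records are duck-typed:
    they need ``sequence_id``, ``stage1_label``, ``stage1_prob``,
    ``category`` and ``category_prob`` attributes (see
    :class:`nifscan.pipeline.PredictionRecord`).
    """
    with open(path, "w") as fh:
        fh.write("serial\tsequence_id\tprediction\tprobability\n")
        for serial, rec in enumerate(records, start=1):
            if getattr(rec, "error", None):
                label, prob = "error", float("nan")
            elif rec.category is not None:
                label, prob = rec.category, rec.category_prob
            elif rec.stage1_label == "nif":
                label, prob = "unassigned", rec.category_prob
            else:
                label, prob = "non-nif", rec.stage1_prob
            fh.write(f"{serial}\t{rec.sequence_id}\t{label}\t{prob:.6f}\n")
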