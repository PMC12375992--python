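"""FASTA input/output and sequence-record normalisation.

Records are plain dataclasses; parsing validates residue alphabets and
identifier uniqueness up front so downstream motif scans can assume clean
input. The pre-alignment trimming rule (drop everything before the first
cysteine, which marks the boundary of the beta-barrel core) lives here.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, TextIO

import pandas as pd

#: the 20 standard one-letter codes plus ambiguity codes and selenocysteine
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_AA = STANDARD_AA | set("XBZU")
GAP_CHARS = set("-.")

CLASS_LABELS = ("class_I", "class_II", "unknown")


class FastaParseError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


class DuplicateIdError(FastaParseError):
    """Two records share an identifier."""


class NoCysteineError(ValueError):
    """Raised when an operation requires at least one cysteine."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with identifier, description, and class label."""

    id: str
    residues: str
    description: str = ""
    class_label: str = "unknown"
    taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        bad = set(self.residues) - ALLOWED_AA
        if bad:
            raise ValueError(f"invalid residue codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TrimResult:
    """Outcome of trimming residues preceding the first cysteine."""

    record: SequenceRecord
    n_removed: int


def _parse_header(line: str) -> tuple[str, str]:
    """Extract (id, description) from a FASTA header line (no leading '>').

    UniProt-style three-field headers like ``sp|P78714|EAS_NEUCR desc`` yield
    the accession; anything else falls back to the first whitespace token.
    """
    token, _, rest = line.partition(" ")
    fields = token.split("|")
    if len(fields) == 3 and fields[0] in ("sp", "tr") and fields[1]:
        return fields[1], line
    return token, rest.strip()


def read_fasta(source: TextIO | str) -> list[SequenceRecord]:
    """Parse FASTA text into a list of :class:`SequenceRecord`.

    Wrapped sequence lines are concatenated and lowercase residues coerced
    to uppercase. Gap characters (``-``, ``.``) are stripped with a warning.

    Raises
    ------
    FastaParseError
        On residue characters outside the amino-acid alphabet (the error
        names the line) or on duplicate record identifiers.
    """
    if isinstance(source, str):
        source = io.StringIO(source)

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    saw_gaps = False

    def flush() -> None:
        if header is None:
            return
        rec_id, desc = _parse_header(header)
        if rec_id in seen:
            raise DuplicateIdError(f"duplicate record id {rec_id!r}")
        seen.add(rec_id)
        records.append(SequenceRecord(id=rec_id, residues="".join(chunks), description=desc))

    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            if not header:
                raise FastaParseError(f"line {lineno}: empty FASTA header")
            chunks = []
        else:
            if header is None:
                raise FastaParseError(f"line {lineno}: sequence data before any header")
            seq = line.upper()
            if any(c in GAP_CHARS for c in seq):
                saw_gaps = True
                seq = "".join(c for c in seq if c not in GAP_CHARS)
            bad = set(seq) - ALLOWED_AA
            if bad:
                raise FastaParseError(
                    f"line {lineno}: invalid residue characters {sorted(bad)}"
                )
            chunks.append(seq)
    flush()
    if saw_gaps:
        warnings.warn("gap characters ('-', '.') stripped from input sequences")
    return records


def write_fasta(records: Iterable[SequenceRecord], dest: TextIO, width: int = 80) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    for rec in records:
        desc = f" {rec.description}" if rec.description else ""
        dest.write(f">{rec.id}{desc}\n")
        for i in range(0, len(rec.residues), width):
            dest.write(rec.residues[i : i + width] + "\n")


def trim_before_first_cys(record: SequenceRecord) -> TrimResult:
    """Drop residues preceding the first cysteine (the core boundary).

    Idempotent; the number of removed residues is reported alongside.

    Raises
    ------
    NoCysteineError
        If the sequence contains no cysteine; such records are excluded
        from motif-based analyses downstream.
    """
    idx = record.residues.find("C")
    if idx < 0:
        raise NoCysteineError(f"record {record.id!r} contains no cysteine")
    return TrimResult(record=replace(record, residues=record.residues[idx:]), n_removed=idx)


def metadata_table(records: Iterable[SequenceRecord]) -> pd.DataFrame:
    """Per-record metadata (id, length, class_label) as a DataFrame."""
    rows = [
        {"seq_id": r.id, "length": len(r), "class_label": r.class_label} for r in records
    ]
    return pd.DataFrame(rows, columns=["seq_id", "length", "class_label"])
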