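"""FASTA and labeled-FASTA input/output.

Plain FASTA is handled through Biopython.  The labeled dialect used for
benchmark datasets stores, per record, the amino-acid sequence followed by a
per-residue topology string of equal length drawn from a six-state alphabet:

    H/h  transmembrane helix
    B/b  transmembrane beta strand
    S    signal peptide
    1    intracellular
    2    extracellular
    U    unknown / unresolved

Sequence and label blocks may each span several lines; the concatenated
payload is split at its midpoint (the two halves must have equal length, so
an odd payload is a format error rather than a guess).

All coordinates exposed by this module are 1-based inclusive.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "AMBIGUITY_LETTERS",
    "LABEL_ALPHABET",
    "SequenceRecord",
    "TopologyAnnotation",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "read_labeled_fasta",
    "write_labeled_fasta",
    "annotation_segments",
]

#: The 20 standard amino-acid one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard letters accepted on input and passed through.
AMBIGUITY_LETTERS = "XBZUO"

_VALID_RESIDUES = frozenset(AMINO_ACIDS + AMBIGUITY_LETTERS)

#: Six-state per-residue topology labels.
LABEL_ALPHABET = frozenset("HhBbS12U")

Source = Union[str, Path, TextIO]


class FastaFormatError(ValueError):
    """Raised for malformed FASTA / labeled-FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: identifier, free-text description, residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TopologyAnnotation:
    """Per-residue six-state topology labels paired with one sequence."""

    labels: str

    def __post_init__(self) -> None:
        bad = set(self.labels) - LABEL_ALPHABET
        if bad:
            raise ValueError(
                f"labels contain characters outside the six-state alphabet: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.labels)


def _as_text_stream(source: Source) -> tuple[TextIO, bool]:
    """Return (stream, owns_it).  Accepts a path, a path string or a stream."""
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.exists() or "\n" not in str(source):
            return open(p, "r", encoding="utf-8", newline=None), True
        # A string with newlines but no such file: treat as literal text.
        return _stdio.StringIO(str(source)), True
    return source, False


def _check_residues(record_id: str, residues: str, base_offset: int = 0) -> None:
    for pos, ch in enumerate(residues, start=1):
        if ch not in _VALID_RESIDUES:
            raise FastaFormatError(
                f"record {record_id!r}: illegal residue character {ch!r} "
                f"at position {base_offset + pos}"
            )


def read_fasta(source: Source) -> list[SequenceRecord]:
    """Read plain FASTA into a list of :class:`SequenceRecord`.

    Whitespace inside sequence lines is stripped and lowercase residues are
    uppercased.  Raises :class:`FastaFormatError` for an empty file, for
    sequence data before the first header, for duplicate ids and for residue
    characters outside the amino-acid + ambiguity alphabet.
    """
    stream, owns = _as_text_stream(source)
    try:
        text = stream.read()
    finally:
        if owns:
            stream.close()
    stripped = text.lstrip()
    if not stripped:
        raise FastaFormatError("no records found (empty input)")
    if not stripped.startswith(">"):
        raise FastaFormatError("sequence data before the first '>' header")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_stdio.StringIO(text), "fasta"):
        residues = "".join(str(rec.seq).split()).upper()
        if not rec.id:
            raise FastaFormatError("record with empty id")
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if not residues:
            raise FastaFormatError(f"record {rec.id!r}: empty sequence")
        _check_residues(rec.id, residues)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, residues, desc))
    if not records:
        raise FastaFormatError("no records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], dest: Union[str, Path, TextIO],
                width: int = 60) -> None:
    """Write records as plain FASTA, wrapping sequence lines at ``width``."""
    recs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            _write_fasta_stream(recs, fh, width)
    else:
        _write_fasta_stream(recs, dest, width)


def _write_fasta_stream(recs: list[SeqRecord], fh: TextIO, width: int) -> None:
    for rec in recs:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        fh.write(f">{header}\n")
        s = str(rec.seq)
        for i in range(0, len(s), width):
            fh.write(s[i:i + width] + "\n")


def read_labeled_fasta(source: Source) -> list[tuple[SequenceRecord, TopologyAnnotation]]:
    """Read the labeled dialect: header, sequence block, label block.

    The non-header payload of each record is concatenated and split at its
    midpoint into sequence and labels; an odd total length is a format error
    naming the record.
    """
    stream, owns = _as_text_stream(source)
    try:
        text = stream.read()
    finally:
        if owns:
            stream.close()
    stripped = text.lstrip()
    if not stripped:
        raise FastaFormatError("no records found (empty input)")
    if not stripped.startswith(">"):
        raise FastaFormatError("data before the first '>' header")

    pairs: list[tuple[SequenceRecord, TopologyAnnotation]] = []
    seen: set[str] = set()
    header: str | None = None
    payload: list[str] = []

    def _flush() -> None:
        assert header is not None
        body = "".join(payload)
        fields = header.split(None, 1)
        rec_id = fields[0]
        desc = fields[1] if len(fields) > 1 else ""
        if rec_id in seen:
            raise FastaFormatError(f"duplicate record id {rec_id!r}")
        seen.add(rec_id)
        if not body:
            raise FastaFormatError(f"record {rec_id!r}: empty payload")
        if len(body) % 2 != 0:
            raise FastaFormatError(
                f"record {rec_id!r}: sequence and label lengths differ "
                f"(odd payload of {len(body)} characters)"
            )
        half = len(body) // 2
        residues, labels = body[:half].upper(), body[half:]
        _check_residues(rec_id, residues)
        bad = set(labels) - LABEL_ALPHABET
        if bad:
            raise FastaFormatError(
                f"record {rec_id!r}: label characters outside the six-state "
                f"alphabet: {sorted(bad)}"
            )
        pairs.append((SequenceRecord(rec_id, residues, desc),
                      TopologyAnnotation(labels)))

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                _flush()
            header = line[1:].strip()
            payload = []
        else:
            payload.append("".join(line.split()))
    if header is not None:
        _flush()
    if not pairs:
        raise FastaFormatError("no records found")
    return pairs


def write_labeled_fasta(pairs: Iterable[tuple[SequenceRecord, TopologyAnnotation]],
                        dest: Union[str, Path, TextIO], width: int = 60) -> None:
    """Write (record, annotation) pairs in the labeled dialect."""

    def _write(fh: TextIO) -> None:
        for rec, ann in pairs:
            if len(rec) != len(ann):
                raise ValueError(
                    f"record {rec.id!r}: sequence length {len(rec)} != "
                    f"label length {len(ann)}"
                )
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")
            for i in range(0, len(ann.labels), width):
                fh.write(ann.labels[i:i + width] + "\n")

    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            _write(fh)
    else:
        _write(dest)


def annotation_segments(annotation: TopologyAnnotation,
                        classes: Iterable[str]) -> list[tuple[int, int]]:
    """Maximal runs (1-based inclusive) of positions whose label is in *classes*.

    Passing both cases of a paired label (``{'H', 'h'}``) merges them into a
    single class, since membership is literal per position.
    """
    cls = set(classes)
    if not cls:
        raise ValueError("classes must be a non-empty set of labels")
    bad = cls - LABEL_ALPHABET
    if bad:
        raise ValueError(f"unknown label classes: {sorted(bad)}")
    segments: list[tuple[int, int]] = []
    start: int | None = None
    for pos, ch in enumerate(annotation.labels, start=1):
        if ch in cls:
            if start is None:
                start = pos
        elif start is not None:
            segments.append((start, pos - 1))
            start = None
    if start is not None:
        segments.append((start, len(annotation.labels)))
    return segments
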