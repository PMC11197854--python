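"""Transcript reference annotation: the coordinate system for everything else.

Coordinates are 0-based, half-open ``[start, end)`` throughout the
package. The CDS interval includes the stop codon, so the first
nucleotide of the stop codon sits at ``cds_end - 3``.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

__all__ = [
    "TranscriptRecord",
    "Reference",
    "AnnotationError",
    "load_annotation",
    "attach_sequences",
]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent transcript annotations."""


@dataclass(frozen=True)
class TranscriptRecord:
    """A single transcript: id, length and CDS bounds, optional sequence.

    Parameters
    ----------
    id : str
        Unique transcript identifier.
    length : int
        Transcript length in nucleotides; must be positive.
    cds_start : int
        0-based inclusive start of the coding sequence.
    cds_end : int
        0-based exclusive end of the coding sequence (stop codon
        included in the interval).
    sequence : str, optional
        Nucleotide sequence (A/C/G/T/N); present only after FASTA
        attachment and then exactly ``length`` characters long.
    """

    id: str
    length: int
    cds_start: int
    cds_end: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise AnnotationError(f"transcript {self.id!r}: length must be > 0, got {self.length}")
        if not (0 <= self.cds_start < self.cds_end <= self.length):
            raise AnnotationError(
                f"transcript {self.id!r}: CDS bounds [{self.cds_start}, {self.cds_end}) "
                f"violate 0 <= cds_start < cds_end <= length ({self.length})"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise AnnotationError(
                f"transcript {self.id!r}: sequence length {len(self.sequence)} != {self.length}"
            )

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start


@dataclass(frozen=True)
class Reference:
    """An ordered collection of transcripts plus a content digest.

    Record order is stable and defines the transcript index used by
    every downstream array. The digest covers ids, lengths and CDS
    bounds only — attaching sequences never changes it — and is the
    identity check for cross-experiment comparison.
    """

    name: str
    records: tuple[TranscriptRecord, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index: dict[str, int] = {}
        for i, rec in enumerate(self.records):
            if rec.id in index:
                raise AnnotationError(f"duplicate transcript id {rec.id!r}")
            index[rec.id] = i
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key):
        if isinstance(key, str):
            return self.records[self._index[key]]
        return self.records[key]

    def __contains__(self, tid: str) -> bool:
        return tid in self._index

    def index_of(self, tid: str) -> int:
        """Return the array index of transcript ``tid``."""
        try:
            return self._index[tid]
        except KeyError:
            raise KeyError(f"unknown transcript {tid!r}") from None

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def digest(self) -> str:
        """SHA-256 over (id, length, cds_start, cds_end) of every record."""
        h = hashlib.sha256()
        for rec in self.records:
            h.update(f"{rec.id}\t{rec.length}\t{rec.cds_start}\t{rec.cds_end}\n".encode())
        return h.hexdigest()


def _parse_int(token: str, what: str, row: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise AnnotationError(f"row {row}: non-integer {what}: {token!r}") from None


def load_annotation(path, name: Optional[str] = None) -> Reference:
    """Load a transcript annotation TSV into a :class:`Reference`.

    The file has 4 tab-separated columns: id, length, cds_start,
    cds_end. Lines starting with ``#`` are ignored; a single header row
    is detected by a non-integer second column. Any row violating the
    :class:`TranscriptRecord` invariants aborts the load.
    """
    path = Path(path)
    records: list[TranscriptRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise AnnotationError(
                    f"row {lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            if not records and not _is_int(fields[1]):
                # header row
                continue
            tid = fields[0]
            length = _parse_int(fields[1], "length", lineno)
            cds_start = _parse_int(fields[2], "cds_start", lineno)
            cds_end = _parse_int(fields[3], "cds_end", lineno)
            try:
                rec = TranscriptRecord(tid, length, cds_start, cds_end)
            except AnnotationError as exc:
                raise AnnotationError(f"row {lineno}: {exc}") from None
            if rec.cds_length % 3 != 0:
                warnings.warn(
                    f"transcript {tid!r}: CDS length {rec.cds_length} not divisible by 3",
                    stacklevel=2,
                )
            records.append(rec)
    if not records:
        raise AnnotationError(f"{path}: no transcripts")
    return Reference(name=name or path.stem, records=tuple(records))


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def attach_sequences(ref: Reference, fasta_path) -> Reference:
    """Return a new Reference with sequences attached from a FASTA file.

    FASTA records are matched to transcripts by the token before the
    first whitespace in the record name, case-sensitively. Transcripts
    without a matching FASTA record keep their sequence absent (with a
    warning); FASTA records without a matching transcript are ignored
    (with a warning). A sequence whose length disagrees with the
    annotation is an error — silent truncation is forbidden.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        tid = rec.id  # SeqIO already takes the token before whitespace
        if tid not in ref:
            warnings.warn(f"FASTA record {tid!r} has no matching transcript; ignored", stacklevel=2)
            continue
        seq = str(rec.seq).upper()
        expected = ref[tid].length
        if len(seq) != expected:
            raise AnnotationError(f"length mismatch {tid}: {len(seq)} vs {expected}")
        seqs[tid] = seq
    new_records = []
    for rec in ref.records:
        if rec.id in seqs:
            new_records.append(replace(rec, sequence=seqs[rec.id]))
        else:
            warnings.warn(f"no sequence for {rec.id}", stacklevel=2)
            new_records.append(rec)
    return Reference(name=ref.name, records=tuple(new_records))


def write_annotation(ref: Reference, path) -> None:
    """Write a Reference back to the 4-column annotation TSV format."""
    with open(path, "w") as fh:
        fh.write("# transcript_id\tlength\tcds_start\tcds_end\n")
        for rec in ref.records:
            fh.write(f"{rec.id}\t{rec.length}\t{rec.cds_start}\t{rec.cds_end}\n")


def write_fasta(ref: Reference, path, width: int = 60) -> None:
    """Write attached sequences as FASTA (transcripts without sequence skipped)."""
    with open(path, "w") as fh:
        for rec in ref.records:
            if rec.sequence is None:
                continue
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
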