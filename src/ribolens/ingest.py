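"""Stream transcriptome SAM/BAM alignments into filtered read records and
accumulate them into the per-experiment arrays the occupancy store holds.

Filters are applied in a fixed order — unmapped, secondary/supplementary,
reverse strand, footprint length, unknown transcript, out of bounds — and
the first failing filter is the one charged in :class:`FilterStats`, so
the statistics are deterministic and each record is counted exactly once.

Footprint length is the reference span consumed by the CIGAR (sum of
M/D/N/=/X operations), not the SEQ length: soft-clipped untemplated
additions do not change the footprint, and span plus position fully
determines occupancy on the transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pysam

from ribolens.annotation import Reference

__all__ = [
    "ReadRecord",
    "LengthRange",
    "FilterStats",
    "ExperimentData",
    "SparseCoverage",
    "IngestError",
    "parse_alignments",
    "build_experiment",
]

REGIONS = ("UTR5", "CDS", "UTR3")

DEFAULT_MIN_LEN = 15
DEFAULT_MAX_LEN = 40
DEFAULT_RADIUS = 50


class IngestError(ValueError):
    """Raised for malformed alignment input."""


class ReadRecord(NamedTuple):
    """One accepted footprint: (transcript index, 5' end, length).

    ``five_prime`` is the 0-based transcript coordinate of the
    footprint's 5' end; ``length`` its reference span in nt.
    """

    transcript_index: int
    five_prime: int
    length: int


@dataclass(frozen=True)
class LengthRange:
    """Inclusive range of tracked footprint lengths."""

    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError(f"invalid length range [{self.min_len}, {self.max_len}]")

    @property
    def n_lengths(self) -> int:
        return self.max_len - self.min_len + 1

    @property
    def lengths(self) -> range:
        return range(self.min_len, self.max_len + 1)

    def __contains__(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len

    def index(self, length: int) -> int:
        """Row index of ``length`` in the per-length arrays."""
        if length not in self:
            raise ValueError(f"length {length} outside range [{self.min_len}, {self.max_len}]")
        return length - self.min_len

    def issubrange(self, other: "LengthRange") -> bool:
        return other.min_len <= self.min_len and self.max_len <= other.max_len


@dataclass
class FilterStats:
    """Counters of alignment-record fates during ingestion.

    ``accepted`` is the "total number of mapped and filtered reads" used
    for CPM normalization; the invariant
    ``total_records == accepted + sum(rejections)`` always holds.
    """

    total_records: int = 0
    unmapped: int = 0
    secondary_or_supplementary: int = 0
    reverse_strand: int = 0
    out_of_length_range: int = 0
    unknown_transcript: int = 0
    out_of_bounds: int = 0
    accepted: int = 0

    COUNTER_NAMES = (
        "total_records",
        "unmapped",
        "secondary_or_supplementary",
        "reverse_strand",
        "out_of_length_range",
        "unknown_transcript",
        "out_of_bounds",
        "accepted",
    )

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in self.COUNTER_NAMES}

    def check(self) -> None:
        rejected = (
            self.unmapped
            + self.secondary_or_supplementary
            + self.reverse_strand
            + self.out_of_length_range
            + self.unknown_transcript
            + self.out_of_bounds
        )
        if self.total_records != self.accepted + rejected:
            raise AssertionError("FilterStats counters do not sum to total_records")


def parse_alignments(
    path,
    ref: Reference,
    length_range: Optional[LengthRange] = None,
) -> tuple[list[ReadRecord], FilterStats]:
    """Parse a transcriptome-space SAM/BAM into filtered ReadRecords.

    Returns the accepted records (one per accepted alignment, in file
    order) together with the full :class:`FilterStats`. SAM POS is
    1-based in the file; ``five_prime = POS - 1`` internally. Alignments
    to reference names absent from ``ref`` are counted as
    ``unknown_transcript``, not fatal.
    """
    if length_range is None:
        length_range = LengthRange()
    stats = FilterStats()
    records: list[ReadRecord] = []
    tlen = {rec.id: rec.length for rec in ref.records}
    tidx = {rec.id: i for i, rec in enumerate(ref.records)}

    try:
        fh = pysam.AlignmentFile(str(path), check_sq=False)
    except (ValueError, OSError) as exc:
        raise IngestError(f"cannot read alignments from {path}: {exc}") from exc

    with fh:
        for aln in fh.fetch(until_eof=True):
            stats.total_records += 1
            if aln.is_unmapped:
                stats.unmapped += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                stats.secondary_or_supplementary += 1
                continue
            if aln.is_reverse:
                stats.reverse_strand += 1
                continue
            span = aln.reference_length  # sum of M/D/N/=/X
            if span is None or span not in length_range:
                stats.out_of_length_range += 1
                continue
            rname = aln.reference_name
            if rname not in tidx:
                stats.unknown_transcript += 1
                continue
            five_prime = aln.reference_start
            if five_prime < 0 or five_prime + span > tlen[rname]:
                stats.out_of_bounds += 1
                continue
            stats.accepted += 1
            records.append(ReadRecord(tidx[rname], five_prime, span))
    stats.check()
    return records, stats


@dataclass
class SparseCoverage:
    """Per-transcript 5'-end counts for one footprint length, CSR-style.

    ``indptr`` has ``n_transcripts + 1`` entries; positions within each
    transcript's row are strictly increasing and below the transcript
    length; values are positive counts.
    """

    indptr: np.ndarray
    positions: np.ndarray
    values: np.ndarray

    def row(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        """(positions, values) for transcript index ``t``."""
        lo, hi = self.indptr[t], self.indptr[t + 1]
        return self.positions[lo:hi], self.values[lo:hi]

    def dense_row(self, t: int, length: int) -> np.ndarray:
        out = np.zeros(length, dtype=np.int64)
        pos, val = self.row(t)
        out[pos] = val
        return out

    @property
    def total(self) -> int:
        return int(self.values.sum())


@dataclass
class ExperimentData:
    """All per-experiment arrays held by the occupancy store.

    region_counts : (n_lengths, n_transcripts, 3) int64, region axis
        fixed as (UTR5, CDS, UTR3), assignment by the 5' end.
    metagene_start / metagene_stop : (n_lengths, 2*radius + 1) int64,
        counts of 5' ends at each position relative to the start codon's
        first nucleotide / the stop codon's first nucleotide.
    coverage : optional dict length -> SparseCoverage of 5'-end counts.
    """

    length_range: LengthRange
    radius: int
    stats: FilterStats
    region_counts: np.ndarray
    metagene_start: np.ndarray
    metagene_stop: np.ndarray
    coverage: Optional[dict[int, SparseCoverage]] = None
    metadata: str = ""

    def validate(self, n_transcripts: int) -> None:
        nl = self.length_range.n_lengths
        w = 2 * self.radius + 1
        assert self.region_counts.shape == (nl, n_transcripts, 3)
        assert self.metagene_start.shape == (nl, w)
        assert self.metagene_stop.shape == (nl, w)


def build_experiment(
    reads: Iterable[ReadRecord],
    ref: Reference,
    length_range: Optional[LengthRange] = None,
    radius: int = DEFAULT_RADIUS,
    stats: Optional[FilterStats] = None,
    with_coverage: bool = True,
    metadata: str = "",
) -> ExperimentData:
    """Accumulate read records into region counts, metagene matrices and
    per-length sparse coverage.

    Region assignment uses the 5' end: UTR5 if ``five_prime <
    cds_start``, CDS if ``cds_start <= five_prime < cds_end``, UTR3
    otherwise. ``metagene_start[L, p]`` counts 5' ends at
    ``p = five_prime - cds_start`` for ``-radius <= p <= radius``;
    ``metagene_stop`` anchors at the stop codon's first nucleotide,
    ``cds_end - 3``. Positions outside a short transcript's window
    simply receive no counts.
    """
    if length_range is None:
        length_range = LengthRange()
    n_t = len(ref)
    nl = length_range.n_lengths
    width = 2 * radius + 1

    read_list = reads if isinstance(reads, list) else list(reads)
    if read_list:
        tarr = np.fromiter((r.transcript_index for r in read_list), dtype=np.int64, count=len(read_list))
        parr = np.fromiter((r.five_prime for r in read_list), dtype=np.int64, count=len(read_list))
        larr = np.fromiter((r.length for r in read_list), dtype=np.int64, count=len(read_list))
    else:
        tarr = parr = larr = np.empty(0, dtype=np.int64)

    if read_list:
        tlen = np.array([rec.length for rec in ref.records], dtype=np.int64)
        bad = (
            (larr < length_range.min_len)
            | (larr > length_range.max_len)
            | (parr < 0)
            | (parr + larr > tlen[tarr])
        )
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(f"read {read_list[i]} violates invariants against the reference")

    cds_start = np.array([rec.cds_start for rec in ref.records], dtype=np.int64)
    cds_end = np.array([rec.cds_end for rec in ref.records], dtype=np.int64)

    lidx = larr - length_range.min_len

    # region counts
    region = np.where(parr < cds_start[tarr], 0, np.where(parr < cds_end[tarr], 1, 2))
    region_counts = np.zeros((nl, n_t, 3), dtype=np.int64)
    np.add.at(region_counts, (lidx, tarr, region), 1)

    # metagene matrices
    metagene_start = np.zeros((nl, width), dtype=np.int64)
    metagene_stop = np.zeros((nl, width), dtype=np.int64)
    p_start = parr - cds_start[tarr]
    in_win = np.abs(p_start) <= radius
    np.add.at(metagene_start, (lidx[in_win], p_start[in_win] + radius), 1)
    p_stop = parr - (cds_end[tarr] - 3)
    in_win = np.abs(p_stop) <= radius
    np.add.at(metagene_stop, (lidx[in_win], p_stop[in_win] + radius), 1)

    coverage: Optional[dict[int, SparseCoverage]] = None
    if with_coverage:
        coverage = {}
        max_len = max((rec.length for rec in ref.records), default=1)
        for L in length_range.lengths:
            sel = larr == L
            t_sel, p_sel = tarr[sel], parr[sel]
            key = t_sel * max_len + p_sel
            uniq, counts = np.unique(key, return_counts=True)
            u_t, u_p = uniq // max_len, uniq % max_len
            indptr = np.zeros(n_t + 1, dtype=np.int64)
            np.add.at(indptr, u_t + 1, 1)
            np.cumsum(indptr, out=indptr)
            coverage[L] = SparseCoverage(
                indptr=indptr,
                positions=u_p.astype(np.int64),
                values=counts.astype(np.int64),
            )

    if stats is None:
        stats = FilterStats(total_records=len(read_list), accepted=len(read_list))
    exp = ExperimentData(
        length_range=length_range,
        radius=radius,
        stats=stats,
        region_counts=region_counts,
        metagene_start=metagene_start,
        metagene_stop=metagene_stop,
        coverage=coverage,
        metadata=metadata,
    )
    exp.validate(n_t)
    return exp
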