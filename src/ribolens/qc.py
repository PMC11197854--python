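"""Per-experiment analyses: length distributions, metagene aggregation,
region counts, P-site offset detection and correction, triplet
periodicity, per-transcript coverage, and read-depth normalization.

All operations take a length subrange and are additive over lengths:
restricting to ``[a, b]`` equals summing single-length invocations for
each length in ``[a, b]``.

P-site convention: the offset is measured from the footprint's 5' end,
``position_P = five_prime + offset`` — the dominant ribo-seq convention
(~12 nt for ~28 nt footprints in most eukaryotic datasets).

The automated offset detection rule implemented here (argmax of the
start-codon metagene column over a candidate window) is this package's
own definition of a standard heuristic: initiating ribosomes pile up
with their P-site over the start codon, so for each footprint length L
the most populated position upstream of the start codon reveals the
distance from the 5' end to the P-site.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from ribolens.annotation import Reference
from ribolens.ingest import ExperimentData, LengthRange, SparseCoverage
from ribolens.ribostore import OccupancyStore

__all__ = [
    "OffsetTable",
    "MetageneProfile",
    "PsiteCoverage",
    "length_distribution",
    "metagene",
    "region_counts",
    "detect_psite_offsets",
    "apply_offsets",
    "frame_distribution",
    "transcript_coverage",
    "normalize_cpm",
]

DEFAULT_SEARCH = (3, 18)
DEFAULT_MIN_COUNT = 10
DEFAULT_OFFSET = 12

StoreLike = Union[OccupancyStore, ExperimentData]


def _exp_data(store: StoreLike, exp: Optional[str], with_coverage: bool = False) -> ExperimentData:
    if isinstance(store, ExperimentData):
        return store
    return store.experiment_data(exp, with_coverage=with_coverage)


def _check_subrange(requested: LengthRange, stored: LengthRange) -> None:
    if not requested.issubrange(stored):
        raise ValueError(
            f"requested length range [{requested.min_len}, {requested.max_len}] is outside "
            f"the stored range [{stored.min_len}, {stored.max_len}]"
        )


def _length_slice(requested: LengthRange, stored: LengthRange) -> slice:
    lo = requested.min_len - stored.min_len
    return slice(lo, lo + requested.n_lengths)


@dataclass(frozen=True)
class OffsetEntry:
    offset: int
    confident: bool
    support: int


@dataclass
class OffsetTable:
    """Per-read-length P-site offsets with confidence flags.

    Every length in the covered range has an entry; ``offset < L`` for
    every length L. The P-site of a footprint of length L is
    ``five_prime + offset(L)``.
    """

    entries: dict[int, OffsetEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for L, e in self.entries.items():
            if not (0 <= e.offset < L):
                raise ValueError(f"offset {e.offset} invalid for length {L} (need 0 <= offset < L)")

    def offset(self, length: int) -> int:
        return self.entries[length].offset

    def __contains__(self, length: int) -> bool:
        return length in self.entries

    def lengths(self) -> list[int]:
        return sorted(self.entries)

    @property
    def all_confident(self) -> bool:
        return all(e.confident for e in self.entries.values())

    @classmethod
    def from_dict(cls, offsets: dict[int, int], confident: bool = True) -> "OffsetTable":
        """Build a manual table from a plain length -> offset mapping."""
        return cls({L: OffsetEntry(int(o), confident, 0) for L, o in offsets.items()})

    def as_dict(self) -> dict[int, int]:
        return {L: e.offset for L, e in sorted(self.entries.items())}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"length": L, "offset": e.offset, "confident": e.confident, "support": e.support}
            for L, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["length", "offset", "confident", "support"])

    def to_tsv(self, path) -> None:
        """Write the 2-column length -> offset TSV (manual-offset format)."""
        with open(path, "w") as fh:
            fh.write("# length\toffset\n")
            for L, e in sorted(self.entries.items()):
                fh.write(f"{L}\t{e.offset}\n")

    @classmethod
    def from_tsv(cls, path) -> "OffsetTable":
        entries: dict[int, OffsetEntry] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"offset TSV: expected 2 columns, got {line!r}")
                L, off = int(parts[0]), int(parts[1])
                entries[L] = OffsetEntry(off, True, 0)
        if not entries:
            raise ValueError(f"{path}: no offsets")
        return cls(entries)


@dataclass
class MetageneProfile:
    """Aggregated occupancy around the start or stop codon.

    ``positions`` run from -radius to +radius, 0 being the first
    nucleotide of the start codon (site='start') or of the stop codon
    (site='stop'); ``values`` are raw counts or CPM.
    """

    site: str
    radius: int
    positions: np.ndarray
    values: np.ndarray
    lengths_used: LengthRange
    normalized: bool = False

    def value_at(self, p: int) -> float:
        return self.values[p + self.radius]


def length_distribution(
    store: StoreLike, exp: Optional[str] = None, length_range: Optional[LengthRange] = None
) -> pd.DataFrame:
    """Footprint counts and fractions per length over a subrange.

    Returns a DataFrame indexed by length with columns ``count`` and
    ``fraction``; fractions sum to 1 when the total is positive, and are
    all zero (with a warning) for an empty experiment.
    """
    data = _exp_data(store, exp)
    rng = length_range or data.length_range
    _check_subrange(rng, data.length_range)
    counts = data.region_counts[_length_slice(rng, data.length_range)].sum(axis=(1, 2))
    total = counts.sum()
    if total > 0:
        fractions = counts / total
    else:
        warnings.warn("length_distribution: experiment has no reads in range", stacklevel=2)
        fractions = np.zeros_like(counts, dtype=float)
    return pd.DataFrame(
        {"count": counts, "fraction": fractions},
        index=pd.Index(list(rng.lengths), name="length"),
    )


def metagene(
    store: StoreLike,
    exp: Optional[str] = None,
    site: str = "start",
    length_range: Optional[LengthRange] = None,
    normalize: bool = False,
) -> MetageneProfile:
    """Aggregate the per-length metagene matrix over a length subrange.

    ``values[p]`` is the number of footprint 5' ends at position ``p``
    relative to the anchor, summed over lengths in range; with
    ``normalize=True`` values are scaled to counts per million mapped
    and filtered reads.
    """
    if site not in ("start", "stop"):
        raise ValueError(f"site must be 'start' or 'stop', got {site!r}")
    data = _exp_data(store, exp)
    rng = length_range or data.length_range
    _check_subrange(rng, data.length_range)
    matrix = data.metagene_start if site == "start" else data.metagene_stop
    values = matrix[_length_slice(rng, data.length_range)].sum(axis=0)
    if normalize:
        values = normalize_cpm(values, data.stats.accepted)
    radius = data.radius
    return MetageneProfile(
        site=site,
        radius=radius,
        positions=np.arange(-radius, radius + 1),
        values=values,
        lengths_used=rng,
        normalized=normalize,
    )


def region_counts(
    store: StoreLike,
    exp: Optional[str] = None,
    length_range: Optional[LengthRange] = None,
    per_transcript: bool = False,
):
    """Footprint totals and percentages per region (UTR5, CDS, UTR3).

    Returns a DataFrame indexed by region with columns ``count`` and
    ``percent``; with ``per_transcript=True`` also returns the
    (transcripts, 3) per-transcript breakdown summed over the range.
    """
    data = _exp_data(store, exp)
    rng = length_range or data.length_range
    _check_subrange(rng, data.length_range)
    sub = data.region_counts[_length_slice(rng, data.length_range)]
    by_transcript = sub.sum(axis=0)  # (T, 3)
    totals = by_transcript.sum(axis=0)
    grand = totals.sum()
    if grand > 0:
        percents = 100.0 * totals / grand
    else:
        warnings.warn("region_counts: experiment has no reads in range", stacklevel=2)
        percents = np.zeros(3)
    frame = pd.DataFrame(
        {"count": totals, "percent": percents},
        index=pd.Index(["UTR5", "CDS", "UTR3"], name="region"),
    )
    if per_transcript:
        return frame, by_transcript
    return frame


def detect_psite_offsets(
    store: StoreLike,
    exp: Optional[str] = None,
    search: tuple[int, int] = DEFAULT_SEARCH,
    min_count: int = DEFAULT_MIN_COUNT,
    default_offset: int = DEFAULT_OFFSET,
) -> OffsetTable:
    """Automatically detect per-length P-site offsets from the start metagene.

    For each footprint length L, candidate offsets are
    ``search ∩ [1, L-1]``; the score of candidate o is the start-codon
    metagene count at position -o (a 5' end o nucleotides upstream of
    the start codon places the P-site on the start codon). The offset is
    the argmax, ties broken toward the smallest offset. When the total
    support over candidates is below ``min_count`` the call falls back
    to ``default_offset`` (clamped below L) with ``confident=False``.
    """
    data = _exp_data(store, exp)
    matrix = data.metagene_start
    radius = data.radius
    lo, hi = search
    entries: dict[int, OffsetEntry] = {}
    for L in data.length_range.lengths:
        row = matrix[data.length_range.index(L)]
        cand = [o for o in range(max(lo, 1), min(hi, L - 1) + 1) if o <= radius]
        if not cand:
            entries[L] = OffsetEntry(min(default_offset, L - 1), False, 0)
            continue
        scores = np.array([row[radius - o] for o in cand], dtype=np.int64)
        support = int(scores.sum())
        if support < min_count:
            entries[L] = OffsetEntry(min(default_offset, L - 1), False, support)
        else:
            best = cand[int(np.argmax(scores))]  # argmax takes first max: smallest offset
            entries[L] = OffsetEntry(best, True, support)
    return OffsetTable(entries)


@dataclass
class PsiteCoverage:
    """P-site-corrected per-transcript coverage plus the clipped tally.

    ``vectors[t][x]`` is the P-site count at position x of transcript t;
    ``clipped`` counts footprints whose shifted position fell beyond the
    transcript end and were dropped. Mass conservation:
    input coverage total == total + clipped.
    """

    vectors: list[np.ndarray]
    clipped: int

    @property
    def total(self) -> int:
        return int(sum(v.sum() for v in self.vectors))


def apply_offsets(
    store: StoreLike,
    exp: Optional[str] = None,
    offsets: Optional[OffsetTable] = None,
    length_range: Optional[LengthRange] = None,
    ref: Optional[Reference] = None,
) -> PsiteCoverage:
    """Shift stored 5'-end coverage by per-length offsets to P-site coverage.

    For every length L in range, coverage at (t, x) accumulates into
    position ``x + offset(L)`` of transcript t; shifted positions at or
    beyond the transcript length are dropped and counted in ``clipped``.
    Requires a store built with coverage.
    """
    if offsets is None:
        raise ValueError("apply_offsets requires an OffsetTable")
    data = _exp_data(store, exp, with_coverage=True)
    if data.coverage is None:
        raise ValueError(
            "store was built without coverage; re-ingest with coverage enabled to apply offsets"
        )
    if ref is None:
        if isinstance(store, OccupancyStore):
            ref = store.reference
        else:
            raise ValueError("apply_offsets on bare ExperimentData requires ref=")
    rng = length_range or data.length_range
    _check_subrange(rng, data.length_range)
    tlens = [rec.length for rec in ref.records]
    vectors = [np.zeros(n, dtype=np.int64) for n in tlens]
    clipped = 0
    for L in rng.lengths:
        if L not in data.coverage:
            continue
        if L not in offsets:
            raise ValueError(f"offset table has no entry for length {L}")
        off = offsets.offset(L)
        sc = data.coverage[L]
        for t in range(len(tlens)):
            pos, val = sc.row(t)
            if pos.size == 0:
                continue
            shifted = pos + off
            ok = shifted < tlens[t]
            clipped += int(val[~ok].sum())
            np.add.at(vectors[t], shifted[ok], val[ok])
    return PsiteCoverage(vectors=vectors, clipped=clipped)


def frame_distribution(psite_coverage: PsiteCoverage, ref: Reference, include_stop: bool = True) -> np.ndarray:
    """Triplet-periodicity fractions over reading frames (0, 1, 2).

    Accumulates P-site mass at CDS positions x by ``(x - cds_start) mod
    3`` over all transcripts; frame 0 is the annotated reading frame.
    ``include_stop=False`` excludes the final codon's interval. Returns
    fractions summing to 1, or zeros (with a warning) if there is no CDS
    mass.
    """
    mass = np.zeros(3, dtype=np.int64)
    for t, rec in enumerate(ref.records):
        end = rec.cds_end if include_stop else rec.cds_end - 3
        vec = psite_coverage.vectors[t][rec.cds_start : end]
        if vec.size == 0:
            continue
        frames = np.arange(vec.size) % 3
        np.add.at(mass, frames, vec)
    total = mass.sum()
    if total == 0:
        warnings.warn("frame_distribution: zero CDS mass", stacklevel=2)
        return np.zeros(3)
    return mass / total


def transcript_coverage(
    store: StoreLike,
    exp: Optional[str] = None,
    transcript_id: str = "",
    length_range: Optional[LengthRange] = None,
    offsets: Optional[OffsetTable] = None,
    ref: Optional[Reference] = None,
):
    """Position-indexed coverage for one transcript, optionally P-site shifted.

    Without offsets: summed 5'-end counts per position over lengths in
    range. With offsets: P-site-shifted coverage (same semantics as
    :func:`apply_offsets`, restricted to this transcript). Returns
    ``(vector, sequence_or_None)``; the sequence track is present when
    the reference carries sequences.
    """
    data = _exp_data(store, exp, with_coverage=True)
    if ref is None:
        if isinstance(store, OccupancyStore):
            ref = store.reference
        else:
            raise ValueError("transcript_coverage on bare ExperimentData requires ref=")
    if transcript_id not in ref:
        near = difflib.get_close_matches(transcript_id, ref.ids, n=3)
        hint = f"; did you mean {', '.join(near)}?" if near else ""
        raise KeyError(f"unknown transcript {transcript_id!r}{hint}")
    if data.coverage is None:
        raise ValueError(
            "store was built without coverage; re-ingest with coverage enabled for coverage plots"
        )
    t = ref.index_of(transcript_id)
    rec = ref[transcript_id]
    rng = length_range or data.length_range
    _check_subrange(rng, data.length_range)
    vec = np.zeros(rec.length, dtype=np.int64)
    for L in rng.lengths:
        if L not in data.coverage:
            continue
        pos, val = data.coverage[L].row(t)
        if pos.size == 0:
            continue
        if offsets is None:
            np.add.at(vec, pos, val)
        else:
            shifted = pos + offsets.offset(L)
            ok = shifted < rec.length
            np.add.at(vec, shifted[ok], val[ok])
    return vec, rec.sequence


def normalize_cpm(values, accepted_total: int) -> np.ndarray:
    """Scale a count vector to counts per million mapped-and-filtered reads."""
    if accepted_total <= 0:
        raise ValueError("cannot normalize empty experiment (accepted total is 0)")
    return np.asarray(values, dtype=float) * (1e6 / accepted_total)
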