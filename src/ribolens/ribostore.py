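"""Versioned hierarchical HDF5 container for ribosome occupancy data.

Once built, analyses read this store and never touch SAM again. Schema
(this package's own dialect, documented in docs/methods.md)::

    /                       attrs: format_version, region_order
    /reference/names        (T,) variable-length UTF-8
    /reference/lengths      (T,) int64
    /reference/cds_start    (T,) int64
    /reference/cds_end      (T,) int64       attrs: name, digest
    /experiments/<name>/region_counts    (L, T, 3) int64
    /experiments/<name>/metagene_start   (L, 2r+1) int64
    /experiments/<name>/metagene_stop    (L, 2r+1) int64
    /experiments/<name>/coverage/len_<L>/{indptr,positions,values}  (optional)
        experiment attrs: min_len, max_len, radius, metadata,
        stats_* (one per FilterStats counter)

All integer datasets are stored as 64-bit with shuffle + deflate.
Opening a store checks shapes cheaply; ``deep_validate=True`` also
checks coverage monotonicity and non-negativity. Coverage datasets are
only read when explicitly requested, so opening is fast regardless of
store size.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from ribolens.annotation import Reference, TranscriptRecord
from ribolens.ingest import REGIONS, ExperimentData, FilterStats, LengthRange, SparseCoverage

__all__ = ["FORMAT_VERSION", "StoreError", "OccupancyStore", "write_store", "read_store", "merge_stores"]

FORMAT_VERSION = "1.0"
_SUPPORTED_MAJOR = 1

_DSET_KW = dict(compression="gzip", compression_opts=4, shuffle=True)


class StoreError(ValueError):
    """Raised for schema, version or integrity problems in a store file."""


def _write_experiment(grp: h5py.Group, exp: ExperimentData) -> None:
    grp.attrs["min_len"] = exp.length_range.min_len
    grp.attrs["max_len"] = exp.length_range.max_len
    grp.attrs["radius"] = exp.radius
    grp.attrs["metadata"] = exp.metadata
    for key, val in exp.stats.as_dict().items():
        grp.attrs[f"stats_{key}"] = val
    grp.create_dataset("region_counts", data=exp.region_counts.astype(np.int64), **_DSET_KW)
    grp.create_dataset("metagene_start", data=exp.metagene_start.astype(np.int64), **_DSET_KW)
    grp.create_dataset("metagene_stop", data=exp.metagene_stop.astype(np.int64), **_DSET_KW)
    if exp.coverage is not None:
        cov = grp.create_group("coverage")
        for L, sc in exp.coverage.items():
            lg = cov.create_group(f"len_{L}")
            lg.create_dataset("indptr", data=sc.indptr.astype(np.int64), **_DSET_KW)
            lg.create_dataset("positions", data=sc.positions.astype(np.int64), **_DSET_KW)
            lg.create_dataset("values", data=sc.values.astype(np.int64), **_DSET_KW)


def write_store(
    path,
    ref: Reference,
    experiments: dict[str, ExperimentData],
    metadata: str = "",
    overwrite: bool = False,
) -> None:
    """Write a Reference plus named experiments to an HDF5 store.

    The file is created atomically: written to a temporary sibling and
    renamed into place, so a killed write leaves no partial file at the
    target path. Experiment names must be unique, non-empty and free of
    ``/``.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise StoreError(f"{path} exists; pass overwrite=True to replace it")
    names = list(experiments)
    for name in names:
        if not name or "/" in name:
            raise StoreError(f"invalid experiment name {name!r}")
    if len(set(names)) != len(names):
        raise StoreError("duplicate experiment names")

    fd, tmp = tempfile.mkstemp(prefix=path.name + ".", suffix=".tmp", dir=path.parent or ".")
    os.close(fd)
    try:
        with h5py.File(tmp, "w", track_order=True) as f:
            f.attrs["format_version"] = FORMAT_VERSION
            f.attrs["region_order"] = list(REGIONS)
            f.attrs["metadata"] = metadata
            rg = f.create_group("reference")
            rg.attrs["name"] = ref.name
            rg.attrs["digest"] = ref.digest
            str_dt = h5py.string_dtype(encoding="utf-8")
            rg.create_dataset("names", data=np.array(ref.ids, dtype=object), dtype=str_dt, **_DSET_KW)
            rg.create_dataset(
                "lengths", data=np.array([r.length for r in ref.records], dtype=np.int64), **_DSET_KW
            )
            rg.create_dataset(
                "cds_start", data=np.array([r.cds_start for r in ref.records], dtype=np.int64), **_DSET_KW
            )
            rg.create_dataset(
                "cds_end", data=np.array([r.cds_end for r in ref.records], dtype=np.int64), **_DSET_KW
            )
            eg = f.create_group("experiments", track_order=True)
            for name, exp in experiments.items():
                _write_experiment(eg.create_group(name, track_order=True), exp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


class OccupancyStore:
    """Lazy read handle over an occupancy store file.

    Reference tables and per-experiment attributes are available
    immediately; array datasets are read from disk only when the
    corresponding accessor is called. Use as a context manager or call
    :meth:`close` when done.
    """

    def __init__(self, path, deep_validate: bool = False):
        self.path = Path(path)
        try:
            self._f = h5py.File(self.path, "r")
        except OSError as exc:
            raise StoreError(f"cannot open {self.path}: {exc}") from exc
        version = self._f.attrs.get("format_version")
        if version is None:
            self._f.close()
            raise StoreError(f"{self.path}: not an occupancy store (no format_version)")
        major = int(str(version).split(".")[0])
        if major > _SUPPORTED_MAJOR:
            self._f.close()
            raise StoreError(f"unsupported format version {version} (reader supports <= {_SUPPORTED_MAJOR}.x)")
        self.format_version = str(version)
        self._check_schema(deep_validate)

    # -- lifecycle ---------------------------------------------------
    def close(self) -> None:
        self._f.close()

    def __enter__(self) -> "OccupancyStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- schema & validation -----------------------------------------
    def _check_schema(self, deep: bool) -> None:
        for needed in ("reference/names", "reference/lengths", "reference/cds_start", "reference/cds_end"):
            if needed not in self._f:
                raise StoreError(f"{self.path}: missing mandatory dataset /{needed}")
        if "experiments" not in self._f:
            raise StoreError(f"{self.path}: missing mandatory group /experiments")
        n_t = self._f["reference/names"].shape[0]
        for name in self._f["experiments"]:
            grp = self._f["experiments"][name]
            for dset in ("region_counts", "metagene_start", "metagene_stop"):
                if dset not in grp:
                    raise StoreError(f"{self.path}: missing dataset /experiments/{name}/{dset}")
            nl = int(grp.attrs["max_len"]) - int(grp.attrs["min_len"]) + 1
            w = 2 * int(grp.attrs["radius"]) + 1
            if grp["region_counts"].shape != (nl, n_t, 3):
                raise StoreError(f"{self.path}: /experiments/{name}/region_counts shape mismatch")
            for dset in ("metagene_start", "metagene_stop"):
                if grp[dset].shape != (nl, w):
                    raise StoreError(f"{self.path}: /experiments/{name}/{dset} shape mismatch")
            if deep:
                self._deep_validate_experiment(name)

    def _deep_validate_experiment(self, name: str) -> None:
        grp = self._f["experiments"][name]
        tlen = self._f["reference/lengths"][:]
        for dset in ("region_counts", "metagene_start", "metagene_stop"):
            if (grp[dset][:] < 0).any():
                raise StoreError(f"{self.path}: negative counts in /experiments/{name}/{dset}")
        if "coverage" in grp:
            for lname in grp["coverage"]:
                lg = grp["coverage"][lname]
                indptr = lg["indptr"][:]
                pos = lg["positions"][:]
                val = lg["values"][:]
                if (np.diff(indptr) < 0).any():
                    raise StoreError(f"{self.path}: non-monotone indptr in {name}/{lname}")
                if (val < 0).any():
                    raise StoreError(f"{self.path}: negative coverage values in {name}/{lname}")
                for t in range(len(indptr) - 1):
                    row = pos[indptr[t] : indptr[t + 1]]
                    if row.size and ((np.diff(row) <= 0).any() or row[-1] >= tlen[t]):
                        raise StoreError(
                            f"{self.path}: bad positions for transcript {t} in {name}/{lname}"
                        )

    # -- reference ---------------------------------------------------
    @property
    def reference(self) -> Reference:
        rg = self._f["reference"]
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in rg["names"][:]]
        lengths = rg["lengths"][:]
        cs, ce = rg["cds_start"][:], rg["cds_end"][:]
        records = tuple(
            TranscriptRecord(names[i], int(lengths[i]), int(cs[i]), int(ce[i]))
            for i in range(len(names))
        )
        return Reference(name=str(rg.attrs.get("name", "reference")), records=records)

    @property
    def reference_digest(self) -> str:
        return str(self._f["reference"].attrs["digest"])

    @property
    def region_order(self) -> tuple[str, ...]:
        return tuple(str(r) for r in self._f.attrs["region_order"])

    # -- experiments -------------------------------------------------
    @property
    def experiment_names(self) -> list[str]:
        return list(self._f["experiments"])

    def _exp_group(self, name: str) -> h5py.Group:
        eg = self._f["experiments"]
        if name not in eg:
            raise StoreError(
                f"no experiment {name!r} in {self.path}; available: {', '.join(eg) or '(none)'}"
            )
        return eg[name]

    def length_range(self, name: str) -> LengthRange:
        grp = self._exp_group(name)
        return LengthRange(int(grp.attrs["min_len"]), int(grp.attrs["max_len"]))

    def radius(self, name: str) -> int:
        return int(self._exp_group(name).attrs["radius"])

    def stats(self, name: str) -> FilterStats:
        grp = self._exp_group(name)
        return FilterStats(**{k: int(grp.attrs[f"stats_{k}"]) for k in FilterStats.COUNTER_NAMES})

    def metadata(self, name: str) -> str:
        return str(self._exp_group(name).attrs.get("metadata", ""))

    def region_counts(self, name: str) -> np.ndarray:
        return self._exp_group(name)["region_counts"][:]

    def metagene_matrix(self, name: str, site: str) -> np.ndarray:
        if site not in ("start", "stop"):
            raise ValueError(f"site must be 'start' or 'stop', got {site!r}")
        return self._exp_group(name)[f"metagene_{site}"][:]

    def has_coverage(self, name: str) -> bool:
        return "coverage" in self._exp_group(name)

    def _load_coverage(self, name: str) -> dict[int, SparseCoverage]:
        grp = self._exp_group(name)
        if "coverage" not in grp:
            raise StoreError(
                f"experiment {name!r} was stored without coverage; re-ingest with coverage enabled"
            )
        out: dict[int, SparseCoverage] = {}
        for lname in grp["coverage"]:
            L = int(lname.removeprefix("len_"))
            lg = grp["coverage"][lname]
            out[L] = SparseCoverage(
                indptr=lg["indptr"][:], positions=lg["positions"][:], values=lg["values"][:]
            )
        return out

    def coverage(self, name: str) -> dict[int, SparseCoverage]:
        """Load all per-length sparse coverage for an experiment."""
        return self._load_coverage(name)

    def experiment_data(self, name: str, with_coverage: bool = True) -> ExperimentData:
        """Materialize a full :class:`ExperimentData` from the store."""
        cov = None
        if with_coverage and self.has_coverage(name):
            cov = self._load_coverage(name)
        return ExperimentData(
            length_range=self.length_range(name),
            radius=self.radius(name),
            stats=self.stats(name),
            region_counts=self.region_counts(name),
            metagene_start=self.metagene_matrix(name, "start"),
            metagene_stop=self.metagene_matrix(name, "stop"),
            coverage=cov,
            metadata=self.metadata(name),
        )

    def summary(self) -> dict:
        """JSON-serializable description of the store (for `ribolens inspect`)."""
        out = {
            "path": str(self.path),
            "format_version": self.format_version,
            "region_order": list(self.region_order),
            "reference": {
                "name": str(self._f["reference"].attrs.get("name", "")),
                "digest": self.reference_digest,
                "n_transcripts": int(self._f["reference/names"].shape[0]),
            },
            "experiments": {},
        }
        for name in self.experiment_names:
            rng = self.length_range(name)
            out["experiments"][name] = {
                "length_range": [rng.min_len, rng.max_len],
                "radius": self.radius(name),
                "has_coverage": self.has_coverage(name),
                "stats": self.stats(name).as_dict(),
            }
        return out


def read_store(path, deep_validate: bool = False) -> OccupancyStore:
    """Open an occupancy store for reading (lazy handle)."""
    return OccupancyStore(path, deep_validate=deep_validate)


def merge_stores(paths: list, out, overwrite: bool = False) -> None:
    """Merge experiments from several stores sharing one reference.

    All input stores must have an identical reference digest; experiment
    name collisions are an error. The output holds the union of
    experiments over the shared reference.
    """
    if not paths:
        raise StoreError("no input stores")
    stores = [read_store(p) for p in paths]
    try:
        digest0 = stores[0].reference_digest
        for st in stores[1:]:
            if st.reference_digest != digest0:
                raise StoreError(
                    f"reference digest mismatch between {stores[0].path} and {st.path}"
                )
        seen: dict[str, Path] = {}
        merged: dict[str, ExperimentData] = {}
        for st in stores:
            for name in st.experiment_names:
                if name in seen:
                    raise StoreError(
                        f"duplicate experiment name {name!r} (in {seen[name]} and {st.path})"
                    )
                seen[name] = st.path
                merged[name] = st.experiment_data(name)
        ref = stores[0].reference
    finally:
        for st in stores:
            st.close()
    write_store(out, ref, merged, overwrite=overwrite)
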