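"""Cross-experiment comparison: gene-level CDS quantification, Spearman
correlation adjacency matrix, and pairwise scatter data.

"Gene-level" is implemented as transcript-level over the reference
(ribo-seq references conventionally carry one isoform per gene); an
optional transcript-to-gene map collapses rows by summation.
Quantification is fixed to the CDS region (the translation signal) over
a selected footprint length range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ribolens.ingest import LengthRange
from ribolens.ribostore import OccupancyStore

__all__ = ["GeneCountMatrix", "CorrelationMatrix", "gene_counts", "spearman_matrix", "scatter_pairs"]

_CDS = 1  # region axis order (UTR5, CDS, UTR3)


@dataclass
class GeneCountMatrix:
    """Transcripts-by-experiments matrix of CDS footprint counts.

    ``counts`` is a DataFrame with transcript ids as the row index and
    experiment names as columns; all entries are non-negative integers
    counted over a shared length range against one reference (recorded
    by its digest).
    """

    counts: pd.DataFrame
    length_range: LengthRange
    reference_digest: str

    @property
    def experiments(self) -> list[str]:
        return list(self.counts.columns)

    def collapse_by_gene(self, gene_map: dict[str, str]) -> "GeneCountMatrix":
        """Sum rows by a transcript -> gene mapping (unmapped rows kept as-is)."""
        genes = [gene_map.get(t, t) for t in self.counts.index]
        collapsed = self.counts.groupby(pd.Index(genes, name="gene"), sort=False).sum()
        return GeneCountMatrix(collapsed, self.length_range, self.reference_digest)


@dataclass
class CorrelationMatrix:
    """Experiments-by-experiments Spearman rho matrix.

    Symmetric; diagonal 1 for non-constant columns; undefined entries
    (a zero-variance column involved) are NaN, never silently 0. Tie
    handling: average ranks.
    """

    rho: pd.DataFrame
    method: str = "spearman(average-rank)"

    @property
    def experiments(self) -> list[str]:
        return list(self.rho.columns)


def gene_counts(
    stores: Union[OccupancyStore, Sequence[OccupancyStore]],
    exps: Sequence[str],
    length_range: Optional[LengthRange] = None,
) -> GeneCountMatrix:
    """Per-transcript CDS footprint counts for the selected experiments.

    ``entry[t, e]`` is the sum over lengths in range of the CDS region
    counts of experiment e. Experiments may come from one store or a
    list of stores (one per experiment); all stores must share the same
    reference digest, and the range must be within every experiment's
    stored range.
    """
    if not exps:
        raise ValueError("need at least one experiment")
    if isinstance(stores, OccupancyStore):
        store_list = [stores] * len(exps)
    else:
        store_list = list(stores)
        if len(store_list) == 1:
            store_list = store_list * len(exps)
        if len(store_list) != len(exps):
            raise ValueError("number of stores must be 1 or match the number of experiments")

    digest = store_list[0].reference_digest
    for st in store_list[1:]:
        if st.reference_digest != digest:
            raise ValueError(
                f"reference digest mismatch between {store_list[0].path} and {st.path}; "
                "experiments must share one reference to be compared"
            )

    stored_ranges = [st.length_range(e) for st, e in zip(store_list, exps)]
    if length_range is None:
        lo = max(r.min_len for r in stored_ranges)
        hi = min(r.max_len for r in stored_ranges)
        if lo > hi:
            raise ValueError("experiments have no common stored length range")
        length_range = LengthRange(lo, hi)
    for e, r in zip(exps, stored_ranges):
        if not length_range.issubrange(r):
            raise ValueError(
                f"length range [{length_range.min_len}, {length_range.max_len}] outside the "
                f"stored range [{r.min_len}, {r.max_len}] of experiment {e!r}"
            )

    ids = store_list[0].reference.ids
    columns = {}
    for st, e, stored in zip(store_list, exps, stored_ranges):
        rc = st.region_counts(e)
        lo = length_range.min_len - stored.min_len
        col = rc[lo : lo + length_range.n_lengths, :, _CDS].sum(axis=0)
        if col.sum() == 0:
            warnings.warn(f"experiment {e!r}: no CDS reads in the selected length range", stacklevel=2)
        columns[e] = col
    frame = pd.DataFrame(columns, index=pd.Index(ids, name="transcript"))
    return GeneCountMatrix(frame, length_range, digest)


def spearman_matrix(m: GeneCountMatrix) -> CorrelationMatrix:
    """Spearman rho between every pair of experiments.

    Average-rank transform per column, then Pearson correlation on the
    ranks. Columns with zero variance produce NaN entries plus a
    warning. Requires at least 2 experiments and 3 transcripts.
    """
    frame = m.counts
    if frame.shape[1] < 2:
        raise ValueError("spearman_matrix needs at least 2 experiments")
    if frame.shape[0] < 3:
        raise ValueError("spearman_matrix needs at least 3 transcripts (correlation meaningless)")
    names = list(frame.columns)
    ranks = np.column_stack([rankdata(frame[c].to_numpy(), method="average") for c in names])
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    constant = norms == 0
    if constant.any():
        warnings.warn(
            f"zero-variance counts in experiment(s) {[n for n, c in zip(names, constant) if c]}; "
            "their correlations are undefined (NaN)",
            stacklevel=2,
        )
    n = len(names)
    rho = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            if constant[i] or constant[j]:
                continue
            r = float(centered[:, i] @ centered[:, j] / (norms[i] * norms[j]))
            rho[i, j] = rho[j, i] = r
    for i in range(n):
        if not constant[i]:
            rho[i, i] = 1.0
    return CorrelationMatrix(pd.DataFrame(rho, index=names, columns=names))


def scatter_pairs(
    m: GeneCountMatrix, exp_a: str, exp_b: str, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, float]:
    """Per-gene log10 scatter data for two experiments plus their rho.

    Returns a DataFrame with one row per transcript and columns
    ``log10(count_a + pseudocount)`` / same for b, and the Spearman rho
    computed on the raw counts (identical to rho on the transformed
    values, since log10(x + c) is strictly monotone).
    """
    if exp_a == exp_b:
        raise ValueError(f"degenerate comparison: {exp_a!r} vs itself")
    for e in (exp_a, exp_b):
        if e not in m.counts.columns:
            raise KeyError(f"unknown experiment {e!r}; available: {', '.join(m.counts.columns)}")
    a = m.counts[exp_a].to_numpy(dtype=float)
    b = m.counts[exp_b].to_numpy(dtype=float)
    ra = rankdata(a, method="average")
    rb = rankdata(b, method="average")
    ca, cb = ra - ra.mean(), rb - rb.mean()
    denom = np.sqrt((ca**2).sum() * (cb**2).sum())
    rho = float(ca @ cb / denom) if denom > 0 else float("nan")
    frame = pd.DataFrame(
        {
            exp_a: np.log10(a + pseudocount),
            exp_b: np.log10(b + pseudocount),
        },
        index=m.counts.index,
    )
    return frame, rho
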