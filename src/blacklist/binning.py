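"""Sliding-window grid and per-sample bin metrics.

Each chromosome is tiled with overlapping windows (default 1 kb windows
whose consecutive starts are 900 bp apart, i.e. adjacent windows share
100 bp). Every sample is scored per window with two quantities:

* depth  — reads per uniquely mappable base in the window,
* multi  — multimapping reads in the window per million mapped reads
           in the sample.

Reads are assigned to a window by their leftmost position, so a read can
be counted in every window that covers its start. Reads on excluded
chromosomes (mitochondrial by default) are dropped before any counting,
including from the per-million denominator.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import ALIGNMENT_COLUMNS, AlignmentRecord, GenomicInterval
from .mappability import MappabilityTrack

logger = logging.getLogger("blacklist")

DEFAULT_BIN_SIZE = 1000
DEFAULT_STEP = 900
DEFAULT_EXCLUDE_CHROMS = ("chrM", "MT")


class EmptySampleError(ValueError):
    """A sample retained zero reads after chromosome exclusion."""


@dataclass
class BinGrid:
    """Ordered overlapping windows covering every chromosome.

    Stored as flat arrays over all bins: ``chrom_index`` indexes into
    ``chroms``; ``starts``/``ends`` are window coordinates. The final
    window of a chromosome is clipped to the chromosome end.
    """

    bin_size: int
    step: int
    chroms: list[str]
    chrom_lengths: dict[str, int]
    chrom_index: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def chrom_slice(self, chrom: str) -> slice:
        ci = self.chroms.index(chrom)
        idx = np.flatnonzero(self.chrom_index == ci)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def intervals(self) -> Iterator[GenomicInterval]:
        for ci, s, e in zip(self.chrom_index, self.starts, self.ends):
            yield GenomicInterval(self.chroms[int(ci)], int(s), int(e))

    def same_chrom_as_prev(self) -> np.ndarray:
        """Boolean over bins 1..n-1: bin i is on the same chromosome as i-1."""
        return self.chrom_index[1:] == self.chrom_index[:-1]


def make_grid(
    chrom_lengths: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    step: int = DEFAULT_STEP,
) -> BinGrid:
    """Window starts at 0, step, 2*step, ... while start < chromosome length;
    each window end is min(start + bin_size, length)."""
    if bin_size <= 0 or step <= 0:
        raise ValueError(f"bin_size and step must be positive, got {bin_size}, {step}")
    if step > bin_size:
        raise ValueError(f"step ({step}) may not exceed bin_size ({bin_size})")
    chroms = list(chrom_lengths)
    ci_parts, s_parts, e_parts = [], [], []
    for i, chrom in enumerate(chroms):
        length = int(chrom_lengths[chrom])
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        ci_parts.append(np.full(len(starts), i, dtype=np.int32))
        s_parts.append(starts)
        e_parts.append(ends)
    return BinGrid(
        bin_size=bin_size,
        step=step,
        chroms=chroms,
        chrom_lengths={c: int(v) for c, v in chrom_lengths.items()},
        chrom_index=np.concatenate(ci_parts),
        starts=np.concatenate(s_parts),
        ends=np.concatenate(e_parts),
    )


def bin_mappable_counts(grid: BinGrid, track: MappabilityTrack) -> np.ndarray:
    """Uniquely mappable start positions per window."""
    out = np.zeros(grid.n_bins, dtype=np.int64)
    for chrom in grid.chroms:
        sl = grid.chrom_slice(chrom)
        cs = track._cumsum(chrom)
        out[sl] = cs[grid.ends[sl]] - cs[grid.starts[sl]]
    return out


def _as_table(alignments) -> pd.DataFrame:
    if isinstance(alignments, pd.DataFrame):
        return alignments
    records = list(alignments)
    if records and not isinstance(records[0], AlignmentRecord):
        raise TypeError("alignments must be a DataFrame or AlignmentRecord iterable")
    return pd.DataFrame(records, columns=ALIGNMENT_COLUMNS)


@dataclass
class SampleBinCounts:
    """Raw and normalized per-bin quantities for one sample."""

    reads: np.ndarray  # read starts per bin
    multi_reads: np.ndarray  # multimapping read starts per bin
    depth: np.ndarray  # reads per mappable base (0 where unmappable)
    multi: np.ndarray  # multimapping reads per million mapped reads
    n_retained: int
    n_excluded: int


def bin_sample(
    alignments,
    grid: BinGrid,
    track: MappabilityTrack,
    exclude_chroms: Sequence[str] = DEFAULT_EXCLUDE_CHROMS,
    *,
    mappable: np.ndarray | None = None,
    include_multimapping_in_depth: bool = True,
) -> SampleBinCounts:
    """Score one sample's reads over the grid.

    Raises :class:`EmptySampleError` when no reads survive chromosome
    exclusion; callers building a panel should catch it and drop the sample.
    """
    table = _as_table(alignments)
    if mappable is None:
        mappable = bin_mappable_counts(grid, track)

    excluded_mask = table["chrom"].isin(set(exclude_chroms)) if len(table) else None
    if excluded_mask is not None:
        n_excluded = int(excluded_mask.sum())
        table = table[~excluded_mask]
    else:
        n_excluded = 0
    # reads on chromosomes outside the grid are also dropped (not counted
    # in the per-million denominator, which is defined over the binnable genome)
    if len(table):
        on_grid = table["chrom"].isin(grid.chroms)
        off = len(table) - int(on_grid.sum())
        if off:
            logger.warning("dropping %d reads on chromosomes absent from the grid", off)
            table = table[on_grid]
    total = len(table)
    if total == 0:
        raise EmptySampleError("sample has no reads after chromosome exclusion")

    reads = np.zeros(grid.n_bins, dtype=np.int64)
    multi_reads = np.zeros(grid.n_bins, dtype=np.int64)
    for chrom, sub in table.groupby("chrom", sort=False):
        sl = grid.chrom_slice(chrom)
        starts = np.sort(sub["start"].to_numpy(dtype=np.int64))
        reads[sl] = np.searchsorted(starts, grid.ends[sl], "left") - np.searchsorted(
            starts, grid.starts[sl], "left"
        )
        mstarts = np.sort(
            sub.loc[sub["is_multimapping"].astype(bool), "start"].to_numpy(np.int64)
        )
        multi_reads[sl] = np.searchsorted(mstarts, grid.ends[sl], "left") - np.searchsorted(
            mstarts, grid.starts[sl], "left"
        )

    depth_numer = reads if include_multimapping_in_depth else reads - multi_reads
    with np.errstate(divide="ignore", invalid="ignore"):
        depth = np.where(mappable > 0, depth_numer / np.maximum(mappable, 1), 0.0)
    multi = multi_reads * 1e6 / total
    return SampleBinCounts(
        reads=reads,
        multi_reads=multi_reads,
        depth=depth,
        multi=multi,
        n_retained=total,
        n_excluded=n_excluded,
    )


@dataclass
class BinSignalMatrix:
    """bins x samples matrices of the two window metrics.

    ``mappable`` is shared across samples; windows with zero mappable bases
    carry depth 0 and are flagged via :attr:`zero_map` for the caller's
    no-mappability merge rule.
    """

    grid: BinGrid
    sample_ids: list[str]
    depth: np.ndarray  # (n_bins, n_samples)
    multi: np.ndarray  # (n_bins, n_samples)
    mappable: np.ndarray  # (n_bins,)
    reads: np.ndarray | None = None  # raw counts, kept for inspection
    multi_reads: np.ndarray | None = None
    retained: dict[str, int] | None = None
    excluded: dict[str, int] | None = None

    def __post_init__(self) -> None:
        n, s = self.depth.shape
        if n != self.grid.n_bins or s != len(self.sample_ids):
            raise ValueError("matrix shape does not match grid/sample ids")
        for name, m in (("depth", self.depth), ("multi", self.multi)):
            if not np.all(np.isfinite(m)) or (m < 0).any():
                raise ValueError(f"{name} matrix must be finite and non-negative")

    @property
    def zero_map(self) -> np.ndarray:
        return self.mappable == 0

    def to_frame(self) -> pd.DataFrame:
        grid = self.grid
        data = {
            "chrom": [grid.chroms[i] for i in grid.chrom_index],
            "start": grid.starts,
            "end": grid.ends,
            "mappable": self.mappable,
        }
        for j, sid in enumerate(self.sample_ids):
            data[f"depth:{sid}"] = self.depth[:, j]
        for j, sid in enumerate(self.sample_ids):
            data[f"multi:{sid}"] = self.multi[:, j]
        return pd.DataFrame(data)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_signal_matrix(
    samples: Mapping[str, object] | Iterable[tuple[str, object]],
    grid: BinGrid,
    track: MappabilityTrack,
    exclude_chroms: Sequence[str] = DEFAULT_EXCLUDE_CHROMS,
    *,
    include_multimapping_in_depth: bool = True,
) -> BinSignalMatrix:
    """Bin a panel of samples. Empty samples are skipped with a warning."""
    items = samples.items() if isinstance(samples, Mapping) else samples
    mappable = bin_mappable_counts(grid, track)
    ids: list[str] = []
    depth_cols, multi_cols, read_cols, mread_cols = [], [], [], []
    retained: dict[str, int] = {}
    excluded: dict[str, int] = {}
    for sid, aln in items:
        try:
            cols = bin_sample(
                aln,
                grid,
                track,
                exclude_chroms,
                mappable=mappable,
                include_multimapping_in_depth=include_multimapping_in_depth,
            )
        except EmptySampleError:
            logger.warning("sample %s has no usable reads; skipping", sid)
            continue
        ids.append(sid)
        depth_cols.append(cols.depth)
        multi_cols.append(cols.multi)
        read_cols.append(cols.reads)
        mread_cols.append(cols.multi_reads)
        retained[sid] = cols.n_retained
        excluded[sid] = cols.n_excluded
    if not ids:
        raise EmptySampleError("no sample retained any reads")
    return BinSignalMatrix(
        grid=grid,
        sample_ids=ids,
        depth=np.column_stack(depth_cols),
        multi=np.column_stack(multi_cols),
        mappable=mappable,
        reads=np.column_stack(read_cols),
        multi_reads=np.column_stack(mread_cols),
        retained=retained,
        excluded=excluded,
    )
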