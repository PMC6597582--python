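"""Blacklist region calling from the normalized signal tracks.

Bins in the extreme upper tail of either standard-value track are flagged
(default: top 0.1% of bins with signal). Flagged bins grow across adjacent
bins that either keep signal in a looser upper tail (default: top 1%) or
have no signal because nothing there is uniquely mappable; regions within
the join distance (default 20 kb) are then combined. The read-depth track
yields "High Signal Region" calls; the multimapping track, seeded
additionally by zero-mappability bins, yields "Low Mappability" calls.
Excluded chromosomes (mitochondrial by default) are emitted whole.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .binning import (
    DEFAULT_BIN_SIZE,
    DEFAULT_EXCLUDE_CHROMS,
    DEFAULT_STEP,
    BinGrid,
)
from .genome_io import GenomicInterval
from .mappability import DEFAULT_READ_LENGTH
from .normalization import NormalizedSignal

logger = logging.getLogger("blacklist")

HIGH_SIGNAL = "High Signal Region"
LOW_MAPPABILITY = "Low Mappability"


@dataclass
class BlacklistConfig:
    """Every numeric knob of the calling procedure.

    Defaults are the published operating point for mammalian-scale
    genomes: 1 kb windows every 900 bp, flag the top 0.1% of signal,
    extend through the top 1%, combine regions within 20 kb.
    """

    bin_size: int = DEFAULT_BIN_SIZE
    step: int = DEFAULT_STEP
    flag_quantile: float = 0.999
    extend_quantile: float = 0.99
    join_distance: int = 20_000
    exclude_chroms: tuple[str, ...] = tuple(DEFAULT_EXCLUDE_CHROMS)
    read_length: int = DEFAULT_READ_LENGTH
    quantile: float = 0.5  # standard-value quantile across samples
    multimap_mapq_max: int = 0
    collapse: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.flag_quantile < 1 or not 0 < self.extend_quantile < 1:
            raise ValueError("quantiles must lie strictly between 0 and 1")
        if self.flag_quantile < self.extend_quantile:
            raise ValueError("flag_quantile must be >= extend_quantile")
        if self.join_distance < 0:
            raise ValueError("join_distance must be >= 0")
        if self.step <= 0 or self.bin_size <= 0 or self.step > self.bin_size:
            raise ValueError("need 0 < step <= bin_size")
        self.exclude_chroms = tuple(self.exclude_chroms)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exclude_chroms"] = list(self.exclude_chroms)
        return d


@dataclass(frozen=True)
class BlacklistRegion:
    interval: GenomicInterval
    label: str

    def to_interval(self) -> GenomicInterval:
        iv = self.interval
        return GenomicInterval(iv.chrom, iv.start, iv.end, name=self.label)


def tail_threshold(values: np.ndarray, quantile: float) -> float | None:
    """Value of the k-th largest entry, k = ceil(n * (1 - quantile)),
    over strictly positive entries. None when everything is zero.

    k is computed as n - floor(n*q + eps), identical in exact arithmetic
    but immune to the upward float spill of n*(1-q).
    """
    nonzero = values[values > 0]
    n = len(nonzero)
    if n == 0:
        return None
    k = max(1, n - math.floor(n * quantile + 1e-6))
    return float(np.partition(nonzero, n - k)[n - k])


def flag_bins(std_values: np.ndarray, flag_quantile: float) -> np.ndarray:
    """Indices of bins in the upper tail of the signal distribution.

    The threshold is the empirical ``flag_quantile`` of the nonzero-signal
    distribution; every bin at or above it is flagged (ties included).
    An all-zero track flags nothing.
    """
    values = np.asarray(std_values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("signal vector contains NaN or infinite values")
    thr = tail_threshold(values, flag_quantile)
    if thr is None:
        return np.empty(0, dtype=np.int64)
    flagged = np.flatnonzero(values >= thr)
    if len(flagged) == np.count_nonzero(values):
        logger.warning("degenerate signal: every nonzero bin is flagged")
    return flagged


def _bins_to_intervals(
    included: np.ndarray, grid: BinGrid
) -> list[tuple[int, int, int]]:
    """Collapse a bin mask to maximal (chrom_index, start, end) intervals,
    merging bins that overlap or touch."""
    out: list[tuple[int, int, int]] = []
    idx = np.flatnonzero(included)
    if len(idx) == 0:
        return out
    ci = grid.chrom_index[idx]
    starts = grid.starts[idx]
    ends = grid.ends[idx]
    cur = [int(ci[0]), int(starts[0]), int(ends[0])]
    for c, s, e in zip(ci[1:], starts[1:], ends[1:]):
        if int(c) == cur[0] and int(s) <= cur[2]:
            cur[2] = max(cur[2], int(e))
        else:
            out.append(tuple(cur))
            cur = [int(c), int(s), int(e)]
    out.append(tuple(cur))
    return out


def _join_gaps(
    intervals: list[tuple[int, int, int]], join_distance: int
) -> list[tuple[int, int, int]]:
    out: list[tuple[int, int, int]] = []
    for iv in intervals:
        if out and iv[0] == out[-1][0] and iv[1] - out[-1][2] <= join_distance:
            out[-1] = (out[-1][0], out[-1][1], max(out[-1][2], iv[2]))
        else:
            out.append(iv)
    return out


def grow_and_join(
    flagged: Iterable[int],
    std_values: np.ndarray,
    extend_quantile: float,
    zero_map_flags: np.ndarray,
    join_distance: int,
    grid: BinGrid,
) -> list[GenomicInterval]:
    """Grow flagged bins and combine nearby regions.

    Each flagged bin seeds a region; regions extend across adjacent grid
    bins whose signal stays at or above the ``extend_quantile`` tail of the
    nonzero distribution, or which have the zero-mappability flag, to a
    fixed point. Regions on the same chromosome separated by at most
    ``join_distance`` bases are then unioned (gap included), and finally
    overlapping bins are collapsed to maximal intervals.
    """
    values = np.asarray(std_values, dtype=float)
    included = np.zeros(grid.n_bins, dtype=bool)
    flagged = np.asarray(list(flagged), dtype=np.int64)
    if flagged.size == 0:
        return []
    included[flagged] = True

    thr = tail_threshold(values, extend_quantile)
    extendable = np.zeros(grid.n_bins, dtype=bool)
    if thr is not None:
        extendable = values >= thr
    extendable |= np.asarray(zero_map_flags, dtype=bool)

    same_prev = grid.same_chrom_as_prev()
    while True:
        neighbor = np.zeros(grid.n_bins, dtype=bool)
        neighbor[1:] |= included[:-1] & same_prev
        neighbor[:-1] |= included[1:] & same_prev
        newly = neighbor & extendable & ~included
        if not newly.any():
            break
        included |= newly

    merged = _join_gaps(_bins_to_intervals(included, grid), join_distance)
    return [GenomicInterval(grid.chroms[c], s, e) for c, s, e in merged]


def call_blacklist(
    norm: NormalizedSignal,
    config: BlacklistConfig,
    genome_lengths: Mapping[str, int],
) -> list[BlacklistRegion]:
    """Run the caller on both tracks and assemble the labeled blacklist.

    Read-depth calls are labeled "High Signal Region"; multimapping-rate
    calls, additionally seeded by bins with no uniquely mappable base, are
    labeled "Low Mappability". Excluded chromosomes present in the genome
    are emitted whole as "High Signal Region". Where a locus qualifies
    under both tracks, both labeled records are kept (they may overlap).
    """
    if norm.n_samples < 2:
        raise ValueError(
            "blacklist calling requires >= 2 input samples; "
            "single-sample mode is unsupported"
        )
    grid = norm.grid
    regions: list[BlacklistRegion] = []

    depth_flagged = flag_bins(norm.depth_std, config.flag_quantile)
    for iv in grow_and_join(
        depth_flagged,
        norm.depth_std,
        config.extend_quantile,
        norm.zero_map,
        config.join_distance,
        grid,
    ):
        regions.append(BlacklistRegion(iv, HIGH_SIGNAL))

    multi_flagged = flag_bins(norm.multi_std, config.flag_quantile)
    multi_seeds = np.union1d(multi_flagged, np.flatnonzero(norm.zero_map))
    for iv in grow_and_join(
        multi_seeds,
        norm.multi_std,
        config.extend_quantile,
        norm.zero_map,
        config.join_distance,
        grid,
    ):
        regions.append(BlacklistRegion(iv, LOW_MAPPABILITY))

    for chrom in config.exclude_chroms:
        length = genome_lengths.get(chrom)
        if length:
            regions.append(
                BlacklistRegion(GenomicInterval(chrom, 0, int(length)), HIGH_SIGNAL)
            )

    chrom_order = {c: i for i, c in enumerate(genome_lengths)}
    for i, c in enumerate(grid.chroms):
        chrom_order.setdefault(c, len(chrom_order))
    regions.sort(
        key=lambda r: (
            chrom_order.get(r.interval.chrom, len(chrom_order)),
            r.interval.start,
            r.interval.end,
            r.label,
        )
    )
    return regions


def collapse_blacklist(regions: Sequence[BlacklistRegion]) -> list[GenomicInterval]:
    """Union all calls label-free into disjoint intervals (input order
    defines chromosome order)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for r in regions:
        iv = r.interval
        if iv.chrom not in by_chrom:
            by_chrom[iv.chrom] = []
            order.append(iv.chrom)
        by_chrom[iv.chrom].append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for chrom in order:
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def blacklist_to_intervals(regions: Sequence[BlacklistRegion]) -> list[GenomicInterval]:
    return [r.to_interval() for r in regions]


def filter_peaks(
    peaks: Sequence[GenomicInterval],
    blacklist: Sequence[BlacklistRegion] | Sequence[GenomicInterval],
) -> tuple[list[GenomicInterval], int]:
    """Drop every peak overlapping any blacklist region by >= 1 bp.

    Returns (surviving peaks in input order, number removed).
    """
    spans: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    raw: dict[str, list[tuple[int, int]]] = {}
    for r in blacklist:
        iv = r.interval if isinstance(r, BlacklistRegion) else r
        raw.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, pairs in raw.items():
        pairs.sort()
        merged: list[tuple[int, int]] = []
        for s, e in pairs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        spans[chrom] = (
            np.array([s for s, _ in merged], dtype=np.int64),
            np.array([e for _, e in merged], dtype=np.int64),
        )

    kept: list[GenomicInterval] = []
    removed = 0
    for p in peaks:
        hit = False
        if p.chrom in spans:
            starts, ends = spans[p.chrom]
            # rightmost blacklist region starting before the peak end
            i = int(np.searchsorted(starts, p.end, "left")) - 1
            hit = i >= 0 and ends[i] > p.start
        if hit:
            removed += 1
        else:
            kept.append(p)
    return kept, removed
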