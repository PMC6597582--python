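"""Cross-sample quantile normalization and the per-bin standard value.

The panel of input samples is made comparable with classic rank-mean
quantile normalization (every sample column ends up with the same value
distribution), and each bin is then summarized by the 50% quantile across
samples. The median is deliberate: a copy-number gain in one cell type, or
one failed low-coverage input, moves a single column and leaves the
standard value untouched, so the resulting track is cell-type agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .binning import BinGrid, BinSignalMatrix

logger = logging.getLogger("blacklist")


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Rank-mean quantile normalization over columns (samples).

    Each column is sorted; the reference distribution is the across-column
    mean at each rank; every entry is replaced by the reference value at
    its within-column rank. Ties within a column receive the mean of the
    reference values over the tied rank range.

    A single-column matrix is returned unchanged (logged); NaNs are an error.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D bins x samples matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains NaN or infinite values")
    n_bins, n_samples = m.shape
    if n_bins < 2:
        raise ValueError("need at least 2 bins to quantile normalize")
    if n_samples == 1:
        logger.info("single sample: quantile normalization is the identity")
        return m.copy()

    reference = np.sort(m, axis=0).mean(axis=1)
    cum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(m)
    for j in range(n_samples):
        rmin = rankdata(m[:, j], method="min").astype(np.int64)
        rmax = rankdata(m[:, j], method="max").astype(np.int64)
        out[:, j] = (cum[rmax] - cum[rmin - 1]) / (rmax - rmin + 1)
    return out


def standard_value(matrix_qn: np.ndarray, quantile: float = 0.5) -> np.ndarray:
    """Per-bin empirical quantile across samples (linear interpolation).

    At 0.5 with an even sample count this is the mean of the two central
    order statistics.
    """
    if not 0.0 <= quantile <= 1.0:
        raise ValueError(f"quantile must be in [0, 1], got {quantile}")
    m = np.asarray(matrix_qn, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D bins x samples matrix")
    return np.quantile(m, quantile, axis=1)


@dataclass
class NormalizedSignal:
    """Quantile-normalized metrics and their per-bin standard values.

    ``depth_std`` / ``multi_std`` are pinned to exactly 0 for bins whose raw
    metric was 0 in every sample: tie-averaging during normalization can
    impute a small positive value into such bins, but they carry no
    evidence and must stay out of the caller's signal distribution.
    """

    grid: BinGrid
    n_samples: int
    depth_qn: np.ndarray
    multi_qn: np.ndarray
    depth_std: np.ndarray
    multi_std: np.ndarray
    zero_map: np.ndarray


def normalize_signal(matrix: BinSignalMatrix, quantile: float = 0.5) -> NormalizedSignal:
    """Quantile-normalize both metrics independently and take the per-bin
    standard value across samples."""
    depth_qn = quantile_normalize(matrix.depth)
    multi_qn = quantile_normalize(matrix.multi)
    depth_std = standard_value(depth_qn, quantile)
    multi_std = standard_value(multi_qn, quantile)
    depth_std[~(matrix.depth > 0).any(axis=1)] = 0.0
    multi_std[~(matrix.multi > 0).any(axis=1)] = 0.0
    return NormalizedSignal(
        grid=matrix.grid,
        n_samples=len(matrix.sample_ids),
        depth_qn=depth_qn,
        multi_qn=multi_qn,
        depth_std=depth_std,
        multi_std=multi_std,
        zero_map=matrix.zero_map.copy(),
    )
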