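"""Brute-force reference implementations used only to check the package.

Everything here is deliberately naive (string scans, all-pairs loops,
per-base arrays) and shares no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def _count_occurrences(seqs: list[str], pattern: str) -> int:
    """Overlapping occurrences of pattern across all sequences."""
    total = 0
    for seq in seqs:
        start = 0
        while True:
            i = seq.find(pattern, start)
            if i < 0:
                break
            total += 1
            start = i + 1
    return total


def naive_mappability(sequences: dict[str, str], k: int) -> dict[str, list[bool]]:
    """Position-by-position substring-search uniqueness at read length k."""
    seqs = list(sequences.values())
    out: dict[str, list[bool]] = {}
    for chrom, seq in sequences.items():
        L = len(seq)
        vec = [False] * L
        for p in range(L - k + 1):
            s = seq[p : p + k]
            if any(ch not in "ACGT" for ch in s):
                continue
            rc = revcomp(s)
            if s == rc:
                vec[p] = _count_occurrences(seqs, s) == 1
            else:
                vec[p] = _count_occurrences(seqs, s) + _count_occurrences(seqs, rc) == 1
        out[chrom] = vec
    return out


def stab_counts(read_starts_by_chrom: dict[str, list[int]], bins) -> list[int]:
    """Count reads per bin by testing every read against every bin."""
    counts = []
    for iv in bins:
        starts = read_starts_by_chrom.get(iv.chrom, [])
        counts.append(sum(1 for s in starts if iv.start <= s < iv.end))
    return counts


def _tail_count(n: int, quantile: float) -> int:
    # ceil(n * (1-q)) without the upward float spill of n*(1-q)
    return max(1, n - math.floor(n * quantile + 1e-6))


def flag_oracle(values, quantile: float) -> set[int]:
    """Sort-and-slice: top ceil(n_nonzero * (1-q)) values with tie closure."""
    nonzero = sorted(v for v in values if v > 0)
    if not nonzero:
        return set()
    threshold = nonzero[-_tail_count(len(nonzero), quantile)]
    return {i for i, v in enumerate(values) if v >= threshold}


def grow_oracle(
    flagged,
    values,
    extend_quantile: float,
    zero_map,
    join_distance: int,
    bins,
) -> list[tuple[str, int, int]]:
    """BFS over extendable neighbors, per-base union, pairwise gap closure."""
    n = len(bins)
    flagged = set(int(i) for i in flagged)
    if not flagged:
        return []
    nonzero = sorted(v for v in values if v > 0)
    if nonzero:
        thr = nonzero[-_tail_count(len(nonzero), extend_quantile)]
        extendable = [v >= thr or z for v, z in zip(values, zero_map)]
    else:
        extendable = [bool(z) for z in zero_map]

    included = set(flagged)
    frontier = list(flagged)
    while frontier:
        i = frontier.pop()
        for j in (i - 1, i + 1):
            if (
                0 <= j < n
                and j not in included
                and bins[j].chrom == bins[i].chrom
                and extendable[j]
            ):
                included.add(j)
                frontier.append(j)

    # per-base coverage, then maximal runs
    by_chrom: dict[str, np.ndarray] = {}
    for i in included:
        iv = bins[i]
        if iv.chrom not in by_chrom:
            max_end = max(b.end for b in bins if b.chrom == iv.chrom)
            by_chrom[iv.chrom] = np.zeros(max_end, dtype=bool)
        by_chrom[iv.chrom][iv.start : iv.end] = True

    chrom_order = []
    for b in bins:
        if b.chrom not in chrom_order:
            chrom_order.append(b.chrom)

    out: list[tuple[str, int, int]] = []
    for chrom in chrom_order:
        if chrom not in by_chrom:
            continue
        cov = by_chrom[chrom]
        padded = np.concatenate([[False], cov, [False]]).astype(np.int8)
        starts = list(np.flatnonzero(np.diff(padded) == 1))
        ends = list(np.flatnonzero(np.diff(padded) == -1))
        spans = [[int(s), int(e)] for s, e in zip(starts, ends)]
        # pairwise gap-union to closure
        changed = True
        while changed:
            changed = False
            for a in range(len(spans)):
                for b2 in range(a + 1, len(spans)):
                    sa, sb = spans[a], spans[b2]
                    gap = max(sa[0], sb[0]) - min(sa[1], sb[1])
                    if gap <= join_distance:
                        spans[a] = [min(sa[0], sb[0]), max(sa[1], sb[1])]
                        del spans[b2]
                        changed = True
                        break
                if changed:
                    break
        out.extend((chrom, s, e) for s, e in sorted(spans))
    return out


def overlap_filter_oracle(peaks, regions):
    """All-pairs peak-vs-region overlap test."""
    kept = []
    removed = 0
    for p in peaks:
        if any(
            p.chrom == r.chrom and p.start < r.end and r.start < p.end for r in regions
        ):
            removed += 1
        else:
            kept.append(p)
    return kept, removed


def jaccard_oracle(a, b) -> float:
    """Per-base intersection over union of two intervals."""
    if a.chrom != b.chrom:
        return 0.0
    hi = max(a.end, b.end)
    va = np.zeros(hi, dtype=bool)
    vb = np.zeros(hi, dtype=bool)
    va[a.start : a.end] = True
    vb[b.start : b.end] = True
    union = int((va | vb).sum())
    return int((va & vb).sum()) / union if union else 0.0
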