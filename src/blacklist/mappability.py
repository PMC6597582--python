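"""Exact k-mer uniqueness: which positions start a uniquely mappable read.

A position p on chromosome c is uniquely mappable at read length k when the
k-mer starting there occurs exactly once in the whole genome, counting both
strands. Occurrences are tallied per canonical k-mer (the lexicographic
minimum of a k-mer and its reverse complement), so for a non-palindromic
k-mer the count is forward occurrences of the k-mer plus forward occurrences
of its reverse complement; for a palindrome it is the forward count alone,
and a single locus still counts as unique (a read of that sequence has one
genomic origin even though its strand is ambiguous).

Windows containing N (or any non-ACGT code) are never mappable.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .genome_io import GenomeSequence, GenomicInterval

_RC = str.maketrans("ACGT", "TGCA")

#: default read length: a common short-read length for input controls
DEFAULT_READ_LENGTH = 36


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class MappabilityTrack:
    """Per-chromosome boolean vectors: True = uniquely mappable start.

    Each vector has the full chromosome length; the trailing k-1 positions
    (where no k-mer fits) are padded False so vectors align with coordinates.
    """

    k: int
    vectors: dict[str, np.ndarray]
    _cumsums: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def _cumsum(self, chrom: str) -> np.ndarray:
        cs = self._cumsums.get(chrom)
        if cs is None:
            vec = self.vectors[chrom]
            cs = np.concatenate([[0], np.cumsum(vec, dtype=np.int64)])
            self._cumsums[chrom] = cs
        return cs

    def mappable_in(self, chrom: str, start: int, end: int) -> int:
        """Count uniquely mappable start positions in [start, end)."""
        if chrom not in self.vectors:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = len(self.vectors[chrom])
        if not (0 <= start < end <= n):
            raise ValueError(f"interval {start}-{end} outside {chrom} (length {n})")
        cs = self._cumsum(chrom)
        return int(cs[end] - cs[start])

    def to_intervals(self) -> list[GenomicInterval]:
        """Maximal runs of uniquely mappable positions, as intervals."""
        out: list[GenomicInterval] = []
        for chrom, vec in self.vectors.items():
            padded = np.concatenate([[False], vec, [False]])
            diff = np.diff(padded.astype(np.int8))
            starts = np.flatnonzero(diff == 1)
            ends = np.flatnonzero(diff == -1)
            out.extend(
                GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)
            )
        return out


def _n_window_mask(seq: str, k: int) -> np.ndarray:
    """Boolean array over start positions: True where the k-window is N-free."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_acgt = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    bad = np.concatenate([[0], np.cumsum(~is_acgt, dtype=np.int64)])
    n_starts = len(seq) - k + 1
    return (bad[k:] - bad[:n_starts]) == 0


def compute_mappability(genome: GenomeSequence, k: int) -> MappabilityTrack:
    """Exhaustive unique-mappability track at read length ``k``.

    Exact (no sketching); memory is linear in the number of distinct
    canonical k-mers, which is adequate for desk-scale genomes.
    """
    if k <= 0:
        raise ValueError(f"read length k must be positive, got {k}")
    lengths = genome.lengths
    if not lengths or k > min(lengths.values()):
        raise ValueError(
            f"k={k} exceeds the shortest chromosome "
            f"(min length {min(lengths.values()) if lengths else 0})"
        )

    counts: Counter[str] = Counter()
    clean_masks: dict[str, np.ndarray] = {}
    revcomps: dict[str, str] = {}
    for chrom, seq in genome.sequences.items():
        L = len(seq)
        if L < k:
            clean_masks[chrom] = np.zeros(0, dtype=bool)
            continue
        clean = _n_window_mask(seq, k)
        clean_masks[chrom] = clean
        rc = reverse_complement(seq)
        revcomps[chrom] = rc
        for p in np.flatnonzero(clean):
            p = int(p)
            fwd = seq[p : p + k]
            rev = rc[L - p - k : L - p]
            counts[fwd if fwd <= rev else rev] += 1

    vectors: dict[str, np.ndarray] = {}
    for chrom, seq in genome.sequences.items():
        L = len(seq)
        vec = np.zeros(L, dtype=bool)
        clean = clean_masks[chrom]
        if clean.size:
            rc = revcomps[chrom]
            for p in np.flatnonzero(clean):
                p = int(p)
                fwd = seq[p : p + k]
                rev = rc[L - p - k : L - p]
                if counts[fwd if fwd <= rev else rev] == 1:
                    vec[p] = True
        vectors[chrom] = vec
    return MappabilityTrack(k=k, vectors=vectors)


def mappable_bases_in(track: MappabilityTrack, interval: GenomicInterval) -> int:
    """Uniquely mappable start positions within an interval (the
    denominator of reads-per-mappable-base)."""
    return track.mappable_in(interval.chrom, interval.start, interval.end)


def write_track_bed(track: MappabilityTrack, path: str | os.PathLike) -> None:
    from .genome_io import write_bed

    write_bed(track.to_intervals(), path)
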