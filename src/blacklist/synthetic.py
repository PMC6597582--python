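"""Synthetic genomes and input-control read panels with planted artifacts.

The generator emulates the artifact mechanisms the caller is meant to
detect, on a genome small enough to analyze in seconds:

* collapsed repeats — the reference holds one copy of a segment that the
  sampled genome carries in ``c`` copies, so read starts pile up at
  ``c x`` the background rate;
* a NUMT-like locus — a nuclear insertion of mitochondrial sequence whose
  effective copy number (many mitochondrial genomes per nucleus) inflates
  depth the same way, only more so;
* duplicated segments — the same sequence placed at two reference loci, so
  every read from either copy is ambiguous: reads are emitted as
  multimapping with their position assigned to one copy at random, and the
  duplicated sequence genuinely destroys unique mappability there;
* Poisson background everywhere else, independently per sample;
* optionally a single-sample CNV, to exercise the median's robustness, and
  a mitochondrial chromosome, to exercise the chrM pre-filter.

Reads are start positions plus a fixed read length — no sequences are
simulated and no aligner runs; the pipeline consumes exactly this.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    ALIGNMENT_COLUMNS,
    GenomeSequence,
    GenomicInterval,
    write_alignment_table,
    write_bed,
    write_fasta,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

COLLAPSED_REPEAT = "collapsed_repeat"
NUMT = "numt"
DUPLICATED = "duplicated"


@dataclass(frozen=True)
class CnvSpec:
    """Copy-number gain present in a single sample."""

    length: int = 10_000
    fold: float = 10.0
    sample_index: int = 0


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic panel.

    Defaults describe the standard benchmark panel: a 1 Mb genome sampled
    by 20 input controls at 0.05 reads per base, with five 5 kb collapsed
    repeats at copy number 50, one 3 kb NUMT at copy number 100 and one
    duplicated 4 kb segment pair.
    """

    genome_length: int = 1_000_000
    n_samples: int = 20
    background_depth: float = 0.05
    collapsed_repeats: Sequence[tuple[int, int]] = ((5000, 50),) * 5
    numt: tuple[int, int] | None = (3000, 100)
    duplicated_segments: Sequence[int] = (4000,)
    read_length: int = 36
    seed: int = 1
    chrm_length: int = 0
    chrm_depth_fold: float = 50.0
    cnv: CnvSpec | None = None
    min_locus_separation: int = 40_000

    def to_dict(self) -> dict:
        d = asdict(self)
        d["collapsed_repeats"] = [list(x) for x in self.collapsed_repeats]
        d["duplicated_segments"] = list(self.duplicated_segments)
        d["numt"] = list(self.numt) if self.numt else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if d.get("cnv"):
            d["cnv"] = CnvSpec(**d["cnv"])
        if d.get("collapsed_repeats") is not None:
            d["collapsed_repeats"] = tuple(tuple(x) for x in d["collapsed_repeats"])
        if d.get("numt"):
            d["numt"] = tuple(d["numt"])
        if d.get("duplicated_segments") is not None:
            d["duplicated_segments"] = tuple(d["duplicated_segments"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """A generated panel plus the planted ground truth."""

    spec: SyntheticSpec
    genome: GenomeSequence
    regions: list[GenomicInterval]  # planted artifacts, named by mechanism
    samples: list[pd.DataFrame]  # per-sample alignment tables
    cnv_region: GenomicInterval | None = None

    @property
    def sample_ids(self) -> list[str]:
        return [f"sample_{i:02d}" for i in range(len(self.samples))]

    def write(self, outdir: str | os.PathLike) -> dict[str, object]:
        os.makedirs(outdir, exist_ok=True)
        paths: dict[str, object] = {}
        fasta = os.path.join(outdir, "genome.fa")
        write_fasta(self.genome, fasta)
        paths["fasta"] = fasta
        truth = os.path.join(outdir, "truth.bed")
        write_bed(sorted(self.regions, key=lambda iv: (iv.chrom, iv.start)), truth)
        paths["truth"] = truth
        sample_paths = []
        for sid, table in zip(self.sample_ids, self.samples):
            p = os.path.join(outdir, f"{sid}.alignments.tsv")
            write_alignment_table(table, p)
            sample_paths.append(p)
        paths["samples"] = sample_paths
        return paths


def _place_loci(
    rng: np.random.Generator,
    genome_length: int,
    lengths: list[int],
    separation: int,
) -> list[int]:
    """Deterministically place non-overlapping loci, one per equal slot of
    the genome, jittered within the slot and kept clear of slot edges."""
    n = len(lengths)
    if n == 0:
        return []
    slot = genome_length // n
    margin = separation // 2
    starts = []
    for i, length in enumerate(lengths):
        lo = i * slot + margin
        hi = (i + 1) * slot - margin - length
        if hi <= lo:
            raise ValueError(
                f"cannot place a {length} bp locus in a {slot} bp slot with "
                f"{margin} bp margins; genome too small for the requested loci"
            )
        starts.append(int(rng.integers(lo, hi)))
    return starts


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _poisson_reads(
    rng: np.random.Generator, start: int, end: int, rate: float, max_start: int
) -> np.ndarray:
    """Uniform read starts over [start, end) at the given per-base rate."""
    hi = min(end, max_start)
    if hi <= start or rate <= 0:
        return np.empty(0, dtype=np.int64)
    n = rng.poisson(rate * (hi - start))
    return rng.integers(start, hi, size=n, dtype=np.int64)


def generate(spec: SyntheticSpec) -> SyntheticTruth:
    """Build the reference, plant the artifacts and sample the read panel.

    All randomness derives from ``spec.seed`` through one stream for the
    genome and placement plus one independent substream per sample, so a
    fixed spec regenerates byte-identical output.
    """
    seqs = np.random.SeedSequence(spec.seed).spawn(spec.n_samples + 1)
    g_rng = np.random.default_rng(seqs[0])

    repeats = [(int(l), int(c)) for l, c in spec.collapsed_repeats]
    dups = [int(l) for l in spec.duplicated_segments]
    for length, c in repeats + ([tuple(spec.numt)] if spec.numt else []):
        if c < 2:
            raise ValueError("planted copy numbers must be >= 2")

    lengths = [l for l, _ in repeats]
    mechanisms = [COLLAPSED_REPEAT] * len(repeats)
    rates = [c * spec.background_depth for _, c in repeats]
    if spec.numt:
        lengths.append(int(spec.numt[0]))
        mechanisms.append(NUMT)
        rates.append(int(spec.numt[1]) * spec.background_depth)
    for l in dups:  # two reference copies each
        lengths.extend([l, l])
        mechanisms.extend([DUPLICATED, DUPLICATED])
        rates.extend([None, None])  # handled jointly below
    if spec.cnv:
        lengths.append(int(spec.cnv.length))
        mechanisms.append("cnv")
        rates.append(None)

    starts = _place_loci(g_rng, spec.genome_length, lengths, spec.min_locus_separation)

    seq = _random_seq(g_rng, spec.genome_length)
    regions: list[GenomicInterval] = []
    cnv_region: GenomicInterval | None = None
    dup_pairs: list[tuple[int, int, int]] = []  # (startA, startB, length)
    i = 0
    for length, mech, start in zip(lengths, mechanisms, starts):
        if mech == DUPLICATED:
            if i % 2 == 0:
                dup_pairs.append((start, None, length))  # partner fills next
            else:
                a, _, l = dup_pairs[-1]
                dup_pairs[-1] = (a, start, l)
                segment = _random_seq(g_rng, length)
                seq[a : a + length] = segment
                seq[start : start + length] = segment
            i += 1
        if mech == "cnv":
            cnv_region = GenomicInterval("chr1", start, start + length, name="cnv")
            continue
        regions.append(GenomicInterval("chr1", start, start + length, name=mech))

    sequences = {"chr1": seq.tobytes().decode("ascii")}
    if spec.chrm_length:
        sequences["chrM"] = (
            _random_seq(g_rng, spec.chrm_length).tobytes().decode("ascii")
        )
    genome = GenomeSequence(sequences)

    # piecewise rates for the unique (non-multimapping) background + pileups
    high_loci = [
        (iv.start, iv.end, rate)
        for iv, rate in zip(
            [r for r in regions if r.name in (COLLAPSED_REPEAT, NUMT)],
            [r for r, m in zip(rates, mechanisms) if m in (COLLAPSED_REPEAT, NUMT)],
        )
    ]
    dup_spans = [(a, a + l) for a, b, l in dup_pairs] + [
        (b, b + l) for a, b, l in dup_pairs
    ]

    max_start = spec.genome_length - spec.read_length
    samples: list[pd.DataFrame] = []
    for s in range(spec.n_samples):
        rng = np.random.default_rng(seqs[s + 1])
        pos_parts: list[np.ndarray] = []
        multi_parts: list[np.ndarray] = []
        # background over the whole genome minus duplicated spans
        cuts = sorted(dup_spans)
        cursor = 0
        for a, b in cuts + [(spec.genome_length, spec.genome_length)]:
            pos_parts.append(
                _poisson_reads(rng, cursor, a, spec.background_depth, max_start)
            )
            cursor = b
        # extra unique reads inside collapsed repeats / NUMT (rate c*bg total)
        for a, b, rate in high_loci:
            pos_parts.append(
                _poisson_reads(
                    rng, a, b, rate - spec.background_depth, max_start
                )
            )
        # single-sample CNV
        if spec.cnv and s == spec.cnv.sample_index and cnv_region is not None:
            pos_parts.append(
                _poisson_reads(
                    rng,
                    cnv_region.start,
                    cnv_region.end,
                    (spec.cnv.fold - 1.0) * spec.background_depth,
                    max_start,
                )
            )
        # duplicated segments: both copies sampled at background, every read
        # ambiguous, position assigned to one copy uniformly at random
        for a, b, l in dup_pairs:
            hi = min(l, max_start - max(a, b))
            n = rng.poisson(2.0 * spec.background_depth * hi)
            offsets = rng.integers(0, hi, size=n, dtype=np.int64)
            which = rng.integers(0, 2, size=n)
            multi_parts.append(np.where(which == 0, a, b) + offsets)

        uniq = np.concatenate(pos_parts) if pos_parts else np.empty(0, dtype=np.int64)
        multi = (
            np.concatenate(multi_parts) if multi_parts else np.empty(0, dtype=np.int64)
        )
        chroms = ["chr1"] * (len(uniq) + len(multi))
        starts_col = np.concatenate([uniq, multi])
        flags = np.concatenate(
            [np.zeros(len(uniq), dtype=bool), np.ones(len(multi), dtype=bool)]
        )
        if spec.chrm_length:
            m_hi = spec.chrm_length - spec.read_length
            m_reads = _poisson_reads(
                rng, 0, m_hi, spec.chrm_depth_fold * spec.background_depth, m_hi
            )
            chroms += ["chrM"] * len(m_reads)
            starts_col = np.concatenate([starts_col, m_reads])
            flags = np.concatenate([flags, np.zeros(len(m_reads), dtype=bool)])
        table = pd.DataFrame(
            {
                "chrom": chroms,
                "start": starts_col,
                "read_length": np.full(len(starts_col), spec.read_length),
                "is_multimapping": flags,
            },
            columns=list(ALIGNMENT_COLUMNS),
        )
        table = table.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )
        samples.append(table)

    return SyntheticTruth(
        spec=spec,
        genome=genome,
        regions=regions,
        samples=samples,
        cnv_region=cnv_region,
    )


@dataclass
class RegionComparison:
    """Recovery metrics of a called region set against a planted truth."""

    jaccards: list[float] = field(default_factory=list)  # best J per truth region
    n_recovered: int = 0  # truth regions with best J >= 0.5
    n_truth: int = 0
    n_spurious: int = 0  # calls overlapping no truth +- slack


def _jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    if inter == 0:
        return 0.0
    union = (a.end - a.start) + (b.end - b.start) - inter
    return inter / union


def compare_region_sets(
    called: Sequence[GenomicInterval],
    truth: Sequence[GenomicInterval],
    *,
    slack: int = 20_000,
    recovery_jaccard: float = 0.5,
) -> RegionComparison:
    """Best per-truth Jaccard (in bases), recovery and spurious-call counts.

    A truth region is recovered when some single call reaches Jaccard >=
    ``recovery_jaccard`` against it; a call is spurious when it overlaps no
    truth region extended by ``slack`` on each side.
    """
    cmp = RegionComparison(n_truth=len(truth))
    for t in truth:
        best = max((_jaccard(c, t) for c in called), default=0.0)
        cmp.jaccards.append(best)
        if best >= recovery_jaccard:
            cmp.n_recovered += 1
    for c in called:
        near = any(
            c.chrom == t.chrom and c.start < t.end + slack and t.start - slack < c.end
            for t in truth
        )
        if not near:
            cmp.n_spurious += 1
    return cmp


def suggested_config(spec: SyntheticSpec, **overrides):
    """Caller configuration with flag/extend tails scaled to the panel.

    The published flag (0.1%) and extension (1%) tails presume artifact
    loci occupy far less of the genome than the flag tail itself, which
    holds for mammalian assemblies. On a toy genome the planted high-signal
    loci occupy a known fraction of the bins, so the tails are set just
    outside that fraction: flag at 1 - f and extend at 1 - 1.2 f, where f
    is the fraction of the genome covered by planted high-depth loci.
    """
    from .caller import BlacklistConfig

    high_bases = sum(l for l, _ in spec.collapsed_repeats) + (
        spec.numt[0] if spec.numt else 0
    )
    f = high_bases / spec.genome_length
    params = dict(
        flag_quantile=min(0.999, 1.0 - f),
        extend_quantile=min(0.99, 1.0 - 1.2 * f),
        read_length=spec.read_length,
    )
    params.update(overrides)
    return BlacklistConfig(**params)
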