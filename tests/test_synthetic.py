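import numpy as np
import pytest

from blacklist import (
    CnvSpec,
    GenomicInterval,
    SyntheticSpec,
    compare_region_sets,
    generate,
)
from blacklist.genome_io import read_alignment_table, read_bed, read_fasta
from _oracles import jaccard_oracle


SMALL = dict(
    genome_length=120_000,
    n_samples=3,
    collapsed_repeats=((3000, 50),),
    numt=(2500, 100),
    duplicated_segments=(3000,),
    min_locus_separation=10_000,
)


class TestGenerate:
    def test_background_read_count_near_poisson_mean(self):
        spec = SyntheticSpec(
            genome_length=100_000,
            n_samples=1,
            background_depth=0.05,
            collapsed_repeats=(),
            numt=None,
            duplicated_segments=(),
            seed=7,
        )
        truth = generate(spec)
        n = len(truth.samples[0])
        mean = 0.05 * 100_000
        assert abs(n - mean) < 4 * np.sqrt(mean)

    def test_collapsed_repeat_rate_matches_copy_number(self):
        spec = SyntheticSpec(
            genome_length=200_000,
            n_samples=1,
            collapsed_repeats=((5000, 50),),
            numt=None,
            duplicated_segments=(),
            seed=11,
            min_locus_separation=10_000,
        )
        truth = generate(spec)
        locus = truth.regions[0]
        starts = truth.samples[0]["start"].to_numpy()
        inside = int(((starts >= locus.start) & (starts < locus.end)).sum())
        mean = 50 * 0.05 * len(locus)
        assert abs(inside - mean) < 4 * np.sqrt(mean)

    def test_fixed_seed_reproduces_identically(self):
        a = generate(SyntheticSpec(**SMALL, seed=5))
        b = generate(SyntheticSpec(**SMALL, seed=5))
        assert a.genome.sequences == b.genome.sequences
        assert a.regions == b.regions
        for ta, tb in zip(a.samples, b.samples):
            assert ta.equals(tb)

    def test_duplicated_reads_are_the_only_multimappers(self):
        truth = generate(SyntheticSpec(**SMALL, seed=5))
        dups = [r for r in truth.regions if r.name == "duplicated"]
        assert len(dups) == 2
        for t in truth.samples:
            mm = t[t["is_multimapping"]]
            assert len(mm) > 0
            for s in mm["start"]:
                assert any(d.start <= s < d.end for d in dups)
            not_mm = t[~t["is_multimapping"]]
            for d in dups:
                inside = (not_mm["start"] >= d.start) & (not_mm["start"] < d.end)
                assert not inside.any()

    def test_duplicated_copies_share_sequence(self):
        truth = generate(SyntheticSpec(**SMALL, seed=5))
        a, b = [r for r in truth.regions if r.name == "duplicated"]
        seq = truth.genome["chr1"]
        assert seq[a.start : a.end] == seq[b.start : b.end]

    def test_planted_loci_disjoint_and_in_bounds(self):
        spec = SyntheticSpec(seed=3)
        truth = generate(spec)
        regions = sorted(truth.regions, key=lambda r: r.start)
        for r in regions:
            assert 0 <= r.start < r.end <= spec.genome_length
        for prev, nxt in zip(regions, regions[1:]):
            assert nxt.start - prev.end >= spec.min_locus_separation

    def test_cnv_confined_to_one_sample(self):
        spec = SyntheticSpec(
            **SMALL, seed=9, cnv=CnvSpec(length=8000, fold=10, sample_index=1)
        )
        truth = generate(spec)
        cnv = truth.cnv_region
        assert cnv is not None
        counts = []
        for t in truth.samples:
            starts = t["start"].to_numpy()
            counts.append(int(((starts >= cnv.start) & (starts < cnv.end)).sum()))
        background = spec.background_depth * len(cnv)
        assert counts[1] > 5 * background
        for i in (0, 2):
            assert abs(counts[i] - background) < 4 * np.sqrt(background)

    def test_poisson_dispersion_over_disjoint_windows(self):
        spec = SyntheticSpec(
            genome_length=400_000,
            n_samples=1,
            background_depth=0.05,
            collapsed_repeats=(),
            numt=None,
            duplicated_segments=(),
            seed=13,
        )
        starts = generate(spec).samples[0]["start"].to_numpy()
        counts, _ = np.histogram(starts, bins=np.arange(0, 400_001, 1000))
        dispersion = counts.var() / counts.mean()
        assert 0.8 < dispersion < 1.2

    def test_write_produces_readable_fixture(self, tmp_path):
        truth = generate(SyntheticSpec(**SMALL, seed=5, chrm_length=2000))
        paths = truth.write(tmp_path / "sim")
        genome = read_fasta(paths["fasta"])
        assert genome.sequences == truth.genome.sequences
        assert len(read_bed(paths["truth"])) == len(truth.regions)
        table = read_alignment_table(paths["samples"][0])
        assert table.equals(
            truth.samples[0][["chrom", "start", "read_length", "is_multimapping"]]
        )

    def test_overlapping_loci_rejected(self):
        spec = SyntheticSpec(
            genome_length=20_000,
            collapsed_repeats=((5000, 50), (5000, 50), (5000, 50)),
            numt=None,
            duplicated_segments=(),
            min_locus_separation=10_000,
        )
        with pytest.raises(ValueError):
            generate(spec)


class TestCompareRegionSets:
    def test_identical_sets(self):
        ivs = [GenomicInterval("c", 0, 1000), GenomicInterval("c", 5000, 7000)]
        cmp = compare_region_sets(ivs, ivs)
        assert cmp.jaccards == [1.0, 1.0]
        assert cmp.n_recovered == 2
        assert cmp.n_spurious == 0

    def test_partial_overlap_jaccard(self):
        called = [GenomicInterval("c", 0, 1000)]
        truth = [GenomicInterval("c", 500, 1500)]
        cmp = compare_region_sets(called, truth)
        assert cmp.jaccards[0] == pytest.approx(1 / 3)
        assert cmp.n_recovered == 0

    def test_spurious_counts_respect_slack(self):
        truth = [GenomicInterval("c", 10_000, 12_000)]
        called = [
            GenomicInterval("c", 13_000, 14_000),  # within 20 kb slack
            GenomicInterval("c", 40_000, 41_000),  # beyond slack
        ]
        cmp = compare_region_sets(called, truth, slack=20_000)
        assert cmp.n_spurious == 1

    def test_matches_base_counting_oracle(self, rng):
        def random_set(n):
            out = []
            pos = 0
            for _ in range(n):
                s = pos + int(rng.integers(0, 800))
                e = s + int(rng.integers(50, 700))
                out.append(GenomicInterval("c", s, e))
                pos = e
            return out

        called, truth = random_set(8), random_set(6)
        cmp = compare_region_sets(called, truth, slack=500)
        for j, t in zip(cmp.jaccards, truth):
            assert j == pytest.approx(max(jaccard_oracle(c, t) for c in called))

    def test_jaccard_symmetric_under_swap(self, rng):
        a = [GenomicInterval("c", 0, 1000), GenomicInterval("c", 3000, 3500)]
        b = [GenomicInterval("c", 500, 1200)]
        ab = compare_region_sets(a, b)
        ba = compare_region_sets(b, a)
        assert max(ab.jaccards) == pytest.approx(max(ba.jaccards))
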