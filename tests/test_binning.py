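import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blacklist import (
    EmptySampleError,
    GenomeSequence,
    bin_sample,
    build_signal_matrix,
    compute_mappability,
    make_grid,
)
from blacklist.binning import bin_mappable_counts
from blacklist.mappability import MappabilityTrack
from conftest import random_genome
from _oracles import stab_counts


def full_track(lengths, k=3):
    """All-positions-mappable track (unrealistic; isolates the counting)."""
    return MappabilityTrack(k, {c: np.ones(L, dtype=bool) for c, L in lengths.items()})


def table(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "read_length", "is_multimapping"]
    )


class TestMakeGrid:
    def test_overlapping_windows(self):
        grid = make_grid({"c": 2000}, bin_size=1000, step=900)
        assert [(int(s), int(e)) for s, e in zip(grid.starts, grid.ends)] == [
            (0, 1000),
            (900, 1900),
            (1800, 2000),
        ]

    def test_short_chromosome_single_clipped_bin(self):
        grid = make_grid({"c": 500}, bin_size=1000, step=900)
        assert grid.n_bins == 1
        assert (int(grid.starts[0]), int(grid.ends[0])) == (0, 500)

    def test_start_count_enumeration(self):
        # starts 0, 900, ..., 9900: every multiple of 900 below 10000
        grid = make_grid({"c": 10000}, bin_size=1000, step=900)
        assert grid.n_bins == 12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_grid({"c": 1000}, bin_size=0, step=1)
        with pytest.raises(ValueError):
            make_grid({"c": 1000}, bin_size=100, step=0)
        with pytest.raises(ValueError):
            make_grid({"c": 1000}, bin_size=100, step=200)

    def test_every_base_covered(self, rng):
        lengths = {"a": int(rng.integers(100, 3000)), "b": int(rng.integers(100, 3000))}
        grid = make_grid(lengths, bin_size=250, step=200)
        for chrom, L in lengths.items():
            cov = np.zeros(L, dtype=bool)
            sl = grid.chrom_slice(chrom)
            for s, e in zip(grid.starts[sl], grid.ends[sl]):
                cov[s:e] = True
            assert cov.all()
            # consecutive windows overlap by bin_size - step
            starts = grid.starts[sl]
            ends = grid.ends[sl]
            for i in range(len(starts) - 1):
                if ends[i] - starts[i] == 250:  # unclipped
                    assert ends[i] - starts[i + 1] == 50


    @given(
        length=st.integers(1, 5000),
        bin_size=st.integers(1, 600),
        overlap=st.integers(0, 599),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_grid_invariants_hold_for_any_geometry(self, length, bin_size, overlap):
        step = bin_size - min(overlap, bin_size - 1)
        grid = make_grid({"c": length}, bin_size=bin_size, step=step)
        starts, ends = grid.starts, grid.ends
        assert starts[0] == 0
        assert np.all(np.diff(starts) == step)
        assert np.all(ends == np.minimum(starts + bin_size, length))
        assert starts[-1] < length <= starts[-1] + step  # no start beyond, none missing
        cov = np.zeros(length, dtype=bool)
        for s, e in zip(starts, ends):
            cov[s:e] = True
        assert cov.all()


class TestBinSample:
    def test_depth_formula(self):
        grid = make_grid({"c": 1000}, bin_size=1000, step=1000)
        reads = table([("c", int(p), 36, False) for p in np.linspace(0, 900, 10)])
        # pad sample with reads on an excluded chromosome: they must not count
        reads = pd.concat([reads, table([("chrM", 0, 36, False)] * 990)])
        cols = bin_sample(reads, grid, full_track({"c": 1000}))
        assert cols.n_retained == 10
        assert cols.n_excluded == 990
        assert cols.depth[0] == pytest.approx(10 / 1000)
        assert cols.multi[0] == 0

    def test_multi_per_million(self):
        grid = make_grid({"c": 1000}, bin_size=1000, step=1000)
        rows = [("c", 10 + i, 36, True) for i in range(5)]
        rows += [("c", 500, 36, False)] * 95
        cols = bin_sample(table(rows), grid, full_track({"c": 1000}))
        assert cols.multi[0] == pytest.approx(5 * 1e6 / 100)

    def test_zero_mappability_bin_has_zero_depth(self):
        grid = make_grid({"c": 200}, bin_size=100, step=100)
        vec = np.ones(200, dtype=bool)
        vec[100:] = False
        track = MappabilityTrack(3, {"c": vec})
        cols = bin_sample(table([("c", 150, 36, False)]), grid, track)
        assert cols.depth[1] == 0.0
        assert cols.reads[1] == 1  # raw count still recorded

    def test_empty_sample_rejected(self):
        grid = make_grid({"c": 1000}, bin_size=1000, step=1000)
        with pytest.raises(EmptySampleError):
            bin_sample(table([("chrM", 0, 36, False)]), grid, full_track({"c": 1000}))

    def test_counts_match_stabbing_oracle(self, rng):
        genome = random_genome(rng, {"chr1": 30000, "chr2": 20000})
        track = compute_mappability(genome, 10)
        grid = make_grid(genome.lengths, bin_size=1000, step=900)
        rows = []
        for _ in range(2000):
            chrom = "chr1" if rng.random() < 0.6 else "chr2"
            start = int(rng.integers(0, genome.lengths[chrom] - 36))
            rows.append((chrom, start, 36, bool(rng.random() < 0.1)))
        t = table(rows)
        cols = bin_sample(t, grid, track)
        starts_by_chrom = {
            c: sorted(t.loc[t["chrom"] == c, "start"]) for c in ("chr1", "chr2")
        }
        assert list(cols.reads) == stab_counts(starts_by_chrom, list(grid.intervals()))
        multi_by_chrom = {
            c: sorted(t.loc[(t["chrom"] == c) & t["is_multimapping"], "start"])
            for c in ("chr1", "chr2")
        }
        assert list(cols.multi_reads) == stab_counts(
            multi_by_chrom, list(grid.intervals())
        )

    def test_nonoverlapping_grid_conserves_total(self, rng):
        genome = random_genome(rng, {"c": 10000})
        grid = make_grid({"c": 10000}, bin_size=500, step=500)
        rows = [("c", int(rng.integers(0, 9964)), 36, False) for _ in range(500)]
        cols = bin_sample(table(rows), grid, full_track({"c": 10000}))
        assert cols.reads.sum() == 500

    def test_multi_is_scale_free_depth_is_not(self):
        grid = make_grid({"c": 1000}, bin_size=1000, step=1000)
        rows = [("c", 10, 36, True)] * 2 + [("c", 600, 36, False)] * 8
        once = bin_sample(table(rows), grid, full_track({"c": 1000}))
        twice = bin_sample(table(rows * 2), grid, full_track({"c": 1000}))
        assert twice.multi[0] == pytest.approx(once.multi[0])
        assert twice.depth[0] == pytest.approx(2 * once.depth[0])


class TestSignalMatrix:
    def test_panel_skips_empty_sample(self, rng, caplog):
        genome = random_genome(rng, {"c": 5000})
        track = compute_mappability(genome, 5)
        grid = make_grid({"c": 5000}, bin_size=1000, step=900)
        good = table([("c", int(rng.integers(0, 4964)), 36, False) for _ in range(50)])
        empty = table([("chrM", 0, 36, False)])
        m = build_signal_matrix({"s1": good, "s2": empty, "s3": good}, grid, track)
        assert m.sample_ids == ["s1", "s3"]
        assert m.depth.shape == (grid.n_bins, 2)

    def test_mappable_counts_and_zero_flag(self, rng):
        genome = random_genome(rng, {"c": 3000})
        track = compute_mappability(genome, 8)
        grid = make_grid({"c": 3000}, bin_size=300, step=300)
        counts = bin_mappable_counts(grid, track)
        for i, iv in enumerate(grid.intervals()):
            assert counts[i] == int(track.vectors["c"][iv.start : iv.end].sum())

    def test_tsv_round_trip_columns(self, rng, tmp_path):
        genome = random_genome(rng, {"c": 5000})
        track = compute_mappability(genome, 5)
        grid = make_grid({"c": 5000}, bin_size=1000, step=900)
        reads = table([("c", int(rng.integers(0, 4964)), 36, False) for _ in range(60)])
        m = build_signal_matrix({"a": reads, "b": reads}, grid, track)
        out = tmp_path / "m.tsv"
        m.to_tsv(out)
        df = pd.read_csv(out, sep="\t")
        assert list(df.columns) == [
            "chrom", "start", "end", "mappable", "depth:a", "depth:b",
            "multi:a", "multi:b",
        ]
        assert np.allclose(df["depth:a"], m.depth[:, 0])
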