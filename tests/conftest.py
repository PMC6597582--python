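import numpy as np
import pytest

from blacklist import GenomeSequence, compute_mappability, make_grid

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_genome(rng, lengths: dict[str, int], n_run: tuple[int, int] | None = None):
    """Random uniform-ACGT genome; optionally plant one N-run (start, len)
    in the first chromosome."""
    seqs = {}
    for i, (name, L) in enumerate(lengths.items()):
        arr = BASES[rng.integers(0, 4, size=L)].copy()
        if n_run and i == 0:
            s, l = n_run
            arr[s : s + l] = ord("N")
        seqs[name] = arr.tobytes().decode("ascii")
    return GenomeSequence(seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_genome(rng):
    return random_genome(rng, {"chr1": 5000, "chr2": 3000})


@pytest.fixture
def small_track(small_genome):
    return compute_mappability(small_genome, 5)


@pytest.fixture
def small_grid(small_genome):
    return make_grid(small_genome.lengths, bin_size=500, step=450)
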