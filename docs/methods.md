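# Methods

## Model of the artifact signal

The package treats artifact regions as a property of the genome assembly,
not of any experiment. Two mechanisms dominate:

1. **Pileup artifacts.** A sequence present in *c* copies in the sampled
   genome but collapsed to one copy in the reference receives roughly
   *c*-fold the background rate of input reads at that single reference
   locus. Collapsed tandem repeats behave this way, and NUMTs are the same
   mechanism with an unusually high effective copy number (many
   mitochondrial genomes per nucleus, plus many dispersed insertions).
2. **Mappability artifacts.** Sequence duplicated within the reference
   cannot receive uniquely aligned reads; its signal is carried by
   multimapping reads and by stretches with no uniquely mappable base.

Input (non-immunoprecipitated) libraries sample the genome approximately
uniformly, so both mechanisms are visible in any input sample regardless of
cell type. The pipeline therefore scores windows with two statistics —
reads per uniquely mappable base, and multimapping reads per million mapped
reads — and aggregates them across a panel of samples.

## Pipeline stages and conventions

**Coordinates.** 0-based half-open everywhere, including BED output.

**Mappability.** A position is uniquely mappable at read length *k* when
its *k*-mer occurs exactly once genome-wide counting both strands.
Occurrences are tallied per canonical *k*-mer (lexicographic minimum of the
*k*-mer and its reverse complement); a palindromic *k*-mer with a single
forward occurrence counts as unique, since a read of that sequence has one
genomic locus even though its strand is ambiguous. Windows containing N (or
any non-ACGT code) are never mappable. The computation is exact and
hash-based; memory is linear in the number of distinct canonical *k*-mers,
which is fine for the genome sizes this implementation targets. Default
*k* = 36, a common short-read length for input controls; it is a plain
parameter because artifact boundaries shift with read length and lists
should be built at the read length of the data they will filter.

**Binning.** Windows of `bin_size` (default 1000) start every `step`
(default 900) bases, the last window clipped at the chromosome end, so
adjacent windows share `bin_size - step` = 100 bp. The description
"1 kb windows with 100 bp overlap" is read literally as overlap = 100 bp;
step is a first-class knob for anyone preferring the denser step = 100
reading. Reads are assigned to windows by their leftmost aligned position
(a read is counted in every window covering its start); multimapping reads
are included in the depth numerator (configurable off). A window with zero
mappable bases gets depth 0 — never a division by zero — and carries a
zero-mappability flag that the caller uses instead.

**Multimapping definition.** Aligners conventionally report MAPQ 0 for
reads with multiple equally good loci, so `is_multimapping` is MAPQ <=
`multimap_mapq_max` (default 0). The threshold is exposed because MAPQ
conventions differ across aligners.

**Normalization.** Classic rank-mean quantile normalization across sample
columns: sort each column, average across columns at each rank to form the
reference distribution, assign each entry the reference value at its
within-column rank, ties receiving the mean of the reference values over
the tied rank range. Both metrics are normalized independently and
genome-wide (not per chromosome). The per-window standard value is the
empirical 50% quantile across samples (linear interpolation; mean of the
two central values for even panels). The median is what makes the track
cell-type agnostic: with *n* samples, up to floor((n-1)/2) samples can carry
arbitrary excess signal at a window without moving it.

One numerical subtlety: when a window has value 0 in *every* sample (no
multimapping read anywhere, or no mappable base), tie-averaging can impute
a small positive normalized value into it. Such windows carry no evidence,
so their standard value is pinned to exactly 0; this keeps them out of the
caller's signal distribution, which matters on sparse genomes where the
multimapping metric is zero almost everywhere.

## Calling

Per track, the flag threshold is the value of the k-th largest entry of the
nonzero-signal distribution with k = ceil(n_nonzero * (1 - flag_quantile));
every window at or above it is flagged (ties included). Computing the
threshold over nonzero signal is deliberate: on a zero-inflated track the
raw 99.9th percentile can be 0, which would flag everything. Flagged
windows grow across adjacent windows that stay at or above the
extend_quantile threshold or are zero-mappability, to a fixed point;
regions closer than join_distance are unioned; overlapping windows collapse
to maximal intervals.

The depth track produces `High Signal Region` calls. The multimapping
track, seeded by its flagged windows *plus* all zero-mappability windows,
produces `Low Mappability` calls — assembly gaps (N-runs) and duplicated
sequence thus enter the list through the mappability route without any
special-casing of gap annotations (an optional gaps BED would only
annotate, never change calls). A locus qualifying under both tracks yields
two overlapping records, one per label, matching the one-label-per-record
convention of released exclusion lists; `collapse_blacklist` (CLI
`--collapse`) unions them label-free. Excluded chromosomes present in the
genome are emitted whole as `High Signal Region`.

Two readings in the source description were resolved as follows: the
flag/extend pair follows the procedural description (flag at top 0.1%,
extend at top 1%) rather than the looser "top 1% are artifacts" summary,
with both quantiles configurable; and "mappability" as a flagging criterion
is read as the multimapping-read metric (the second computed statistic),
not the mappability track itself.

**Threshold scaling.** The default quantiles (0.999 / 0.99) presume
artifact loci occupy far less of the genome than the flag tail itself —
true for mammalian assemblies, where known lists cover well under 1% of
windows. On a small genome where artifacts occupy a known or expected
fraction *f* of the sequence, the tails must sit just outside that
fraction; `suggested_config` encodes this as flag at 1 - f and extend at
1 - 1.2 f (capped at the published defaults), with *f* taken from the
planted high-depth loci of a synthetic panel. The end-to-end tests and the
acceptance script use exactly this scaling; nothing else about the
procedure changes with genome size.

## Synthetic panels

`SyntheticSpec` defaults define the benchmark: a 1 Mb uniform-random ACGT
genome, 20 samples, Poisson background at 0.05 reads/base (about 125,000
reads per sample, input-like coverage for a toy genome), five 5 kb
collapsed repeats at copy number 50, one 3 kb NUMT at copy number 100, one
duplicated 4 kb segment pair, read length 36, seed 1. Planted loci are
placed one per equal-width slot of the genome with at least 40 kb
separation so that calls cannot merge across loci under the default 20 kb
join distance. Collapsed repeats and the NUMT draw unique reads at *c* x
background inside the locus; the duplicated pair places one random segment
at two reference loci and draws multimapping reads at background rate per
copy, each read assigned to one copy uniformly at random — so duplicated
reads are the panel's only multimappers, and the duplication genuinely
zeroes the mappability track. Options add a mitochondrial chromosome
(pre-filter testing) and a single-sample CNV (median-robustness testing).
One master seed spawns one placement stream plus one independent substream
per sample, so a spec regenerates byte-identical panels.

What the simulator does **not** model: sequencing error and actual read
sequences (no aligner runs — reads are positions plus a multimap flag),
fragment-length structure, GC bias, chromatin accessibility structure in
input coverage, and partially-diverged repeats with intermediate
mappability. Passing the recovery tests therefore shows the statistics,
normalization and caller behave correctly on cleanly planted mechanisms; it
does not by itself validate performance on real assemblies, where artifact
boundaries are fuzzier and input coverage is not uniform.

## Numerical and degenerate-input choices

* Tail counts use k = n - floor(n q + 1e-6) — algebraically ceil(n(1-q)),
  immune to upward float spill of n(1-q).
* Quantile normalization of a single sample is the identity (logged);
  calling requires at least two samples and refuses otherwise.
* An all-zero track flags nothing; an all-equal nonzero track flags every
  nonzero window (degenerate, logged).
* Empty samples (no reads after chromosome exclusion) are dropped from the
  panel with a warning rather than crashing the run.
* Windows shorter than *k* at chromosome ends have no mappable start by
  construction (the track pads the final k-1 positions False).
* Determinism: identical inputs and configuration produce byte-identical
  BED output; the run manifest differs only in its timestamp.

## Known limitations

* The k-mer hash holds the genome's canonical k-mers in memory; a 3 Gb
  genome at k = 36 wants a two-bit-packed or disk-backed index that this
  implementation does not provide.
* Paired-end data is treated as independent mates; CIGAR-aware span
  assignment and fragment extension are out of scope.
* Per-cell-type lists, WGS/RNA-seq filtering and assembly liftover are
  non-goals: depth excess is not an artifact signature in WGS, coding
  regions barely intersect these lists, and exclusion lists are
  assembly-specific by construction.
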