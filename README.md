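# blacklist

Genome exclusion-list ("blacklist") calling from panels of ChIP-seq input
controls.

Short-read functional genomics assays (ChIP-seq, ATAC-seq, DNase-seq)
consistently pile anomalous signal onto a small set of genomic regions —
collapsed repeats, nuclear mitochondrial insertions (NUMTs), and poorly
mappable repetitive sequence — regardless of cell type or antibody. Peaks
called in these regions are assembly artifacts, not biology, and they
distort correlation analyses and quality metrics until they are filtered
out. This package identifies such regions directly from non-immunoprecipitated
"input" control sequencing, producing a BED exclusion list for an assembly,
plus the tooling to apply it to peak sets.

## Method

For every 1 kb window laid every 900 bp across each chromosome (adjacent
windows share 100 bp), and for each input sample *s*, two statistics are
computed:

* **read depth** — reads starting in the window per uniquely mappable base,
  where a base is uniquely mappable if a read of length *k* (default 36)
  starting there matches exactly one genomic locus over both strands;
* **multimapping rate** — reads with ambiguous alignments (MAPQ 0) starting
  in the window, per million mapped reads in the sample.

Mitochondrial chromosomes and their reads are pre-filtered and emitted as
whole-chromosome exclusion records. Each statistic is quantile-normalized
across samples (classic rank-mean transform) and each window is summarized
by the median across samples — a cell-type-agnostic signal that a
copy-number variant or a failed library in any single sample cannot move.

Windows in the top 0.1% of either track are flagged; flagged windows extend
across neighbors that stay in the top 1% or that have no uniquely mappable
base at all; regions within 20 kb are combined. Depth-track calls are
labeled `High Signal Region`, multimapping-track calls (additionally seeded
by zero-mappability windows) `Low Mappability`. All thresholds are
configurable; the percentile thresholds are operating points relative to
genome size and should be widened on small genomes (see
`docs/methods.md`).

## Worked example

The built-in simulator generates a genome with planted artifacts and a
matched input panel, so the whole pipeline can be exercised end to end:

```
blacklist simulate --out sim/            # 1 Mb genome, 20 samples, seed 1
blacklist call --fasta sim/genome.fa \
    $(for f in sim/*.alignments.tsv; do echo --inputs $f; done) \
    --flag-q 0.972 --extend-q 0.9664 --out sim/blacklist.bed
```

The call step logs `{"High Signal Region": 6, "Low Mappability": 2}` and
writes `sim/blacklist.bed`:

```
chr1	20700	27100	High Signal Region
chr1	200700	206200	High Signal Region
chr1	335700	342100	High Signal Region
chr1	408600	414100	High Signal Region
chr1	585900	592300	High Signal Region
chr1	697500	701200	High Signal Region
chr1	814500	818200	Low Mappability
chr1	921600	924400	Low Mappability
```

The six `High Signal Region` records are the five planted collapsed repeats
(copy number 50) and the planted NUMT (copy number 100); the two
`Low Mappability` records are the two reference copies of the planted
duplicated segment, which destroy unique mappability and emit only
multimapping reads. Each call overlaps its planted region with Jaccard
0.70–0.93. `blacklist filter --peaks peaks.bed --blacklist sim/blacklist.bed
--out kept.bed` then removes any peak overlapping a call by one or more
bases.

The same run is available as a library one-liner:

```python
import blacklist as bl
truth = bl.generate(bl.SyntheticSpec())
res = bl.call_from_tables(truth.genome,
                          dict(zip(truth.sample_ids, truth.samples)),
                          bl.suggested_config(truth.spec))
```

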