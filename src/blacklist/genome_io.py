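"""Readers and writers for the standard formats the pipeline touches.

All coordinates are 0-based half-open (BED convention), everywhere:
internally, in alignment tables, and in BED output.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import pyfaidx
import pysam

logger = logging.getLogger("blacklist")

#: columns of the plain-text alignment dialect (TSV, no header)
ALIGNMENT_COLUMNS = ("chrom", "start", "read_length", "is_multimapping")


class FileFormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval, optionally named (BED4 carrier)."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class AlignmentRecord:
    """A mapped read reduced to what the pipeline consumes."""

    chrom: str
    start: int
    read_length: int
    is_multimapping: bool


@dataclass
class GenomeSequence:
    """Named chromosomes with uppercase nucleotide strings.

    Chromosome order is the order of appearance in the source file and is
    preserved through the whole pipeline (bins, BED output).
    """

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequences = {name: seq.upper() for name, seq in self.sequences.items()}

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def subset(self, chroms: Iterable[str]) -> "GenomeSequence":
        return GenomeSequence({c: self.sequences[c] for c in chroms})


def read_fasta(path: str | os.PathLike) -> GenomeSequence:
    """Load a (possibly multi-line) FASTA file into memory.

    The header token before the first whitespace is the chromosome name;
    lowercase sequence is normalized to uppercase. Duplicate names, empty
    files and malformed headers raise :class:`FileFormatError`.
    """
    try:
        fa = pyfaidx.Fasta(
            str(path),
            as_raw=True,
            sequence_always_upper=True,
            rebuild=True,
            build_index=True,
        )
    except (pyfaidx.FastaIndexingError, ValueError, IOError) as exc:
        raise FileFormatError(f"cannot parse FASTA {path}: {exc}") from exc
    try:
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()
    if not seqs:
        raise FileFormatError(f"FASTA {path} contains no records")
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Two-column TSV of chromosome name and length, order preserved."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FileFormatError(f"{path}:{lineno}: expected 2 columns")
            name = fields[0]
            if name in sizes:
                raise FileFormatError(f"{path}:{lineno}: duplicate chromosome {name}")
            try:
                sizes[name] = int(fields[1])
            except ValueError as exc:
                raise FileFormatError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
    return sizes


def _parse_bool(token: str, where: str) -> bool:
    t = token.strip().lower()
    if t in ("0", "false", "f"):
        return False
    if t in ("1", "true", "t"):
        return True
    raise FileFormatError(f"{where}: cannot parse boolean {token!r}")


def _detect_format(path: str | os.PathLike) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return "sam_bam" if ext in (".sam", ".bam") else "tsv"


def read_alignments(
    path: str | os.PathLike,
    format: str = "auto",
    *,
    multimap_mapq_max: int = 0,
    chrom_lengths: Mapping[str, int] | None = None,
) -> Iterator[AlignmentRecord]:
    """Stream mapped reads from a SAM/BAM file or the 4-column TSV dialect.

    Unmapped records are skipped. For SAM/BAM, a read is flagged
    multimapping when its MAPQ is <= ``multimap_mapq_max`` (default 0:
    the conventional aligner signal for a multi-hit read). When
    ``chrom_lengths`` is given, records on unknown chromosomes (or running
    past the chromosome end) are skipped and the skip count logged.
    """
    if format == "auto":
        format = _detect_format(path)
    if format not in ("sam_bam", "tsv"):
        raise ValueError(f"unknown alignment format {format!r}")

    n_skipped_chrom = 0

    def keep(rec: AlignmentRecord) -> bool:
        nonlocal n_skipped_chrom
        if chrom_lengths is not None:
            length = chrom_lengths.get(rec.chrom)
            if length is None or rec.start + rec.read_length > length:
                n_skipped_chrom += 1
                return False
        if rec.start < 0 or rec.read_length <= 0:
            raise FileFormatError(
                f"{path}: invalid record {rec.chrom}:{rec.start} len={rec.read_length}"
            )
        return True

    if format == "sam_bam":
        mode = "rb" if str(path).endswith(".bam") else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
            for aln in af:
                if aln.is_unmapped:
                    continue
                rl = aln.query_length or aln.infer_query_length() or 0
                rec = AlignmentRecord(
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    read_length=rl,
                    is_multimapping=aln.mapping_quality <= multimap_mapq_max,
                )
                if keep(rec):
                    yield rec
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 4:
                    raise FileFormatError(
                        f"{path}:{lineno}: expected 4 tab-separated columns, got {len(fields)}"
                    )
                try:
                    rec = AlignmentRecord(
                        chrom=fields[0],
                        start=int(fields[1]),
                        read_length=int(fields[2]),
                        is_multimapping=_parse_bool(fields[3], f"{path}:{lineno}"),
                    )
                except ValueError as exc:
                    raise FileFormatError(f"{path}:{lineno}: {exc}") from exc
                if keep(rec):
                    yield rec

    if n_skipped_chrom:
        logger.warning(
            "%s: skipped %d records on chromosomes absent from the genome "
            "(or out of bounds)",
            path,
            n_skipped_chrom,
        )


def read_alignment_table(
    path: str | os.PathLike,
    format: str = "auto",
    *,
    multimap_mapq_max: int = 0,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Load alignments into a DataFrame with :data:`ALIGNMENT_COLUMNS`.

    Same semantics as :func:`read_alignments`; this is the bulk container
    the binning stage consumes. The TSV dialect takes a vectorized path.
    """
    if format == "auto":
        format = _detect_format(path)
    if format == "tsv":
        return _read_tsv_table(path, chrom_lengths)
    records = read_alignments(
        path, format, multimap_mapq_max=multimap_mapq_max, chrom_lengths=chrom_lengths
    )
    df = pd.DataFrame(records, columns=ALIGNMENT_COLUMNS)
    if df.empty:
        df = df.astype(
            {"chrom": str, "start": int, "read_length": int, "is_multimapping": bool}
        )
    return df


_BOOL_TOKENS = {
    "0": False, "1": True,
    "false": False, "true": True,
    "f": False, "t": True,
}


def _read_tsv_table(
    path: str | os.PathLike, chrom_lengths: Mapping[str, int] | None
) -> pd.DataFrame:
    empty = pd.DataFrame(columns=ALIGNMENT_COLUMNS).astype(
        {"chrom": str, "start": int, "read_length": int, "is_multimapping": bool}
    )
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=ALIGNMENT_COLUMNS,
            dtype={"chrom": str, "is_multimapping": str},
        )
    except pd.errors.EmptyDataError:
        return empty
    except (ValueError, pd.errors.ParserError) as exc:
        raise FileFormatError(f"cannot parse alignment TSV {path}: {exc}") from exc
    if df.isna().any().any():
        raise FileFormatError(f"{path}: missing fields in alignment TSV")
    try:
        df["start"] = df["start"].astype(np.int64)
        df["read_length"] = df["read_length"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FileFormatError(f"{path}: non-integer coordinates: {exc}") from exc
    flags = df["is_multimapping"].str.strip().str.lower().map(_BOOL_TOKENS)
    if flags.isna().any():
        bad = df.loc[flags.isna(), "is_multimapping"].iloc[0]
        raise FileFormatError(f"{path}: cannot parse boolean {bad!r}")
    df["is_multimapping"] = flags.astype(bool)
    if (df["start"] < 0).any() or (df["read_length"] <= 0).any():
        raise FileFormatError(f"{path}: invalid start or read length")
    if chrom_lengths is not None:
        lengths = df["chrom"].map(chrom_lengths)
        ok = lengths.notna() & (df["start"] + df["read_length"] <= lengths.fillna(0))
        dropped = len(df) - int(ok.sum())
        if dropped:
            logger.warning(
                "%s: skipped %d records on chromosomes absent from the genome "
                "(or out of bounds)",
                path,
                dropped,
            )
            df = df[ok].reset_index(drop=True)
    return df


def write_alignment_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    out = table[list(ALIGNMENT_COLUMNS)].copy()
    out["is_multimapping"] = out["is_multimapping"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


def _check_bed_sorted(regions: list[GenomicInterval]) -> None:
    seen_chroms: list[str] = []
    last_start: dict[str, int] = {}
    last_end_by_label: dict[tuple[str, str | None], int] = {}
    for iv in regions:
        if iv.chrom not in last_start:
            if iv.chrom in seen_chroms:
                raise ValueError(f"BED intervals not grouped by chromosome: {iv.chrom}")
            seen_chroms.append(iv.chrom)
            last_start[iv.chrom] = -1
        if iv.start < last_start[iv.chrom]:
            raise ValueError(
                f"BED intervals not sorted by start on {iv.chrom} at {iv.start}"
            )
        last_start[iv.chrom] = iv.start
        key = (iv.chrom, iv.name)
        if iv.start < last_end_by_label.get(key, 0):
            raise ValueError(
                f"overlapping intervals with label {iv.name!r} on {iv.chrom}"
            )
        last_end_by_label[key] = max(last_end_by_label.get(key, 0), iv.end)


def write_bed(regions: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """Write BED (4 columns when named, 3 otherwise), no header.

    Input must be grouped by chromosome and sorted by start, with no
    overlap between intervals sharing a label.
    """
    regions = list(regions)
    _check_bed_sorted(regions)
    with open(path, "w") as fh:
        for iv in regions:
            if iv.name is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FileFormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                out.append(
                    GenomicInterval(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        name=fields[3] if len(fields) > 3 else None,
                    )
                )
            except ValueError as exc:
                raise FileFormatError(f"{path}:{lineno}: {exc}") from exc
    return out
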