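"""End-to-end wiring: mappability -> binning -> normalization -> calling.

The stages are pure functions of their inputs; this module composes them,
adds file IO, and records a run manifest so a run can be audited and
reproduced. Mappability tracks (the slow stage) are optionally cached on
disk keyed by a content hash of the FASTA and the read length.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .binning import build_signal_matrix, make_grid
from .caller import (
    BlacklistConfig,
    BlacklistRegion,
    blacklist_to_intervals,
    call_blacklist,
    collapse_blacklist,
)
from .genome_io import GenomeSequence, read_alignment_table, read_fasta, write_bed
from .mappability import MappabilityTrack, compute_mappability
from .normalization import normalize_signal

logger = logging.getLogger("blacklist")


@dataclass
class PipelineResult:
    regions: list[BlacklistRegion]
    manifest: dict


def _cached_mappability(
    genome: GenomeSequence, k: int, cache_dir: str | os.PathLike | None
) -> MappabilityTrack:
    if cache_dir is None:
        return compute_mappability(genome, k)
    h = hashlib.sha256()
    h.update(str(k).encode())
    for name, seq in genome.sequences.items():
        h.update(name.encode())
        h.update(seq.encode())
    path = os.path.join(cache_dir, f"mappability_{h.hexdigest()[:16]}.npz")
    if os.path.exists(path):
        with np.load(path) as npz:
            return MappabilityTrack(
                k=k, vectors={name: npz[name] for name in npz.files}
            )
    track = compute_mappability(genome, k)
    os.makedirs(cache_dir, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=cache_dir, suffix=".npz")
    os.close(fd)
    np.savez_compressed(tmp, **track.vectors)
    os.replace(tmp, path)
    return track


def call_from_tables(
    genome: GenomeSequence,
    samples: dict[str, pd.DataFrame],
    config: BlacklistConfig,
    *,
    track: MappabilityTrack | None = None,
    cache_dir: str | os.PathLike | None = None,
) -> PipelineResult:
    """Core in-memory pipeline over already-loaded alignment tables."""
    if len(samples) < 2:
        raise ValueError(
            "blacklist calling requires >= 2 input samples; "
            "single-sample mode is unsupported"
        )
    analysis_chroms = [
        c for c in genome.chrom_names if c not in config.exclude_chroms
    ]
    if not analysis_chroms:
        raise ValueError("every chromosome is excluded; nothing to analyze")
    work = genome.subset(analysis_chroms)
    if track is None:
        track = _cached_mappability(work, config.read_length, cache_dir)
    grid = make_grid(work.lengths, config.bin_size, config.step)
    logger.info("grid: %d bins over %d chromosomes", grid.n_bins, len(grid.chroms))
    matrix = build_signal_matrix(samples, grid, track, config.exclude_chroms)
    logger.info("binned %d samples", len(matrix.sample_ids))
    norm = normalize_signal(matrix, config.quantile)
    regions = call_blacklist(norm, config, genome.lengths)
    per_label: dict[str, int] = {}
    for r in regions:
        per_label[r.label] = per_label.get(r.label, 0) + 1
    logger.info("called %s regions", per_label)
    manifest = {
        "tool": "blacklist",
        "version": __version__,
        "config": config.to_dict(),
        "chromosomes": genome.lengths,
        "n_bins": grid.n_bins,
        "samples": {
            sid: {
                "retained": matrix.retained[sid],
                "excluded_chrom_reads": matrix.excluded[sid],
            }
            for sid in matrix.sample_ids
        },
        "regions_per_label": per_label,
        "blacklisted_bases": sum(len(iv) for iv in collapse_blacklist(regions))
        if regions
        else 0,
    }
    return PipelineResult(regions=regions, manifest=manifest)


def run_pipeline(
    fasta: str | os.PathLike,
    alignment_paths: list[str | os.PathLike],
    config: BlacklistConfig,
    out_bed: str | os.PathLike,
    *,
    manifest_path: str | os.PathLike | None = None,
    cache_dir: str | os.PathLike | None = None,
) -> PipelineResult:
    """File-level pipeline: FASTA + alignment files in, BED + manifest out.

    The manifest is written atomically next to the BED; re-running with
    identical inputs and config reproduces identical outputs (the manifest
    timestamp aside).
    """
    if len(alignment_paths) < 2:
        raise ValueError(
            "blacklist calling requires >= 2 input samples; "
            "single-sample mode is unsupported"
        )
    genome = read_fasta(fasta)
    samples: dict[str, pd.DataFrame] = {}
    for path in alignment_paths:
        sid = os.path.basename(str(path)).split(".")[0]
        if sid in samples:
            sid = os.path.basename(str(path))
        samples[sid] = read_alignment_table(
            path,
            multimap_mapq_max=config.multimap_mapq_max,
            chrom_lengths=genome.lengths,
        )
    result = call_from_tables(genome, samples, config, cache_dir=cache_dir)

    if config.collapse:
        write_bed(collapse_blacklist(result.regions), out_bed)
    else:
        write_bed(blacklist_to_intervals(result.regions), out_bed)

    result.manifest["inputs"] = {
        "fasta": str(fasta),
        "alignments": [str(p) for p in alignment_paths],
        "out_bed": str(out_bed),
    }
    import datetime

    result.manifest["timestamp"] = datetime.datetime.now(
        datetime.timezone.utc
    ).isoformat()
    if manifest_path is None:
        manifest_path = str(out_bed) + ".manifest.json"
    fd, tmp = tempfile.mkstemp(dir=os.path.dirname(os.path.abspath(manifest_path)))
    with os.fdopen(fd, "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, manifest_path)
    return result
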