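"""Contextual signal features: per-bin mean coverage around each locus.

A locus is described by the center bin plus ``bin_number`` bins on each side
(``2*bin_number + 1`` bins total, spanning ``bin_size*(2*bin_number+1)``
bases). For every mark the per-bin mean signal is recorded, and the per-mark
blocks are concatenated in the canonical mark order, giving e.g. a
9 x 21 = 189-dimensional vector at bin_size 40 kb, bin_number 10.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    BinConfig,
    EdgeError,
    FeatureMatrix,
    GenomicLocus,
    ValidationError,
)
from .io import SignalTrack

__all__ = [
    "region_length",
    "make_bins",
    "bin_signal",
    "signal_vector",
    "signal_matrix",
    "zscore_by_factor",
]

logger = logging.getLogger(__name__)


def region_length(config: BinConfig) -> int:
    """Total bases covered by a locus context: bin_size * (2*bin_number + 1)."""
    return config.region_length


def make_bins(
    center: GenomicLocus, config: BinConfig, chrom_length: int | None = None
) -> list[GenomicLocus]:
    """Tile the context window into ordered bins, upstream to downstream.

    ``center`` must already be one bin long (see
    :func:`tadbound.loci.center_bin`); the (bin_number+1)-th returned interval
    is the center itself.
    """
    if len(center) != config.bin_size:
        raise ValidationError(
            f"center {center.id} has length {len(center)}, expected {config.bin_size}"
        )
    first = center.start - config.bin_number * config.bin_size
    last = center.end + config.bin_number * config.bin_size
    if first < 0:
        raise EdgeError(f"{center.id}: context starts at {first} < 0")
    if chrom_length is not None and last > chrom_length:
        raise EdgeError(
            f"{center.id}: context ends at {last} > chromosome length {chrom_length}"
        )
    return [
        GenomicLocus(
            center.chrom,
            first + i * config.bin_size,
            first + (i + 1) * config.bin_size,
            center.label,
        )
        for i in range(config.n_bins)
    ]


def bin_signal(track: SignalTrack, interval: GenomicLocus) -> float:
    """Mean track value over one bin (uncovered bases use the missing policy)."""
    return track.mean(interval.chrom, interval.start, interval.end)


def signal_vector(
    tracks: Sequence[SignalTrack],
    locus: GenomicLocus,
    config: BinConfig,
    chrom_length: int | None = None,
) -> np.ndarray:
    """Concatenated per-mark bin-mean vector for one (center-bin) locus.

    Length is ``len(tracks) * (2*bin_number + 1)``; per-track blocks are
    contiguous in the given track order, bins upstream to downstream.
    """
    if not tracks:
        raise ValidationError("at least one track is required")
    bins = make_bins(locus, config, chrom_length)
    return np.array(
        [bin_signal(t, b) for t in tracks for b in bins], dtype=float
    )


def signal_column_names(marks: Sequence[str], config: BinConfig) -> list[str]:
    return [f"{m}@{off}" for m in marks for off in config.offsets]


def signal_matrix(
    tracks: Sequence[SignalTrack],
    loci: Sequence[GenomicLocus],
    config: BinConfig,
    chrom_lengths: Mapping[str, int] | None = None,
) -> FeatureMatrix:
    """Build the loci x (marks*bins) design matrix.

    Loci whose context window exits the chromosome are dropped with a logged
    warning rather than zero-padded; the row order of the survivors follows
    the input order. Labels are 1 for boundaries, 0 otherwise.
    """
    marks = tuple(t.name for t in tracks)
    rows, labels, kept = [], [], []
    dropped = 0
    for locus in loci:
        clen = chrom_lengths.get(locus.chrom) if chrom_lengths else None
        try:
            rows.append(signal_vector(tracks, locus, config, clen))
        except EdgeError as exc:
            dropped += 1
            logger.warning("dropping locus at the chromosome edge: %s", exc)
            continue
        labels.append(1 if locus.label == "boundary" else 0)
        kept.append(locus)
    if dropped:
        logger.warning("dropped %d of %d loci at chromosome edges", dropped, len(loci))
    df = pd.DataFrame(
        np.array(rows).reshape(len(rows), -1) if rows else
        np.empty((0, len(marks) * config.n_bins)),
        index=[l.id for l in kept],
        columns=signal_column_names(marks, config),
    )
    return FeatureMatrix(df, np.array(labels, dtype=int), marks,
                         config.bin_number, None, tuple(kept))


def zscore_by_factor(matrix: FeatureMatrix) -> FeatureMatrix:
    """Standardise each sample within each mark block (z-score by factor type).

    Every row's per-mark block is centred to mean 0 and scaled to sample
    standard deviation 1 (ddof=1); blocks with zero variance map to all-zeros.
    The k-mer block, if present, is left untouched.
    """
    data = matrix.data.copy()
    for mark in matrix.marks:
        sl = matrix.mark_block(mark)
        block = data.iloc[:, sl].to_numpy(dtype=float)
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True) if block.shape[1] > 1 else np.zeros_like(mu)
        centered = block - mu
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
        data.iloc[:, sl] = z
    return FeatureMatrix(
        data, matrix.labels.copy(), matrix.marks, matrix.bin_number,
        matrix.kmer_k, matrix.loci,
    )
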