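"""End-to-end feature extraction: loci -> matched design matrix.

Composes the stages in the standard order: reduce boundary calls to their
center bins, sample frequency-matched negatives, build the contextual signal
matrix, and optionally append the center-bin k-mer block.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .core import BinConfig, FeatureMatrix, GenomicLocus, KmerSpec
from .io import ContactFrequencyTable, GenomeSequence, SignalTrack
from .loci import SamplingConfig, center_bin, sample_negatives
from .sequence import append_sequence_block
from .signal import signal_matrix

__all__ = ["extract_features"]


def extract_features(
    tracks: Sequence[SignalTrack],
    boundaries: Sequence[GenomicLocus],
    contacts: ContactFrequencyTable,
    config: BinConfig,
    genome: GenomeSequence | None = None,
    kmer: KmerSpec | None = None,
    sampling: SamplingConfig = SamplingConfig(),
    chrom_lengths: Mapping[str, int] | None = None,
) -> FeatureMatrix:
    """Build the labelled design matrix for a set of boundary calls.

    Returns positives (center-binned boundaries) stacked above the matched
    negatives; the k-mer block is appended when both ``genome`` and ``kmer``
    are given. ``chrom_lengths`` defaults to the genome's lengths when a
    genome is supplied.
    """
    if chrom_lengths is None and genome is not None:
        chrom_lengths = {c: genome.length(c) for c in genome.chroms}
    centers = [center_bin(b, config.bin_size) for b in boundaries]
    negatives = sample_negatives(
        list(boundaries), contacts, sampling, config.bin_size,
        chrom_lengths=chrom_lengths, context_bins=config.bin_number,
    )
    matrix = signal_matrix(tracks, centers + negatives, config, chrom_lengths)
    if kmer is not None:
        if genome is None:
            raise ValueError("k-mer features require a genome sequence")
        matrix = append_sequence_block(matrix, genome, kmer, config.bin_size)
    return matrix
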