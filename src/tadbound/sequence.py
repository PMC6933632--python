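"""k-mer frequency features from the center-bin DNA sequence.

All 4^k words over {A, C, G, T} are counted in sliding windows of the center
bin's sequence and normalised by the window count ``m - k + 1``. Windows
containing ``N`` are counted in no entry, so the frequencies sum to at most 1,
with equality exactly for N-free sequences. The k-mer vector is appended
after the signal block, columns named by the literal word in lexicographic
order (AAA ... TTT for k=3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    EdgeError,
    FeatureMatrix,
    GenomicLocus,
    KmerSpec,
    ValidationError,
)
from .io import GenomeSequence
from .loci import center_bin

__all__ = ["kmer_frequencies", "center_bin_sequence", "append_sequence_block"]

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


def kmer_frequencies(sequence: str, spec: KmerSpec) -> np.ndarray:
    """Frequency of every k-mer in lexicographic order.

    Each of the ``m - k + 1`` windows increments the count of its word unless
    it contains a non-ACGT symbol; the denominator is always ``m - k + 1``.
    """
    m, k = len(sequence), spec.k
    if m < k:
        raise ValidationError(f"sequence of length {m} is shorter than k={k}")
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    # rolling base-4 rank over valid windows
    valid = codes >= 0
    ranks = np.zeros(m - k + 1, dtype=np.int64)
    ok = np.ones(m - k + 1, dtype=bool)
    for j in range(k):
        ranks = ranks * 4 + np.where(valid[j : m - k + 1 + j], codes[j : m - k + 1 + j], 0)
        ok &= valid[j : m - k + 1 + j]
    counts = np.bincount(ranks[ok], minlength=spec.n_words)
    return counts.astype(float) / (m - k + 1)


def center_bin_sequence(
    genome: GenomeSequence, locus: GenomicLocus, bin_size: int
) -> str:
    """Upper-case sequence of the grid bin containing the locus midpoint."""
    cb = center_bin(locus, bin_size)
    try:
        return genome.fetch(cb.chrom, cb.start, cb.end)
    except ValidationError as exc:
        raise EdgeError(str(exc)) from exc


def append_sequence_block(
    matrix: FeatureMatrix, genome: GenomeSequence, spec: KmerSpec, bin_size: int
) -> FeatureMatrix:
    """Append the 4^k k-mer columns to a signal feature matrix.

    Rows must carry their loci (as built by
    :func:`tadbound.signal.signal_matrix`) so each center-bin sequence can be
    resolved; a row whose bin falls outside the genome raises an
    :class:`EdgeError` naming it.
    """
    if matrix.kmer_k is not None:
        raise ValidationError("matrix already carries a k-mer block")
    if len(matrix.data) and len(matrix.loci) != len(matrix.data):
        raise ValidationError("matrix rows are missing locus annotations")
    freqs = []
    for locus in matrix.loci:
        try:
            seq = center_bin_sequence(genome, locus, bin_size)
        except EdgeError as exc:
            raise EdgeError(f"row {locus.id}: {exc}") from exc
        freqs.append(kmer_frequencies(seq, spec))
    block = pd.DataFrame(
        np.array(freqs).reshape(len(freqs), -1) if freqs else
        np.empty((0, spec.n_words)),
        index=matrix.data.index,
        columns=spec.words,
    )
    return FeatureMatrix(
        pd.concat([matrix.data, block], axis=1),
        matrix.labels.copy(),
        matrix.marks,
        matrix.bin_number,
        spec.k,
        matrix.loci,
    )
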