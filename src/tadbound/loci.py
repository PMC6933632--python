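"""Locus selection: center-bin reduction and matched negative sampling.

Boundary calls often span several bins; each is reduced to the single
bin-grid bin containing its midpoint. Non-boundary loci are then drawn at
random from the genome so that each negative matches one boundary in Hi-C
interaction frequency, which removes contact intensity as a trivial
confounder between the classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import (
    BOUNDARY,
    NON_BOUNDARY,
    GenomicLocus,
    MatchingError,
    ValidationError,
)
from .io import ContactFrequencyTable

__all__ = ["SamplingConfig", "center_bin", "sample_negatives"]


@dataclass(frozen=True)
class SamplingConfig:
    """Controls frequency-matched negative sampling.

    tolerance : maximal admissible frequency difference for a match;
        interpreted relative to the boundary's frequency when
        ``relative`` is true (default 10% relative).
    exclusion_margin : minimal base-pair gap between a sampled negative and
        any boundary interval; ``None`` means one bin_size.
    seed : seed for the sampling stream.
    """

    tolerance: float = 0.1
    relative: bool = True
    exclusion_margin: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValidationError("tolerance must be non-negative")
        if self.exclusion_margin is not None and self.exclusion_margin < 0:
            raise ValidationError("exclusion_margin must be non-negative")


def center_bin(
    locus: GenomicLocus, bin_size: int, chrom_length: int | None = None
) -> GenomicLocus:
    """Reduce a locus to the genome-grid bin containing its midpoint.

    The grid is the genome-wide tiling ``[i*bin_size, (i+1)*bin_size)``; the
    returned interval is the grid bin the locus midpoint falls into, with the
    label preserved.
    """
    if bin_size <= 0:
        raise ValidationError(f"bin_size must be positive, got {bin_size}")
    mid = locus.midpoint
    if chrom_length is not None and mid >= chrom_length:
        raise ValidationError(
            f"{locus.id}: midpoint {mid} outside chromosome of length {chrom_length}"
        )
    start = (mid // bin_size) * bin_size
    return GenomicLocus(locus.chrom, start, start + bin_size, locus.label)


def sample_negatives(
    boundaries: list[GenomicLocus],
    contacts: ContactFrequencyTable,
    config: SamplingConfig,
    bin_size: int,
    chrom_lengths: Mapping[str, int] | None = None,
    context_bins: int = 0,
    paired: bool = False,
):
    """Sample one frequency-matched non-boundary locus per boundary.

    Candidates are the bins of the contact table. Matching is greedy over a
    seeded random permutation of the boundaries: each boundary claims, without
    replacement, a uniformly random candidate whose frequency differs by at
    most the configured tolerance and which lies at least ``exclusion_margin``
    bases from every boundary. When ``chrom_lengths`` and ``context_bins``
    are given, candidates whose ``context_bins``-bin context window would
    exit the chromosome are excluded up front, so every sampled negative
    survives feature extraction. With ``paired=True`` the return value is a
    list of ``(boundary_center, negative)`` tuples in the input boundary
    order instead of the bare negative list.

    Raises
    ------
    MatchingError
        If some boundary has no remaining admissible candidate; the message
        names it so the caller can widen the tolerance.
    """
    if not boundaries:
        raise ValidationError("boundaries must be nonempty")
    margin = config.exclusion_margin if config.exclusion_margin is not None else bin_size
    rng = np.random.default_rng(config.seed)

    centers = [center_bin(b, bin_size) for b in boundaries]
    bound_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in boundaries:
        bound_by_chrom.setdefault(b.chrom, []).append((b.start, b.end))
    for c in centers:
        bound_by_chrom.setdefault(c.chrom, []).append((c.start, c.end))

    flank = context_bins * bin_size
    gap = max(margin, 1)
    candidates: list[tuple[str, int, int, float]] = []
    for chrom in sorted(contacts.bins):
        starts, ends, freqs = contacts.bins[chrom]
        keep = np.ones(len(starts), dtype=bool)
        if flank:
            keep &= starts - flank >= 0
            if chrom_lengths is not None and chrom in chrom_lengths:
                keep &= ends + flank <= chrom_lengths[chrom]
        spans = bound_by_chrom.get(chrom)
        if spans:
            # candidate [s,e) conflicts with a boundary iff some boundary has
            # b_start < e+gap and b_end > s-gap; with boundaries sorted by
            # start, a prefix-max over b_end resolves this in one searchsorted
            bs = np.array(sorted(s for s, _ in spans))
            be_pref = np.maximum.accumulate(
                np.array([e for _, e in sorted(spans)])
            )
            hi = np.searchsorted(bs, ends + gap, side="left")
            conflict = (hi > 0) & (
                be_pref[np.maximum(hi - 1, 0)] > starts - gap
            )
            keep &= ~conflict
        for i in np.flatnonzero(keep):
            candidates.append((chrom, int(starts[i]), int(ends[i]), float(freqs[i])))
    if not candidates:
        raise MatchingError("no candidate bins clear of the boundaries")

    cand_freq = np.array([c[3] for c in candidates])
    available = np.ones(len(candidates), dtype=bool)

    order = rng.permutation(len(centers))
    chosen: list[GenomicLocus | None] = [None] * len(centers)
    for i in order:
        c = centers[i]
        try:
            f_b = contacts.lookup(c.chrom, c.midpoint)
        except KeyError as exc:
            raise MatchingError(
                f"boundary {c.id} is not covered by the contact table"
            ) from exc
        tol = config.tolerance * f_b if config.relative else config.tolerance
        ok = available & (np.abs(cand_freq - f_b) <= tol)
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            raise MatchingError(
                f"no unclaimed candidate within tolerance {tol:.4g} of boundary "
                f"{c.id} (frequency {f_b:.4g}); consider widening the tolerance"
            )
        j = int(rng.choice(idx))
        available[j] = False
        chrom, s, e, _ = candidates[j]
        chosen[i] = GenomicLocus(chrom, s, e, NON_BOUNDARY)

    negatives = [l for l in chosen if l is not None]
    if paired:
        return list(zip(centers, negatives))
    return negatives
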