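"""Synthetic genomes, tracks, boundaries and contact tables for testing.

The generator emulates the structure the classifier exploits: around each
planted boundary, every mark follows one of three qualitative shapes over the
context window — enrichment peaking at the center bin (most marks, CTCF
included), depletion at the center (H3K9me3), or flanking enrichment that
dips at the center (H3K4me1, H3K27me3) — on top of Gaussian noise.
Boundary center-bin sequences optionally carry a planted CTCF-core motif so
k-mer features become informative, and per-bin contact frequencies are drawn
from one distribution for boundary and background bins alike so that
frequency-matched negative sampling is always feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import BOUNDARY, BinConfig, GenomicLocus, MARK_ORDER, ValidationError
from .io import (
    ContactFrequencyTable,
    GenomeSequence,
    SignalTrack,
    write_bedgraph,
    write_loci,
)

__all__ = ["FixtureConfig", "Fixture", "generate_fixture", "DEFAULT_SHAPES"]

CENTER_PEAK = "center_peak"
CENTER_DEPLETION = "center_depletion"
FLANKING_PEAK = "flanking_peak"
CENTER_DELTA = "center_delta"  # effect confined to the center bin

#: Qualitative context shape per mark.
DEFAULT_SHAPES: dict[str, str] = {
    "CTCF": CENTER_PEAK,
    "H3K4me1": FLANKING_PEAK,
    "H3K4me2": CENTER_PEAK,
    "H3K4me3": CENTER_PEAK,
    "H3K9ac": CENTER_PEAK,
    "H3K9me3": CENTER_DEPLETION,
    "H3K27ac": CENTER_PEAK,
    "H3K27me3": FLANKING_PEAK,
    "H3K36me3": CENTER_PEAK,
}

#: CTCF core consensus with degenerate positions resolved to A.
DEFAULT_MOTIF = "CCGCGAGGAGGCAG"


class PlacementError(RuntimeError):
    """Boundaries cannot be placed with the required separation."""


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions of one synthetic dataset.

    Boundaries are kept at least two context-window lengths apart so their
    signal shapes never overlap; the effect size is the peak height of the
    shape in signal units above the baseline of 1.0.
    """

    n_chromosomes: int = 2
    chrom_length: int = 600_000
    bin_size: int = 2_000
    bin_number: int = 5
    n_boundaries: int = 24
    mark_shapes: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SHAPES)
    )
    effect_size: float = 3.0
    noise_sd: float = 1.0
    motif: str = DEFAULT_MOTIF
    motif_copies: int = 8
    plant_prob: float = 0.9
    gc: float = 0.41
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValidationError("effect_size must be non-negative")
        if not 0.0 <= self.plant_prob <= 1.0:
            raise ValidationError("plant_prob must be in [0, 1]")
        if self.chrom_length % self.bin_size:
            raise ValidationError("chrom_length must be a multiple of bin_size")

    @property
    def bin_config(self) -> BinConfig:
        return BinConfig(self.bin_size, self.bin_number)


@dataclass
class Fixture:
    """In-memory synthetic dataset plus writers for the on-disk formats."""

    config: FixtureConfig
    genome: GenomeSequence
    tracks: list[SignalTrack]
    boundaries: list[GenomicLocus]
    contacts: ContactFrequencyTable

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.genome.length(c) for c in self.genome.chroms}

    def write(self, directory) -> dict[str, Path]:
        """Emit FASTA / bedGraph / BED / TSV files; returns their paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["genome"] = directory / "genome.fasta"
        self.genome.to_fasta(paths["genome"])
        for track in self.tracks:
            p = directory / f"{track.name}.bedgraph"
            write_bedgraph(track, p)
            paths[track.name] = p
        paths["boundaries"] = directory / "boundaries.bed"
        write_loci(self.boundaries, paths["boundaries"], with_label=False)
        paths["contacts"] = directory / "contacts.tsv"
        self.contacts.to_tsv(paths["contacts"])
        return paths


def _shape_profile(kind: str, bin_number: int) -> np.ndarray:
    """Unit-height profile over offsets -bin_number..+bin_number."""
    off = np.arange(-bin_number, bin_number + 1, dtype=float)
    sigma_c = max(1.0, bin_number / 3.0)
    center = np.exp(-(off**2) / (2 * sigma_c**2))
    if kind == CENTER_PEAK:
        return center
    if kind == CENTER_DEPLETION:
        return -center
    if kind == FLANKING_PEAK:
        f0 = min(2.0, float(bin_number))
        return np.exp(-((np.abs(off) - f0) ** 2) / 2.0)
    if kind == CENTER_DELTA:
        return (off == 0).astype(float)
    raise ValidationError(f"unknown shape {kind!r}")


def _place_centers(rng: np.random.Generator, n: int, n_bins: int,
                   margin_bins: int, sep_bins: int) -> np.ndarray:
    """Random center-bin indices with pairwise separation >= sep_bins."""
    lo, hi = margin_bins, n_bins - margin_bins - 1
    usable = hi - lo + 1
    need = (n - 1) * sep_bins + 1
    if n < 1 or usable < need:
        raise PlacementError(
            f"cannot place {n} boundaries {sep_bins} bins apart in {usable} bins"
        )
    slack = usable - need
    extras = np.sort(rng.integers(0, slack + 1, size=n))
    return lo + extras + np.arange(n) * sep_bins


def generate_fixture(config: FixtureConfig = FixtureConfig()) -> Fixture:
    """Generate a reproducible synthetic dataset under ``config``."""
    rng = np.random.default_rng(config.seed)
    bc = config.bin_config
    marks = [m for m in MARK_ORDER if m in config.mark_shapes]
    if not marks:
        marks = list(config.mark_shapes)
    n_bins = config.chrom_length // config.bin_size
    sep_bins = int(np.ceil(2 * bc.region_length / config.bin_size))

    # distribute boundaries round-robin over chromosomes
    per_chrom = [config.n_boundaries // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_boundaries % config.n_chromosomes):
        per_chrom[i] += 1

    gc_half = config.gc / 2
    base_p = np.array([0.5 - gc_half, gc_half, gc_half, 0.5 - gc_half])  # A C G T

    chrom_seqs: dict[str, str] = {}
    boundaries: list[GenomicLocus] = []
    track_values: dict[str, list[tuple[str, int, int, float]]] = {m: [] for m in marks}
    contact_records: list[tuple[str, int, int, float]] = []

    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq = rng.choice(list("ACGT"), size=config.chrom_length, p=base_p)

        centers = _place_centers(rng, per_chrom[ci], n_bins,
                                 config.bin_number, sep_bins)
        # per-mark per-bin values: baseline 1.0 + boundary shape + noise
        for mark in marks:
            kind = config.mark_shapes[mark]
            baseline = 1.0 + (config.effect_size if kind == CENTER_DEPLETION else 0.0)
            values = np.full(n_bins, baseline)
            profile = config.effect_size * _shape_profile(kind, config.bin_number)
            for c in centers:
                values[c - config.bin_number : c + config.bin_number + 1] += profile
            values = np.clip(values + rng.normal(0, config.noise_sd, n_bins), 0, None)
            track_values[mark].extend(
                (chrom, int(i * config.bin_size), int((i + 1) * config.bin_size),
                 float(values[i]))
                for i in range(n_bins)
            )

        freqs = rng.uniform(5.0, 15.0, size=n_bins)
        contact_records.extend(
            (chrom, int(i * config.bin_size), int((i + 1) * config.bin_size),
             float(freqs[i]))
            for i in range(n_bins)
        )

        for c in centers:
            start = int(c) * config.bin_size
            boundaries.append(
                GenomicLocus(chrom, start, start + config.bin_size, BOUNDARY)
            )
            if config.motif and rng.random() < config.plant_prob:
                # boundaries carry clustered binding sites: several copies
                # spread over the center bin
                width = len(config.motif)
                slots = max(1, config.bin_size // max(config.motif_copies, 1))
                for c_i in range(config.motif_copies):
                    lo = c_i * slots
                    hi = min((c_i + 1) * slots, config.bin_size) - width
                    if hi <= lo:
                        continue
                    pos = start + int(rng.integers(lo, hi))
                    seq[pos : pos + width] = list(config.motif.upper())
        chrom_seqs[chrom] = "".join(seq)

    genome = GenomeSequence(chrom_seqs)
    tracks = [
        SignalTrack.from_intervals(mark, track_values[mark]) for mark in marks
    ]
    contacts = ContactFrequencyTable.from_records(contact_records)
    return Fixture(config, genome, tracks, boundaries, contacts)
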