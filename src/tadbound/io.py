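"""Readers and writers for the four input artifacts.

Loci arrive as BED (3+ tab-separated columns), coverage tracks as bedGraph,
fixed-step WIG or bigWig, the genome as FASTA, and per-bin Hi-C interaction
frequencies as a 4-column TSV. Everything is normalised into the 0-based
half-open coordinate convention of :mod:`tadbound.core` on the way in.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .core import (
    GenomicLocus,
    ParseError,
    UNLABELED,
    ValidationError,
)

__all__ = [
    "read_loci",
    "write_loci",
    "SignalTrack",
    "read_signal_track",
    "write_bedgraph",
    "GenomeSequence",
    "ContactFrequencyTable",
    "read_contact_table",
]


# ---------------------------------------------------------------------------
# loci (BED)
# ---------------------------------------------------------------------------

def read_loci(path, label: str = UNLABELED) -> list[GenomicLocus]:
    """Read a BED-like file into loci carrying ``label``.

    Only the first three columns (chrom, start, end) are used unless the file
    carries a 4th column holding a recognised label, in which case that label
    wins over the argument. Line order is preserved.
    """
    loci: list[GenomicLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            row_label = label
            if len(fields) >= 4 and fields[3] in ("boundary", "non_boundary", "unlabeled"):
                row_label = fields[3]
            try:
                loci.append(GenomicLocus(chrom, start, end, row_label))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return loci


def write_loci(loci: Iterable[GenomicLocus], path, with_label: bool = True) -> None:
    """Write loci as BED, optionally with the label as a 4th column."""
    with open(path, "w") as fh:
        for l in loci:
            if with_label:
                fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.label}\n")
            else:
                fh.write(f"{l.chrom}\t{l.start}\t{l.end}\n")


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------

@dataclass
class SignalTrack:
    """A genome-wide coverage track queryable for interval means.

    Per chromosome the track stores sorted, non-overlapping records
    ``[start, end) -> value``. Positions covered by no record take the
    ``missing`` value (default 0.0, the coverage-track convention).
    """

    name: str
    records: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    missing: float = 0.0

    def __post_init__(self) -> None:
        canon = {}
        for chrom, (starts, ends, values) in self.records.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValidationError(f"{self.name}/{chrom}: empty or inverted record")
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"{self.name}/{chrom}: overlapping records")
            if not np.isfinite(values).all():
                raise ValidationError(f"{self.name}/{chrom}: non-finite values")
            canon[chrom] = (starts, ends, values)
        self.records = canon

    @classmethod
    def from_intervals(
        cls, name: str,
        intervals: Iterable[tuple[str, int, int, float]],
        missing: float = 0.0,
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, s, e, v in intervals:
            by_chrom.setdefault(chrom, []).append((s, e, v))
        recs = {
            c: (np.array([r[0] for r in rows]),
                np.array([r[1] for r in rows]),
                np.array([r[2] for r in rows]))
            for c, rows in by_chrom.items()
        }
        return cls(name, recs, missing)

    def chrom_extent(self, chrom: str) -> tuple[int, int]:
        starts, ends, _ = self.records[chrom]
        return int(starts[0]), int(ends[-1])

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Per-base arithmetic mean over ``[start, end)``.

        Uncovered bases contribute the missing-policy value; a query on a
        chromosome absent from the track returns the missing value outright.
        """
        if end <= start:
            raise ValidationError(f"empty query [{start}, {end})")
        if chrom not in self.records:
            return self.missing
        starts, ends, values = self.records[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return self.missing
        ov = (np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start))
        covered = int(ov.sum())
        total = float(np.dot(ov, values[lo:hi]))
        total += (end - start - covered) * self.missing
        return total / (end - start)

    def iter_intervals(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in sorted(self.records):
            starts, ends, values = self.records[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)


def _read_bedgraph(path, name: str, missing: float) -> SignalTrack:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                intervals.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return SignalTrack.from_intervals(name, intervals, missing)


def _read_wig_fixed_step(path, name: str, missing: float) -> SignalTrack:
    # fixedStep declarations use 1-based starts; converted to 0-based here.
    intervals = []
    chrom, pos, step, span = None, 0, 1, 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=", 1) for tok in line.split()[1:])
                try:
                    chrom = kv["chrom"]
                    pos = int(kv["start"]) - 1
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", step))
                except (KeyError, ValueError) as exc:
                    raise ParseError(f"{path}:{lineno}: bad fixedStep header") from exc
                continue
            if chrom is None:
                raise ParseError(f"{path}:{lineno}: data before fixedStep header")
            try:
                value = float(line)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value") from exc
            intervals.append((chrom, pos, pos + span, value))
            pos += step
    return SignalTrack.from_intervals(name, intervals, missing)


def _read_bigwig(path, name: str, missing: float) -> SignalTrack:
    import pyBigWig

    intervals = []
    with pyBigWig.open(str(path)) as bw:
        for chrom in bw.chroms():
            for s, e, v in (bw.intervals(chrom) or []):
                intervals.append((chrom, s, e, v))
    return SignalTrack.from_intervals(name, intervals, missing)


_DIALECTS = {
    "bedgraph": _read_bedgraph,
    "wig_fixed_step": _read_wig_fixed_step,
    "bigwig": _read_bigwig,
}


def read_signal_track(
    path, dialect: str = "bedgraph", name: str | None = None, missing: float = 0.0
) -> SignalTrack:
    """Read a coverage track; ``dialect`` is bedgraph, wig_fixed_step or bigwig."""
    try:
        reader = _DIALECTS[dialect]
    except KeyError:
        raise ValidationError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}"
        ) from None
    if name is None:
        name = Path(path).name.split(".")[0]
    return reader(path, name, missing)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, v in track.iter_intervals():
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.12g}\n")


# ---------------------------------------------------------------------------
# genome sequence
# ---------------------------------------------------------------------------

class GenomeSequence:
    """Per-chromosome DNA over ``{A, C, G, T, N}``, upper-cased on read."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}
        for chrom, seq in self._seqs.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValidationError(f"{chrom}: unexpected symbols {sorted(bad)}")

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        from pyfaidx import Fasta

        with Fasta(str(path), rebuild=True) as fa:
            return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return exactly ``end - start`` upper-case symbols."""
        if chrom not in self._seqs:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self._seqs[chrom]) or end <= start:
            raise ValidationError(
                f"{chrom}:[{start},{end}) outside chromosome of length "
                f"{len(self._seqs[chrom])}"
            )
        return self._seqs[chrom][start:end]

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# contact frequencies
# ---------------------------------------------------------------------------

@dataclass
class ContactFrequencyTable:
    """Per-bin Hi-C interaction frequencies used for negative matching.

    Bins are non-overlapping half-open intervals per chromosome; a position
    lookup resolves to the unique bin containing it.
    """

    bins: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        canon = {}
        for chrom, (starts, ends, freqs) in self.bins.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            freqs = np.asarray(freqs, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, freqs = starts[order], ends[order], freqs[order]
            if np.any(freqs < 0):
                raise ValidationError(f"{chrom}: negative interaction frequency")
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"{chrom}: overlapping frequency bins")
            canon[chrom] = (starts, ends, freqs)
        self.bins = canon

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "ContactFrequencyTable":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, s, e, f in records:
            by_chrom.setdefault(chrom, []).append((s, e, f))
        return cls({
            c: (np.array([r[0] for r in rows]),
                np.array([r[1] for r in rows]),
                np.array([r[2] for r in rows]))
            for c, rows in by_chrom.items()
        })

    def lookup(self, chrom: str, pos: int) -> float:
        """Frequency of the bin containing ``pos``; KeyError if uncovered."""
        if chrom not in self.bins:
            raise KeyError(f"{chrom}:{pos} not covered by any frequency bin")
        starts, ends, freqs = self.bins[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= ends[i]:
            raise KeyError(f"{chrom}:{pos} not covered by any frequency bin")
        return float(freqs[i])

    def iter_bins(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in sorted(self.bins):
            starts, ends, freqs = self.bins[chrom]
            for s, e, f in zip(starts, ends, freqs):
                yield chrom, int(s), int(e), float(f)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tfrequency\n")
            for chrom, s, e, f in self.iter_bins():
                fh.write(f"{chrom}\t{s}\t{e}\t{f:.6g}\n")


def read_contact_table(path) -> ContactFrequencyTable:
    """Read a 4-column TSV (chrom, start, end, frequency); header optional."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "chrom":
                continue
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if records[-1][3] < 0:
                raise ValidationError(f"{path}:{lineno}: negative frequency")
    return ContactFrequencyTable.from_records(records)
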