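"""Core data model shared by every pipeline stage.

Coordinates are 0-based half-open throughout (BED convention): an interval
``[start, end)`` covers ``end - start`` bases and two intervals touch, but do
not overlap, when one's ``end`` equals the other's ``start``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

BOUNDARY = "boundary"
NON_BOUNDARY = "non_boundary"
UNLABELED = "unlabeled"
_LABELS = frozenset({BOUNDARY, NON_BOUNDARY, UNLABELED})

#: Canonical ordered mark panel: CTCF plus the eight histone modifications.
MARK_ORDER = (
    "CTCF",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K9ac",
    "H3K9me3",
    "H3K27ac",
    "H3K27me3",
    "H3K36me3",
)


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class EdgeError(ValueError):
    """A locus context extends beyond the chromosome."""


class MatchingError(RuntimeError):
    """No admissible frequency-matched negative exists for some boundary."""


class SchemaError(ValueError):
    """Feature schema of a saved model does not match the supplied matrix."""


@dataclass(frozen=True, order=True)
class GenomicLocus:
    """A labelled genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name (matched exactly; no ``chr`` normalisation).
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    label : str
        One of ``boundary``, ``non_boundary``, ``unlabeled``.
    """

    chrom: str
    start: int
    end: int
    label: str = UNLABELED

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be nonempty")
        if self.start < 0:
            raise ValidationError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start: [{self.start}, {self.end})"
            )
        if self.label not in _LABELS:
            raise ValidationError(f"unknown label {self.label!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class BinConfig:
    """Bin geometry: a center bin plus ``bin_number`` flanking bins per side.

    The full context window spans ``bin_size * (2 * bin_number + 1)`` bases.
    """

    bin_size: int = 40_000
    bin_number: int = 10

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError(f"bin_size must be positive, got {self.bin_size}")
        if self.bin_number < 0:
            raise ValidationError(
                f"bin_number must be non-negative, got {self.bin_number}"
            )

    @property
    def n_bins(self) -> int:
        return 2 * self.bin_number + 1

    @property
    def region_length(self) -> int:
        return self.bin_size * self.n_bins

    @property
    def offsets(self) -> range:
        """Bin offsets upstream to downstream, center at 0."""
        return range(-self.bin_number, self.bin_number + 1)


@dataclass(frozen=True)
class KmerSpec:
    """k-mer feature definition over the DNA alphabet ``{A, C, G, T}``.

    Words are indexed lexicographically (AA.. < AC.. < ... < TT..) and
    frequencies are normalised by the number of windows ``m - k + 1`` in a
    length-``m`` sequence, regardless of how many windows contain ``N``.
    """

    k: int = 3

    ALPHABET = "ACGT"

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 5:
            raise ValidationError(f"k must be in 1..5, got {self.k}")

    @property
    def n_words(self) -> int:
        return 4**self.k

    @property
    def words(self) -> list[str]:
        """All 4^k words in lexicographic order."""
        words = [""]
        for _ in range(self.k):
            words = [w + c for w in words for c in self.ALPHABET]
        return words

    def rank(self, word: str) -> int:
        """Lexicographic rank of ``word`` in 0..4^k-1."""
        if len(word) != self.k:
            raise ValidationError(f"word {word!r} is not length {self.k}")
        r = 0
        for c in word.upper():
            i = self.ALPHABET.find(c)
            if i < 0:
                raise ValidationError(f"non-ACGT symbol {c!r} in {word!r}")
            r = 4 * r + i
        return r


_SIGNAL_COL = re.compile(r"^(?P<mark>.+)@(?P<offset>[+-]?\d+)$")


@dataclass
class FeatureMatrix:
    """Loci-by-feature design matrix with class labels.

    Columns are ordered as contiguous per-mark signal blocks named
    ``mark@offset`` (offset runs upstream to downstream,
    ``-bin_number .. +bin_number``), optionally followed by the 4^k k-mer
    columns named by the literal word. Labels are 1 for boundaries and 0 for
    non-boundaries.
    """

    data: pd.DataFrame
    labels: np.ndarray
    marks: tuple[str, ...]
    bin_number: int
    kmer_k: int | None = None
    loci: tuple[GenomicLocus, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.data):
            raise ValidationError("labels and rows disagree in length")
        expected = len(self.marks) * (2 * self.bin_number + 1)
        if self.kmer_k is not None:
            expected += 4**self.kmer_k
        if self.data.shape[1] != expected:
            raise ValidationError(
                f"expected {expected} columns, found {self.data.shape[1]}"
            )
        if len(self.data) and not np.isfinite(self.data.to_numpy()).all():
            raise ValidationError("feature matrix contains non-finite values")

    # -- structure ---------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return 2 * self.bin_number + 1

    @property
    def signal_columns(self) -> list[str]:
        return [c for c in self.data.columns if _SIGNAL_COL.match(str(c))]

    @property
    def kmer_columns(self) -> list[str]:
        return [c for c in self.data.columns if not _SIGNAL_COL.match(str(c))]

    def mark_block(self, mark: str) -> slice:
        """Column slice of one mark's contiguous signal block."""
        if mark not in self.marks:
            raise KeyError(mark)
        i = self.marks.index(mark)
        return slice(i * self.n_bins, (i + 1) * self.n_bins)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels

    def signal_only(self) -> "FeatureMatrix":
        """Drop the k-mer block, if any."""
        cols = self.signal_columns
        return FeatureMatrix(
            self.data[cols].copy(), self.labels.copy(), self.marks,
            self.bin_number, None, self.loci,
        )

    # -- serialisation -----------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(len(out.columns), "label", self.labels)
        out.to_csv(path, sep="\t", index=True, index_label="locus")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="locus")
        if "label" not in df.columns:
            raise ParseError(f"{path}: missing 'label' column")
        labels = df.pop("label").to_numpy(dtype=int)
        marks: list[str] = []
        offsets: dict[str, list[int]] = {}
        for c in df.columns:
            m = _SIGNAL_COL.match(str(c))
            if m:
                mark = m.group("mark")
                if mark not in marks:
                    marks.append(mark)
                offsets.setdefault(mark, []).append(int(m.group("offset")))
        if not marks:
            raise ParseError(f"{path}: no mark@offset signal columns found")
        bin_number = max(offsets[marks[0]])
        n_kmer = sum(1 for c in df.columns if not _SIGNAL_COL.match(str(c)))
        kmer_k = None
        if n_kmer:
            k = int(round(np.log(n_kmer) / np.log(4)))
            if 4**k != n_kmer:
                raise ParseError(f"{path}: {n_kmer} k-mer columns is not a power of 4")
            kmer_k = k
        return cls(df, labels, tuple(marks), bin_number, kmer_k)


def concat_rows(parts: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Stack feature matrices with identical column structure row-wise."""
    if not parts:
        raise ValidationError("nothing to concatenate")
    first = parts[0]
    for p in parts[1:]:
        if list(p.data.columns) != list(first.data.columns):
            raise ValidationError("column structures differ")
    return FeatureMatrix(
        pd.concat([p.data for p in parts], axis=0),
        np.concatenate([p.labels for p in parts]),
        first.marks,
        first.bin_number,
        first.kmer_k,
        tuple(l for p in parts for l in p.loci),
    )
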