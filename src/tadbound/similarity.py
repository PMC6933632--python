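"""Intra- vs inter-class cosine similarity of signal profiles.

If boundary and non-boundary loci carry distinguishable signal shapes, two
profiles drawn from the same class should look more alike than two drawn
from different classes. This module samples random same-class and cross-class
pairs, computes the cosine similarity of their (per-sample z-scored) per-mark
signal blocks, and compares the two similarity distributions with a two-sided
Wilcoxon rank-sum test per mark.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import FeatureMatrix, ValidationError

__all__ = ["cosine_similarity", "intra_inter_similarity", "SimilarityReport"]

POOLED = "pooled"


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size == 0:
        raise ValidationError("vectors must share a nonzero 1-d shape")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValidationError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


@dataclass
class SimilarityReport:
    """Similarity samples and rank-sum p-values, per mark and pooled."""

    intra: dict[str, np.ndarray]
    inter: dict[str, np.ndarray]
    pvalues: dict[str, float]
    n_pairs: int
    seed: int

    @property
    def medians(self) -> dict[str, dict[str, float]]:
        return {
            m: {
                "intra": float(np.median(self.intra[m])),
                "inter": float(np.median(self.inter[m])),
            }
            for m in self.intra
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("mark\tclass\tcosine_similarity\n")
            for mark in self.intra:
                for v in self.intra[mark]:
                    fh.write(f"{mark}\tintra\t{v:.6g}\n")
                for v in self.inter[mark]:
                    fh.write(f"{mark}\tinter\t{v:.6g}\n")

    def to_json(self, path) -> None:
        payload = {
            "n_pairs_per_class": self.n_pairs,
            "seed": self.seed,
            "medians": self.medians,
            "rank_sum_pvalues": {m: float(p) for m, p in self.pvalues.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _pair_sims(X: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray) -> np.ndarray:
    sims = []
    for a, b in zip(a_idx, b_idx):
        u, v = X[a], X[b]
        if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
            continue  # zero-variance block row: similarity undefined, skip pair
        sims.append(cosine_similarity(u, v))
    return np.array(sims)


def _ranksum(x: np.ndarray, y: np.ndarray) -> float:
    # exact Mann-Whitney below 50 samples, normal approximation otherwise
    method = "exact" if min(len(x), len(y)) < 50 else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def intra_inter_similarity(
    pos: FeatureMatrix,
    neg: FeatureMatrix,
    pairs_per_class: int = 2000,
    seed: int = 0,
) -> SimilarityReport:
    """Sample intra- and inter-class similarity distributions per mark.

    ``pos`` and ``neg`` should already be z-scored by factor
    (:func:`tadbound.signal.zscore_by_factor`) and share column structure.
    Intra pairs are drawn half from within the positive class and half from
    within the negative class; inter pairs cross the two. A ``pooled`` entry
    uses the full concatenated signal vector.
    """
    if pairs_per_class <= 0:
        raise ValidationError("pairs_per_class must be positive")
    if len(pos.data) < 2 or len(neg.data) < 2:
        raise ValidationError("need at least two samples per class")
    if list(pos.data.columns) != list(neg.data.columns):
        raise ValidationError("positive and negative matrices differ in columns")

    rng = np.random.default_rng(seed)
    Xp = pos.data[pos.signal_columns].to_numpy(dtype=float)
    Xn = neg.data[neg.signal_columns].to_numpy(dtype=float)

    def draw_within(n: int, count: int) -> tuple[np.ndarray, np.ndarray]:
        a = rng.integers(0, n, size=count)
        b = rng.integers(0, n - 1, size=count)
        b = np.where(b >= a, b + 1, b)  # distinct indices
        return a, b

    half = pairs_per_class // 2
    pa, pb = draw_within(len(Xp), half)
    na, nb = draw_within(len(Xn), pairs_per_class - half)
    xa = rng.integers(0, len(Xp), size=pairs_per_class)
    xb = rng.integers(0, len(Xn), size=pairs_per_class)

    n_bins = pos.n_bins
    intra: dict[str, np.ndarray] = {}
    inter: dict[str, np.ndarray] = {}
    pvalues: dict[str, float] = {}
    blocks = {m: pos.mark_block(m) for m in pos.marks}
    blocks[POOLED] = slice(0, len(pos.marks) * n_bins)
    for mark, sl in blocks.items():
        ii = np.concatenate([
            _pair_sims(Xp[:, sl], pa, pb),
            _pair_sims(Xn[:, sl], na, nb),
        ])
        cross = []
        for a, b in zip(xa, xb):
            u, v = Xp[a, sl], Xn[b, sl]
            if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
                continue
            cross.append(cosine_similarity(u, v))
        intra[mark] = ii
        inter[mark] = np.array(cross)
        if len(ii) >= 2 and len(cross) >= 2:
            pvalues[mark] = _ranksum(ii, np.array(cross))
        else:
            pvalues[mark] = float("nan")
    return SimilarityReport(intra, inter, pvalues, pairs_per_class, seed)
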