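"""Reference synthetic benchmark conditions and their evaluation.

Four named study conditions exercise the pipeline end to end:

``strong``
    Large signal effect (peak height 3.0 vs noise sd 1.0) — the classifiers
    should separate the classes nearly perfectly.
``null``
    Zero effect and no motif planting, at a larger sample size — held-out
    AUC should sit at chance.
``weak``
    Small signal effect (0.3) with motif-seeded boundary sequences — adding
    the k-mer block should raise AUC over the signal-only model.
``center_delta``
    Signal effect confined to the center bin — random-forest Gini importance
    should concentrate on the center column.

Problem sizes are kept at desk scale (2 kb bins, 5 flanking bins, tens of
boundaries per chromosome) so a full evaluation runs in minutes on one core.
"""

from __future__ import annotations

import numpy as np

from .core import FeatureMatrix, KmerSpec, MARK_ORDER
from .mlp import MLPSpec
from .model import RFSpec, cross_validate
from .pipeline import extract_features
from .simulate import CENTER_DELTA, Fixture, FixtureConfig, generate_fixture

__all__ = [
    "strong_condition",
    "null_condition",
    "weak_condition",
    "center_delta_condition",
    "condition_matrix",
    "RF_FOLDS",
    "MLP_FOLDS",
    "MLP_EPOCHS",
]

RF_FOLDS = 10
MLP_FOLDS = 5   # fewer folds for the slower back-end; same stratified scheme
MLP_EPOCHS = 60


def strong_condition(seed: int) -> FixtureConfig:
    return FixtureConfig(
        n_boundaries=60, n_chromosomes=2, chrom_length=1_500_000,
        effect_size=3.0, noise_sd=1.0, seed=seed,
    )


def null_condition(seed: int) -> FixtureConfig:
    return FixtureConfig(
        n_boundaries=150, n_chromosomes=2, chrom_length=4_000_000,
        effect_size=0.0, plant_prob=0.0, seed=seed,
    )


def weak_condition(seed: int) -> FixtureConfig:
    return FixtureConfig(
        n_boundaries=60, n_chromosomes=2, chrom_length=1_500_000,
        effect_size=0.3, plant_prob=0.9, seed=seed,
    )


def center_delta_condition(seed: int) -> FixtureConfig:
    return FixtureConfig(
        n_boundaries=60, n_chromosomes=2, chrom_length=1_500_000,
        effect_size=3.0, plant_prob=0.0,
        mark_shapes={m: CENTER_DELTA for m in MARK_ORDER}, seed=seed,
    )


def condition_matrix(
    config: FixtureConfig, kmer: int | None = 3
) -> tuple[Fixture, FeatureMatrix]:
    """Generate a fixture and its extracted design matrix."""
    fx = generate_fixture(config)
    matrix = extract_features(
        fx.tracks, fx.boundaries, fx.contacts, config.bin_config,
        genome=fx.genome, kmer=KmerSpec(kmer) if kmer else None,
    )
    return fx, matrix


def rf_auc(matrix: FeatureMatrix, seed: int = 0) -> float:
    return cross_validate(matrix, RFSpec(seed=seed), folds=RF_FOLDS, seed=seed).mean("auc")


def mlp_auc(matrix: FeatureMatrix, seed: int = 0) -> float:
    spec = MLPSpec(epochs=MLP_EPOCHS, seed=seed)
    return cross_validate(matrix, spec, folds=MLP_FOLDS, seed=seed).mean("auc")
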