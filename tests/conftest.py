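"""Shared fixtures: the synthetic benchmark and the trained classifier.

The heavy fixtures are session-scoped and lazy, so unit-test runs that do
not touch the classifier pay nothing.  Benchmark conditions: 5,000 positive
units (HCS mutation rate 0.05) + 5,000 HCSP-free negatives, lengths 20-30
balanced, generator seed 17; 8:2 split with five folds (seed 0); one model
per cross-validation fold arrangement trained with protocol defaults and
combined into the score-averaging ensemble used throughout.
"""

from __future__ import annotations

import pytest

import lrrscan as L
from lrrscan.cnn import TrainingConfig

BENCHMARK_SEED = 17
SPLIT_SEED = 0
TRAIN_SEED = 0
MUTATION_RATE = 0.05
N_UNITS = 5000
N_PROTEINS = 150


@pytest.fixture(scope="session")
def benchmark():
    cfg = L.GeneratorConfig(seed=BENCHMARK_SEED, mutation_rate=MUTATION_RATE)
    units, proteins = L.gen_benchmark(cfg, N_UNITS, N_UNITS, N_PROTEINS)
    positives = [r for r in units if r.label == "positive"]
    negatives = [r for r in units if r.label == "negative"]
    split = L.make_splits(positives, negatives, L.SplitSpec(seed=SPLIT_SEED))
    return {"units": units, "proteins": proteins, "split": split}


@pytest.fixture(scope="session")
def trained_model(benchmark):
    return L.train_cv_ensemble(
        benchmark["split"], tc=TrainingConfig(seed=TRAIN_SEED)
    )


@pytest.fixture(scope="session")
def scanned_proteins(benchmark, trained_model):
    """Window scores of the trained model over every benchmark protein."""
    return [
        (p, L.scan_windows(p.sequence, trained_model))
        for p in benchmark["proteins"]
    ]
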