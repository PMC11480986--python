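"""Shared fixtures: the standard synthetic benchmark and models trained on it.

The benchmark conditions (n=600 molecules, five planted fragment
effects of +1.5 pIC50, noise sd 0.3, censoring mixture 0.40/0.35/0.25)
are the package defaults; expensive artifacts are session-scoped so the
suite trains each model once.
"""

from __future__ import annotations

import pytest

from fragqsar import pipeline as pl
from fragqsar import synthetic_data as sd

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def benchmark600():
    data, manifest = sd.generate_benchmark({"n": 600}, BENCHMARK_SEED)
    return data, manifest


@pytest.fixture(scope="session")
def binary_model_600(benchmark600):
    data, _ = benchmark600
    config = pl.RunConfig(seed=BENCHMARK_SEED, models={
        "binary": pl.TaskModelConfig(family="gradient_boosting")})
    return pl.train_task(data.dataset, "binary", config)


@pytest.fixture(scope="session")
def regression_model_600(benchmark600):
    data, _ = benchmark600
    config = pl.RunConfig(seed=BENCHMARK_SEED)
    return pl.train_task(data.dataset, "regression", config)
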