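"""Shared fixtures: small synthetic datasets and fast network/training configs."""

import numpy as np
import pytest

import trscreen as ts
from trscreen.nn import NetworkSpec, TrainConfig


@pytest.fixture(scope="session")
def tiny_spec() -> NetworkSpec:
    """A down-scaled network for fast unit tests (30-gene panels)."""
    return NetworkSpec(input_length=30, filters1=4, filters2=6, dense_units=8)


@pytest.fixture(scope="session")
def fast_config() -> TrainConfig:
    return TrainConfig(seed=42)


@pytest.fixture(scope="session")
def small_separable():
    """Strongly separable single-cohort dataset: 160 samples x 30 genes."""
    return ts.generate_separable_binary(160, 30, 8, 3.0, seed=11)


@pytest.fixture(scope="session")
def batched_cohorts():
    """Three cohorts with strong additive batch effects confounded with class."""
    cfg = ts.GeneratorConfig(
        n_cohorts=3,
        samples_per_cohort=(40, 40, 40),
        prevalence_per_cohort=(0.3, 0.5, 0.7),
        n_genes=400,
        n_informative=30,
        effect_size=2.0,
        batch_shift_sd=2.0,
        batch_scale_sd=0.2,
        noise_sd=0.5,
        seed=7,
    )
    return ts.generate_multicohort(cfg)
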