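"""Shared fixtures: small synthetic training sets with known truth."""

import numpy as np
import pandas as pd
import pytest

import wacalib as w


@pytest.fixture(scope="session")
def small_benchmark():
    """Reduced calibration benchmark: 150 autocorrelated sites, 40 taxa."""
    pool, env, abundance = w.benchmark_training_set(
        n_sites=150, n_taxa=40, seed=5
    )
    return pool, env, abundance


@pytest.fixture(scope="session")
def small_training(small_benchmark):
    """(relative abundance, transformed TP gradient) for the small benchmark."""
    _, env, abundance = small_benchmark
    return abundance.to_relative(), env.transformed_variable("TP")


@pytest.fixture()
def toy_abundance():
    """5 samples x 3 taxa toy with easily hand-checked weighted averages."""
    data = pd.DataFrame(
        {
            "a": [0.5, 0.2, 0.0, 0.3, 0.1],
            "b": [0.5, 0.3, 0.6, 0.0, 0.4],
            "c": [0.0, 0.5, 0.4, 0.7, 0.5],
        },
        index=pd.Index([f"s{i}" for i in range(5)], name="sample"),
    )
    return w.AbundanceMatrix(data, "rel_density")


@pytest.fixture()
def toy_gradient(toy_abundance):
    return pd.Series(
        [1.0, 2.0, 3.0, 4.0, 5.0], index=toy_abundance.samples, name="TP"
    )
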