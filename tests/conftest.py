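"""Shared fixtures: a desk-scale synthetic cohort and its pipeline products."""

import numpy as np
import pandas as pd
import pytest

import proteonet as pn


def small_config(seed: int = 11, **overrides) -> pn.SyntheticConfig:
    """A reduced cohort (400 proteins, 3 planted modules) for fast tests."""
    kwargs = dict(
        n_proteins=400,
        module_sizes=(40, 30, 25),
        trajectory_per_module=("decreasing", "increasing", "peak_mid"),
        seed=seed,
    )
    kwargs.update(overrides)
    return pn.SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    return pn.generate_dataset(small_config())


@pytest.fixture(scope="session")
def prepped(small_dataset):
    ab, meta, truth = small_dataset
    ab = pn.normalize_to_gis(ab, meta)
    ab = pn.filter_complete_proteins(ab, meta)
    ab, _ = pn.remove_connectivity_outliers(ab, meta)
    return ab, meta.loc[ab.columns], truth


@pytest.fixture(scope="session")
def harmonized(prepped):
    ab, meta, truth = prepped
    harm = pn.run_harmonization_plan(ab, meta)
    return harm, meta.loc[harm.columns], truth


@pytest.fixture(scope="session")
def regressed(harmonized):
    ab, meta, truth = harmonized
    reg = pn.regress_covariates_bootstrap(ab, meta, n_boot=50, seed=11)
    return reg, meta, truth


@pytest.fixture(scope="session")
def fitted_network(regressed):
    ab, meta, truth = regressed
    net = pn.CoexpressionNetwork().fit(ab.T)
    return net, ab, meta, truth


def planted_module_map(net, truth):
    """Recovered color -> dominant planted module label."""
    out = {}
    for color in net.eigenproteins_.columns:
        members = net.labels_[net.labels_ == color].index
        out[color] = truth.module_of_protein[members].mode()[0]
    return out


@pytest.fixture(scope="session")
def mixture_data(small_dataset):
    _, _, truth = small_dataset
    ab, weights = pn.generate_mixture_samples(truth, 20, seed=3, noise_sd=0.1)
    return np.log2(ab), weights, truth
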