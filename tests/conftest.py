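"""Shared fixtures: a scaled simulation study reused across the suite.

The expensive objects (neutral batch, norms, simulated training data,
trained CNN) are session-scoped and built lazily, at a 1/10-scaled
geometry (120-kb locus, 5-100-kb nested windows, 50 chromosomes,
Ne = 10,000) so the full pipeline runs in minutes.  All seeds are fixed.
"""

from __future__ import annotations

import numpy as np
import pytest

import sweepnet as sn
from sweepnet.classifier import Hyperparams
from sweepnet.features import FeatureConfig, assemble, build_norms_from_neutral

SCALE = 10
# Scaled fixture profile: 1/10 locus geometry with mutation/recombination
# rates raised 3x so windows keep a workable SNP density (see docs/methods.md)
BASE = dict(
    locus_length=120_000,
    n_haplotypes=50,
    ne=10_000.0,
    mutation_rate=3.75e-8,
    recombination_rate=3.75e-8,
)


@pytest.fixture(scope="session")
def sim_config() -> sn.SimulationConfig:
    return sn.SimulationConfig(**BASE)


@pytest.fixture(scope="session")
def feature_config() -> FeatureConfig:
    return FeatureConfig.scaled(SCALE)


@pytest.fixture(scope="session")
def neutral_batch(sim_config):
    return [sn.simulate_neutral(sim_config, 1000 + i) for i in range(40)]


@pytest.fixture(scope="session")
def norms(neutral_batch, feature_config):
    return build_norms_from_neutral(
        neutral_batch, feature_config, provenance="fixture-neutral-40"
    )


def _sweep_batch(config, n, seed0, **fixed):
    """Sweep replicates; parameters drawn from the configured distributions
    unless pinned via ``fixed`` (tau/s/saf/eaf)."""
    out = []
    params_list = []
    for i in range(n):
        if fixed:
            params = sn.SweepParams(ne=config.ne, **fixed)
        else:
            params = sn.draw_sweep_params(config, seed0 + 2 * i)
        out.append(sn.simulate_sweep(config, params, seed0 + 2 * i + 1))
        params_list.append(params)
    return out, params_list


def _featurize(matrices, norms, cfg, prefix):
    return [
        assemble(m, norms, cfg, locus_id=f"{prefix}#{i}") for i, m in enumerate(matrices)
    ]


@pytest.fixture(scope="session")
def training_data(sim_config, norms, feature_config):
    neutral = [sn.simulate_neutral(sim_config, 2000 + i) for i in range(150)]
    sweeps, params = _sweep_batch(sim_config, 150, 40_000)
    tensors = _featurize(neutral, norms, feature_config, "train-neut") + _featurize(
        sweeps, norms, feature_config, "train-sweep"
    )
    labels = np.r_[np.zeros(len(neutral)), np.ones(len(sweeps))]
    return tensors, labels, params


@pytest.fixture(scope="session")
def trained_model(training_data):
    tensors, labels, _ = training_data
    return sn.train(tensors, labels, Hyperparams(max_epochs=40, patience=8), seed=7)


@pytest.fixture(scope="session")
def test_data(sim_config, norms, feature_config):
    """Held-out test set drawn from the same distributions as training."""
    neutral = [sn.simulate_neutral(sim_config, 3000 + i) for i in range(50)]
    sweeps, params = _sweep_batch(sim_config, 50, 60_000)
    tensors = _featurize(neutral, norms, feature_config, "test-neut") + _featurize(
        sweeps, norms, feature_config, "test-sweep"
    )
    labels = np.r_[np.zeros(len(neutral)), np.ones(len(sweeps))]
    return tensors, labels, params


@pytest.fixture(scope="session")
def strong_sweep_tensors(sim_config, norms, feature_config):
    """Recent, strong, 90%-complete hard sweeps: the easiest class whose
    derived/ancestral contrasts are still computable."""
    sweeps, _ = _sweep_batch(
        sim_config, 30, 80_000, tau=0.0, s=0.05, saf=0.0, eaf=0.9
    )
    return _featurize(sweeps, norms, feature_config, "strong-sweep")
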