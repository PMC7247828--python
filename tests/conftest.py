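"""Shared fixtures.

The expensive simulation products (flow-pair sets, trained networks, the
coarse-variable pipeline, steady-state datasets) are session-scoped so the
acceptance tests and the unit tests reuse one computation. Ensemble sizes
follow the scaled-down test profile (N = 2000 oscillators / 500 pairs for
flow learning); the coarse-variable and effective-parameter runs use the
reference problem sizes, which are cheap enough to run directly.
"""

from __future__ import annotations

import numpy as np
import pytest

from emergent.coarse_id import build_density_dataset, discover_coarse_variable
from emergent.manifold import KernelConfig
from emergent.oscillator_models import (
    OscillatorEnsemble,
    sample_cauchy_frequencies,
    simulate,
    to_rotating_frame,
)
from emergent.rhs_learning import RK4NetConfig, generate_flow_pairs, train_rhs_net
from emergent.effective_params import steady_state_dataset

TEST_N = 2000
TEST_PAIRS = 500


@pytest.fixture(scope="session")
def flow_pairs_by_dt():
    """Scaled flow-pair sets for both reporting horizons."""
    return {
        dt: generate_flow_pairs(
            n_pairs=TEST_PAIRS, dt=dt, n_oscillators=TEST_N, seed=seed
        )
        for dt, seed in ((0.01, 101), (0.05, 105))
    }


@pytest.fixture(scope="session")
def trained_models(flow_pairs_by_dt):
    """RK4-templated networks trained on the scaled pair sets."""
    # scaled-profile training lengths: the validation-loss plateau of the
    # noisier scaled data is reached by 10-20k epochs, beyond which the
    # network starts memorizing per-pair ensemble noise
    epochs = {0.01: 20000, 0.05: 10000}
    return {
        dt: train_rhs_net(pairs, RK4NetConfig(epochs=epochs[dt], seed=7))
        for dt, pairs in flow_pairs_by_dt.items()
    }


def make_reference_trajectories(n=8000, n_snap=400):
    """The two coarse-variable discovery trajectories: started fully
    synchronized (all phases pi) and incoherent (equally spaced phases).

    Snapshot windows differ per branch — the synchronized start relaxes to
    the steady coherence within a few time units while the structured
    incoherent start grows slowly — so each window spans its branch's
    actual R excursion instead of oversampling the steady-state plateau.
    """
    omega = sample_cauchy_frequencies(0.5, n)
    ensemble = OscillatorEnsemble(phases=np.zeros(n), frequencies=omega, coupling=2.0)
    runs = (
        (np.full(n, np.pi), np.linspace(0.5, 4.0, n_snap)),
        (np.linspace(0.0, 2.0 * np.pi, n, endpoint=False), np.linspace(4.0, 20.0, n_snap)),
    )
    return [to_rotating_frame(simulate(ensemble, s, t)) for s, t in runs]


@pytest.fixture(scope="session")
def coarse_pipeline():
    """Density dataset + diffusion map for the reference configuration
    (N = 8000, K = 2, gamma = 0.5, 200 bins)."""
    trajectories = make_reference_trajectories()
    dataset = build_density_dataset(trajectories)
    result = discover_coarse_variable(dataset, KernelConfig())
    return dataset, result


@pytest.fixture(scope="session")
def hetero_k_dataset():
    return steady_state_dataset("hetero_k", seed=61)


@pytest.fixture(scope="session")
def firing_dataset():
    # this heterogeneity draw settles to a rotating-frame steady state
    # (some draws of the excitable variant instead reach a small
    # collective limit cycle and cannot complete the pipeline)
    return steady_state_dataset("firing", seed=7)


@pytest.fixture(scope="session")
def chung_lu_dataset():
    return steady_state_dataset("chung_lu", seed=63)
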