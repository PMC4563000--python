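"""Shared fixtures: ground-truth parameters and reusable simulations.

Expensive objects (full-ladder simulations, the noise-free staged fit) are
session-scoped so several test modules can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import fibrheo as fr


@pytest.fixture(scope="session")
def truth() -> fr.ModelParameters:
    return fr.default_truth()


@pytest.fixture(scope="session")
def ladder() -> fr.StrainProtocol:
    return fr.standard_laos_protocol()


@pytest.fixture(scope="session")
def ladder_series(ladder, truth) -> fr.StressTimeSeries:
    """Noise-free simulation of the seven-step amplitude ladder."""
    return fr.simulate(ladder, truth)


@pytest.fixture(scope="session")
def ladder_features(ladder_series, ladder, truth):
    return fr.extract_cycle_features(ladder_series, ladder, G00=truth.G00)


@pytest.fixture(scope="session")
def noisefree_experiment(truth) -> fr.SyntheticExperiment:
    cfg = fr.SyntheticConfig(
        true_params=truth,
        noise_rel=0.0,
        noise_floor=0.0,
        seed=1,
        protocol=fr.standard_laos_protocol(include_recovery=True),
    )
    return fr.generate_experiment(cfg)


@pytest.fixture(scope="session")
def noisefree_fit(noisefree_experiment) -> fr.FitResult:
    """Three-step fit of the noise-free full first sequence + recovery."""
    exp = noisefree_experiment
    return fr.fit_three_step(
        exp.laos[0],
        exp.fitting_protocol(),
        saos_records=list(exp.saos),
        seed=0,
    )


def rel_err(est: float, true: float) -> float:
    return abs(est - true) / abs(true)


@pytest.fixture(scope="session")
def linear_params() -> fr.ModelParameters:
    """A linear Kelvin-Voigt parameter set (no nonlinearity, frozen state)."""
    return fr.ModelParameters(
        G00=10.0, eta0=0.2, c_d=0.0, c_i=0.0, a=0.0, b=1.0,
        k1=0.0, n1=0.0, k2=0.0, n2=0.0,
    )
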