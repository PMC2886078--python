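"""Shared fixtures: small random regression instances and simulated datasets.

The heavyweight simulated datasets are session-scoped so the suite builds
them once.
"""

import numpy as np
import pytest

from chylopls import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim_dataset():
    """40 simulated plasma spectra on the default grid, default mechanism."""
    return simulate_dataset(40, SimulationConfig(seed=1234))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_instance(rng, n=20, p=10):
    """A random full-rank regression instance with a planted linear signal."""
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + 0.1 * rng.standard_normal(n)
    return X, y


def informative_interval_dataset(seed, n=30, p=120, k=6, informative=3, snr=10.0):
    """Pure-noise spectra except that one interval's columns are linear in y.

    Used to check that the interval scan recovers the single informative
    interval.  Returns (dataset, informative interval index).
    """
    from chylopls import SpectralDataset, make_intervals

    r = np.random.default_rng(seed)
    y = r.uniform(0.1, 2.8, n)
    X = r.standard_normal((n, p))
    ppm = np.linspace(6.0, 0.1, p)
    specs = make_intervals((0.1, 6.0), k, ppm)
    s0, s1 = specs[informative - 1].column_span
    width = s1 - s0 + 1
    loadings = r.uniform(0.5, 1.5, width)
    X[:, s0 : s1 + 1] = np.outer(y - y.mean(), loadings) * snr / np.sqrt(n)
    X[:, s0 : s1 + 1] += r.standard_normal((n, width)) * (1.0 / snr)
    return SpectralDataset(ppm, X, [f"s{i}" for i in range(n)], y=y), informative
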