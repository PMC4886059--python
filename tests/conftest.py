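"""Shared fixtures: synthetic benchmarks and random outline signals."""

from __future__ import annotations

import numpy as np
import pytest

from drfvt.synthetic import generate_benchmark


def random_blob_signal(rng: np.random.Generator, n: int = 256,
                       r0: float = 30.0) -> np.ndarray:
    """Continuous random-blob outline signal (no rasterization).

    Draws 2-5 harmonics with total relative amplitude < 0.8 so the radius
    function stays positive and the curve is simple and closed.  An h=2
    (ellipticity) component is always present: it feeds the Z_{-1}
    coefficient whose phase anchors the start-point normalization, and a
    shape with no ellipticity at all leaves that phase reference
    undefined (real silhouettes always have some).
    """
    n_harm = int(rng.integers(2, 6))
    amps = rng.uniform(0.05, 0.3, n_harm)
    amps *= rng.uniform(0.2, 0.6) / amps.sum()
    harmonics = rng.integers(1, 8, n_harm)
    phases = rng.uniform(0.0, 2.0 * np.pi, n_harm)
    phi = np.arange(n) * 2.0 * np.pi / n
    r = np.ones(n) + rng.uniform(0.08, 0.2) * np.cos(
        2 * phi + rng.uniform(0, 2 * np.pi))
    for h, a, p in zip(harmonics, amps, phases):
        r += a * np.cos(int(h) * phi + p)
    z = r0 * r * np.exp(1j * phi)
    return z + rng.uniform(-50, 50) + 1j * rng.uniform(-50, 50)


@pytest.fixture(scope="session")
def noisy_benchmark(tmp_path_factory):
    """Default benchmark: 6 categories x 5 models x 3 views, noise 0.05."""
    out = tmp_path_factory.mktemp("bench_noisy")
    return generate_benchmark(out, seed=0)


@pytest.fixture(scope="session")
def separable_benchmark(tmp_path_factory):
    """Noise-free benchmark: views identical, categories well separated."""
    out = tmp_path_factory.mktemp("bench_sep")
    return generate_benchmark(out, noise=0.0, seed=0)


@pytest.fixture(scope="session")
def small_benchmark(tmp_path_factory):
    """Quick 3x2x2 benchmark for index plumbing tests."""
    out = tmp_path_factory.mktemp("bench_small")
    return generate_benchmark(out, n_categories=3, n_models=2, n_views=2,
                              noise=0.05, seed=1, size=96)
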