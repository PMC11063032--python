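import numpy as np
import pytest
from hypothesis import settings

import httime as ht

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def make_tc():
    """Factory for small hand-built dish time courses."""

    def _make(counts, times=None, n=10, T=20.0, psi=0.0, rep="r1"):
        if times is None:
            times = tuple(range(1, len(counts) + 1))
        return ht.GerminationTimeCourse(
            temperature=T,
            water_potential=psi,
            times=tuple(times),
            cumulative_counts=tuple(counts),
            n_seeds=n,
            replicate_id=rep,
        )

    return _make


@pytest.fixture(scope="session")
def sunflower_truth():
    return ht.datasets.sunflower_htt_params()


@pytest.fixture(scope="session")
def noiseless_study(sunflower_truth):
    """Expected-count study at the reference design grid, fine count resolution."""
    cfg = ht.SimulationConfig(
        true_params=sunflower_truth,
        noise_mode="none",
        n_seeds_per_dish=10_000,
        n_replicates=1,
    )
    courses, truth = ht.simulate_study(cfg)
    return courses, truth


def hydro_curves(thetaH, psib50, sigma, psis=(0.0, -0.3, -0.6, -0.9),
                 times_h=None, n=100_000, T=20.0):
    """Exact single-temperature hydrotime curves (kT = 0) for fit tests."""
    from scipy.stats import norm

    if times_h is None:
        times_h = np.arange(24.0, 241.0, 24.0)
    times_h = np.asarray(times_h, dtype=float)
    curves = []
    for psi in psis:
        frac = norm.cdf((psi - thetaH / times_h - psib50) / sigma)
        counts = np.maximum.accumulate(np.round(frac * n).astype(int))
        curves.append(
            ht.GerminationTimeCourse(
                temperature=T,
                water_potential=psi,
                times=tuple(times_h / 24.0),
                cumulative_counts=tuple(int(c) for c in counts),
                n_seeds=n,
            )
        )
    return curves
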