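import numpy as np
import pytest

from rumenprof import PeakTable, SimConfig, simulate_community, simulate_electropherogram


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_peak_table():
    """One dominant peak over a field of small equal peaks."""
    sizes = np.arange(30.0, 240.0, 10.0)  # 21 peaks
    heights = np.full(21, 5.0)
    heights[10] = 500.0
    return PeakTable("S1", sizes, heights)


@pytest.fixture
def planted_sample():
    """A 5-taxon community with its simulated electropherogram."""
    community = simulate_community(5, "uniform", seed=42)
    table = simulate_electropherogram(
        community, SimConfig(n_taxa=5, n_background=200), seed=42, sample_id="S1"
    )
    return community, table


def brute_force_true_peaks(heights, k_sd=3.0):
    """Independent re-implementation of the iterative zero-mean SD rule.

    Pure-python loop over indices; used as the oracle for
    detect_true_peaks and kept deliberately free of its vectorized path.
    """
    remaining = {i: float(h) for i, h in enumerate(heights)}
    declared = set()
    while remaining:
        sd = (sum(h * h for h in remaining.values()) / len(remaining)) ** 0.5
        newly = [i for i, h in remaining.items() if h > k_sd * sd]
        if not newly:
            break
        for i in newly:
            declared.add(i)
            del remaining[i]
    return declared
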