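import numpy as np
import pytest

from bindkin.simulate import SimConfig, simulate_photon_stream
from bindkin.smfret import all_photon_burst_search


@pytest.fixture(scope="session")
def static_stream():
    """A 30 s photon stream of static E = 0.5 molecules (session-shared)."""
    return simulate_photon_stream(SimConfig(seed=1, E1=0.5, E2=0.5), 30.0)


@pytest.fixture(scope="session")
def static_bursts(static_stream):
    return all_photon_burst_search(static_stream)


def brute_force_apbs(timestamps, clock, window, threshold):
    """Independent O(n^2-ish) evaluation of the all-photon search criterion.

    Returns the boolean photon-selection mask: photon i is selected when at
    least ``threshold`` photons lie within +-window/2 of it (inclusive).
    """
    half = round(window / 2 / clock)
    sel = np.zeros(timestamps.size, dtype=bool)
    for i, t in enumerate(timestamps):
        count = int(np.sum((timestamps >= t - half) & (timestamps <= t + half)))
        sel[i] = count >= threshold
    return sel


def runs_of(mask):
    """(start_index, stop_index) pairs of maximal True runs."""
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out
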