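import numpy as np
import pandas as pd
import pytest

from hetchrom.regions import load_agamp3_regions


@pytest.fixture(scope="session")
def agamp3_regions():
    return load_agamp3_regions()


@pytest.fixture()
def small_window_table():
    """A 50-window feature table from known log-link parameters."""
    rng = np.random.default_rng(42)
    classes = np.array(["EU", "PH", "IHc", "PEU", "IHd"] * 10)
    L = rng.uniform(2e4, 3e5, 50)
    K = L * rng.uniform(0.05, 0.3, 50)
    mu = {"EU": -6, "PEU": -6, "PH": -5, "IHc": -7, "IHd": -4}
    eta = np.array([mu[c] for c in classes]) + 0.3 * np.log(L) + 0.5 * np.log(K + 1)
    C = rng.poisson(np.exp(eta))
    return pd.DataFrame({"class": classes, "C": C, "K": np.round(K), "L": np.round(L)})


def brute_force_coverage(window_start, window_end, spans):
    """Per-bp marking oracle for union coverage of a window."""
    covered = np.zeros(window_end - window_start, dtype=bool)
    for s, e in spans:
        lo = max(s, window_start) - window_start
        hi = min(e, window_end) - window_start
        if hi > lo:
            covered[lo:hi] = True
    return int(covered.sum())
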