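"""Shared fixtures: toy recordings, montages, and independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

import tripletlearn as tl
from tripletlearn.simulate import Recording, default_montage


@pytest.fixture(scope="session")
def montage():
    return default_montage()


def build_recording(signal, srate=100.0, montage=None, events=None,
                    block_bounds=None):
    """Wrap a raw array into a Recording with the default montage."""
    montage = montage or default_montage()
    if block_bounds is None:
        block_bounds = [(0, signal.shape[1])]
    if events is None:
        events = pd.DataFrame({"onset": [0.0], "block": [0]})
    return Recording(signal=np.asarray(signal, dtype=float), srate=srate,
                     montage=montage, events=events,
                     block_bounds=block_bounds)


@pytest.fixture
def toy_recording_factory():
    return build_recording


@pytest.fixture(scope="session")
def small_events():
    """2 blocks x 150 triplets with the default deviant/target rates."""
    spec = tl.SequenceSpec(n_blocks=2, triplets_per_block=150, seed=7)
    return tl.generate_sequence(spec)


# ---------------------------------------------------------------------------
# independent oracle: exhaustive cluster permutation on a small instance
# ---------------------------------------------------------------------------

def brute_force_cluster_null(X, n1, alpha=0.05, min_len=2):
    """Enumerate all C(n, n1) relabelings; for each, compute pointwise
    pooled t-tests with scipy, find same-sign suprathreshold runs by a
    plain loop, and record the max |sum of t|.  Fully independent of the
    package implementation."""
    X = np.asarray(X, dtype=float)
    n, T = X.shape
    df = n - 2
    thresh = sst.t.ppf(1 - alpha / 2, df)
    null = []
    for combo in itertools.combinations(range(n), n1):
        g1 = np.zeros(n, dtype=bool)
        g1[list(combo)] = True
        ts = np.array([
            sst.ttest_ind(X[g1, j], X[~g1, j], equal_var=True).statistic
            for j in range(T)])
        best = 0.0
        run = []
        for j in range(T + 1):
            ok = j < T and abs(ts[j]) > thresh and (
                not run or np.sign(ts[j]) == np.sign(ts[run[0]]))
            if ok:
                run.append(j)
            else:
                if len(run) >= min_len:
                    best = max(best, abs(ts[run].sum()))
                run = [j] if j < T and abs(ts[j]) > thresh else []
        null.append(best)
    return np.array(null)


@pytest.fixture(scope="session")
def cluster_oracle():
    return brute_force_cluster_null
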