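import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lamethyl import synthetic
from lamethyl.containers import SignalSet

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return dict(synthetic.DEFAULT_DESIGN)


@pytest.fixture(scope="session")
def small_manifest():
    return synthetic.make_manifest(200, 10, seed=1)


@pytest.fixture(scope="session")
def manifest_with_islands():
    return synthetic.make_manifest(300, 15, seed=2, return_islands=True)


def make_signal_set(M, U, bead=None, negctrl_mean=200.0, samples=None):
    """Hand-built SignalSet from 2-D arrays (probes x samples)."""
    M = np.asarray(M, dtype=float)
    samples = samples or [f"s{i}" for i in range(M.shape[1])]
    probes = pd.Index([f"cg{i:06d}" for i in range(M.shape[0])], name="probe_id")
    if bead is None:
        bead = np.full(M.shape, 10)
    rng = np.random.default_rng(0)
    neg = rng.normal(negctrl_mean, negctrl_mean / 5, size=(50, len(samples))).clip(min=1.0)
    return SignalSet(
        M=pd.DataFrame(M, index=probes, columns=samples),
        U=pd.DataFrame(np.asarray(U, dtype=float), index=probes, columns=samples),
        bead_count=pd.DataFrame(np.asarray(bead), index=probes, columns=samples),
        negctrl=pd.DataFrame(neg, columns=samples),
    )
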