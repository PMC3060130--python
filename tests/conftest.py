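import numpy as np
import pytest

from cytostd.fcs import make_dataset
from cytostd.pipeline import build_example_acs
from cytostd.synth import default_config, simulate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def synth_sample():
    """One simulated PBMC sample with ground truth (session-wide)."""
    return simulate_sample(default_config(n_events=20000, seed=42))


@pytest.fixture(scope="session")
def example_acs_path(tmp_path_factory):
    """A small example container built once for container/CLI tests."""
    outdir = tmp_path_factory.mktemp("acs")
    return build_example_acs(seed=7, outdir=outdir, n_events=6000)


@pytest.fixture
def small_dataset():
    """A tiny 4-event, 2-channel dataset for geometry tests."""
    events = np.array([[0.5, 0.5], [2.0, 2.0], [0.0, 0.0], [1.0, 1.0]])
    return make_dataset(events, ["X", "Y"], ranges=1024.0)


def random_dataset(rng, n_events=None, n_params=None, datatype="F"):
    """Random dataset mixing uniform and log-normal channel intensities."""
    n_events = int(rng.integers(1, 3000)) if n_events is None else n_events
    n_params = int(rng.integers(1, 25)) if n_params is None else n_params
    cols = []
    for _ in range(n_params):
        if rng.random() < 0.5:
            col = rng.uniform(0, 262143, size=n_events)
        else:
            col = np.minimum(rng.lognormal(5, 2, size=n_events), 262143.0)
        cols.append(col)
    events = np.column_stack(cols) if n_params else np.empty((n_events, 0))
    if datatype == "I":
        events = np.floor(events)
    names = [f"CH{i + 1}" for i in range(n_params)]
    ds = make_dataset(events, names)
    if datatype == "I":
        for i, p in enumerate(ds.parameters):
            p.bits = int(rng.choice([16, 32]))
            ds.events[:, i] = np.minimum(ds.events[:, i], 2**p.bits - 1)
    ds.keywords["$DATATYPE"] = datatype
    return ds
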