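import numpy as np
import pytest

from erpload import pipeline as pl
from erpload import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_out(tmp_path_factory):
    """One tiny end-to-end pipeline run shared by the pipeline tests."""
    out = tmp_path_factory.mktemp("tiny_fixture")
    report = pl.make_fixtures("tiny", out, seed=0)
    return out, report


@pytest.fixture(scope="session")
def default_components():
    return sim.default_components()


def make_recording(rng, n_channels=3, n_samples=2000, sfreq=1000.0, labels=None):
    from erpload.io import ContinuousRecording

    if labels is None:
        labels = [f"ch{i}" for i in range(n_channels)]
    data = rng.normal(0.0, 10.0, size=(len(labels), n_samples))
    return ContinuousRecording(labels, sfreq, data)
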