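import numpy as np
import pytest
from hypothesis import settings

from neoburst.core import Annotation

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from neoburst.synthetic import SyntheticConfig, generate_dataset, generate_record


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240317)


@pytest.fixture(scope="session")
def short_record():
    """One 120 s synthetic record with its true annotation."""
    rec, ann = generate_record(SyntheticConfig(duration_s=120.0, seed=7))
    return rec, ann


@pytest.fixture(scope="session")
def small_dataset():
    """Four 120 s records for fast end-to-end training tests."""
    recs, anns = generate_dataset(SyntheticConfig(duration_s=120.0), 4, base_seed=100)
    return [r.samples[0] for r in recs], anns, 256.0


def make_annotation(labels, fs=64.0):
    return Annotation(np.asarray(labels), fs)
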