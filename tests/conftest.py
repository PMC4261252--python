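import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def example_bundle():
    from prknet.synthetic_data import worked_examples

    return worked_examples()


@pytest.fixture
def fixture_transducer(tmp_path, example_bundle):
    """The worked-example transducer, round-tripped through the machine text format."""
    from prknet.wfst_core import read_machine_text

    path = tmp_path / "machine.tsv"
    path.write_text(example_bundle.machine_text())
    return read_machine_text(path.read_text())
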