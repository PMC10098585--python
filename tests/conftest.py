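import numpy as np
import pytest

from roma_ppg.pipeline import PipelineConfig, process_record
from roma_ppg.synth import ConstantHR, SynthConfig, generate, make_fixture_suite


@pytest.fixture(scope="session")
def clean70():
    """A clean 5-minute constant-70-BPM synthetic record."""
    return generate(SynthConfig(duration_s=300.0, hr_trajectory=ConstantHR(70.0), seed=1))


@pytest.fixture(scope="session")
def clean70_result(clean70):
    return process_record(clean70.record, PipelineConfig())


@pytest.fixture(scope="session")
def corrupted():
    """A heavily contact-loss-corrupted synthetic record."""
    return generate(SynthConfig(duration_s=300.0, hr_trajectory=ConstantHR(80.0),
                                contact_loss_rate=0.2, seed=5))


@pytest.fixture(scope="session")
def corrupted_result(corrupted):
    return process_record(corrupted.record, PipelineConfig())


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    make_fixture_suite(out, seed=0)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
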