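import numpy as np
import pytest
from hypothesis import settings

import bandevents as be

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_cfg():
    """Short noiseless recording with no dropped pulses."""
    return be.SyntheticConfig(
        duration_s=120.0,
        seed=7,
        rr_mean=17.4,
        rr_sd=0.0,
        hr_mean=85.0,
        hr_sd=0.0,
        noise_sd_mv=0.0,
        pulse_dropout_prob=0.0,
    )


@pytest.fixture(scope="session")
def resp_only_cfg():
    """Pure respiratory waveform: no pulses, no noise."""
    return be.SyntheticConfig(
        duration_s=120.0,
        seed=7,
        rr_mean=17.4,
        rr_sd=0.0,
        hr_mean=85.0,
        hr_sd=0.0,
        pulse_pp_mv=0.0,
        noise_sd_mv=0.0,
        pulse_dropout_prob=0.0,
    )


@pytest.fixture(scope="session")
def study_result():
    """The reference study conditions: 10 min, constant HR 85 / RR 17.4,
    30% pulse dropout, fixed seed; shared across tests for speed."""
    cfg = be.SyntheticConfig(
        duration_s=600.0,
        seed=1,
        rr_mean=17.4,
        rr_sd=0.0,
        hr_mean=85.0,
        hr_sd=0.0,
        pulse_dropout_prob=0.3,
    )
    return be.analyze(be.PipelineConfig(synthetic=cfg))


def random_event_stream(rng: np.random.Generator, n: int, rate: float = 200.0) -> be.EventStream:
    """A valid random event stream (strictly increasing, non-overlapping)."""
    h = rng.integers(1, 60, size=n)
    gaps = rng.integers(1, 400, size=n)
    ends = np.cumsum(h + gaps)
    return be.EventStream(
        rate,
        T=ends / rate,
        H=h,
        V1=rng.uniform(-2000, 2000, n),
        V2=rng.uniform(-2000, 2000, n),
    )
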