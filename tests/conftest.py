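import numpy as np
import pytest

from rotometry.rotation_measure import measure_arch
from rotometry.synthetic_arch import GeneratorConfig, generate_arch


@pytest.fixture(scope="session")
def clean_case():
    """One mandibular case without jitter, with its ground truth."""
    cfg = GeneratorConfig(seed=11, jitter_sd_mm=0.0, case_id="clean-11")
    return generate_arch(cfg)


@pytest.fixture(scope="session")
def measured_clean(clean_case):
    case, truth = clean_case
    measurements, problems = measure_arch(case)
    assert not problems
    return case, truth, measurements


@pytest.fixture(scope="session")
def jitter_case():
    cfg = GeneratorConfig(seed=12, jitter_sd_mm=0.05, case_id="jitter-12")
    return generate_arch(cfg)


@pytest.fixture(scope="session")
def measured_jitter(jitter_case):
    case, truth = jitter_case
    measurements, problems = measure_arch(case)
    assert not problems
    return case, truth, measurements


def signed_truth(truth):
    """Ground-truth angles re-signed the way the measurement reports them
    (prescribed >= 0, achieved relative to the prescribed direction)."""
    out = {}
    for t in truth.teeth:
        s = 1.0 if t.prescribed_deg >= 0 else -1.0
        out[t.fdi] = (s * t.prescribed_deg, s * t.achieved_deg)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
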