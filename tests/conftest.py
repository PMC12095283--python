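import numpy as np
import pytest

from msdyn import PipelineConfig, canonical_labels, fit_subject_templates
from msdyn.preprocess import clean
from msdyn.synthetic import make_ground_truth, synthesize_recording


@pytest.fixture(scope="session")
def truth_snr4():
    """120 s, 250 Hz, snr=4 subject with group-study-like dwell means."""
    return make_ground_truth(
        120.0, srate=250.0, snr=4.0, seed=7,
        dwell_ms_mean=np.array([71.0, 70.0, 62.0, 110.0]),
    )


@pytest.fixture(scope="session")
def clean_snr4(truth_snr4):
    rec = synthesize_recording(truth_snr4, srate=250.0)
    rc, qc = clean(rec)
    return rc, qc


@pytest.fixture(scope="session")
def recovered_templates(clean_snr4):
    rc, _ = clean_snr4
    return canonical_labels(fit_subject_templates(rc, PipelineConfig()))


@pytest.fixture(scope="session")
def truth_noiseless():
    return make_ground_truth(
        30.0, srate=250.0, snr=np.inf, seed=3,
        dwell_ms_mean=np.array([80.0, 80.0, 80.0, 80.0]),
    )
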