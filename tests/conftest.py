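import numpy as np
import pytest

from ctgkit.layout import ChartLayout
from ctgkit.records import SimParams
from ctgkit.synth import simulate_record


@pytest.fixture(scope="session")
def paper_layout():
    return ChartLayout()


@pytest.fixture(scope="session")
def quiet_record():
    """30-min record, baseline 142, moderate variability, no injected events."""
    return simulate_record(SimParams(duration_s=1800, seed=7))


@pytest.fixture(scope="session")
def flat_record():
    """Zero-variability record: FHR constant at baseline."""
    return simulate_record(SimParams(variability_amp=0.0, duration_s=1800, seed=3))


def constant_record(fhr_bpm, duration_s=1800.0, fs=4.0, uc_mmhg=8.0):
    """Hand-built record with constant channels (no generator involvement)."""
    from ctgkit.records import CTGRecord

    n = int(duration_s * fs)
    return CTGRecord(
        fhr=np.full(n, float(fhr_bpm)),
        uc=np.full(n, float(uc_mmhg)),
        fhr_valid=np.ones(n, bool),
        uc_valid=np.ones(n, bool),
        fs=fs,
    )
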