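import numpy as np
import pytest

from oncokin import (KineticParameters, ProliferationProfile,
                     balanced_composition, calibrate_full)
from oncokin.clinical import SUBTYPE_INDEPENDENTS, SUBTYPE_PROFILES
from oncokin.sensitivity import TABLE4_RANGES, apply_filters, lhs_sample


@pytest.fixture(scope="session")
def adc_profile():
    return SUBTYPE_PROFILES["ADC"]


@pytest.fixture(scope="session")
def scc_profile():
    return SUBTYPE_PROFILES["SCC"]


@pytest.fixture(scope="session")
def adc_independents():
    return SUBTYPE_INDEPENDENTS["ADC"]


@pytest.fixture(scope="session")
def scc_independents():
    return SUBTYPE_INDEPENDENTS["SCC"]


@pytest.fixture(scope="session")
def adc_params(adc_profile, adc_independents):
    res = calibrate_full(adc_profile, adc_independents)
    assert res.ok
    return res.params


@pytest.fixture(scope="session")
def scc_params(scc_profile, scc_independents):
    res = calibrate_full(scc_profile, scc_independents)
    assert res.ok
    return res.params


def random_valid_params(n, seed, integer_durations=True):
    """Growing, biologically relevant parameter sets drawn from the value
    ranges (durations optionally snapped to whole hours so that closed-form
    and tick-quantized kinetics coincide)."""
    sample = lhs_sample(TABLE4_RANGES, max(25 * n, 100), seed)
    if integer_durations:
        for col in ("T_C_stem", "T_C_limp", "T_G0_stem", "T_G0_limp",
                    "T_A", "T_N"):
            sample[col] = np.maximum(np.round(sample[col]), 1.0)
    mask = apply_filters(sample, "sensitivity").mask
    rows = sample[mask]
    out = [KineticParameters.from_dict(dict(r)) for _, r in rows.iterrows()]
    if len(out) < n:
        raise RuntimeError("not enough surviving parameter sets; raise the pool")
    return out[:n]


@pytest.fixture(scope="session")
def random_params_pool():
    return random_valid_params(20, seed=20240917)
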