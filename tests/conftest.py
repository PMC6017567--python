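"""Shared fixtures: generating truths used across the suite."""

import pytest
from hypothesis import settings as hypothesis_settings

import slowbind as sb

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

# Published kinetic constants for the slow-binding tyrosinase inhibitor
# (forward/reverse isomerisation rates and apparent fast-step constant).
TWO_STEP_TRUTH = sb.TwoStepBindingParams(k3=0.0041, k4=0.0004, Kiapp=35.8)

KI_COMPOUND_2 = 10.3  # µM, competitive
KI_COMPOUND_8 = 44.2  # µM, competitive
IC50_COMPOUND_2 = 39.7  # µM
IC50_COMPOUND_8 = 50.0  # µM
IC50_COMPOUND_2_PREINCUBATED = 13.2  # µM

DOSE_SERIES = (6.25, 12.5, 25.0, 50.0, 100.0)  # two-fold series, µM


@pytest.fixture(scope="session")
def two_step_truth() -> sb.TwoStepBindingParams:
    return TWO_STEP_TRUTH


@pytest.fixture(scope="session")
def slow_binding_mechanism() -> sb.MechanismSpec:
    """Competitive slow-binding mechanism whose apparent fast-step constant
    at the default substrate equals the published Kiapp."""
    return sb.mechanism_from_kiapp(TWO_STEP_TRUTH)


@pytest.fixture(scope="session")
def mm_unit() -> sb.MichaelisMentenParams:
    """Convenient unit-scale Michaelis-Menten parameters."""
    return sb.MichaelisMentenParams(Vmax=1.0, Km=100.0)
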