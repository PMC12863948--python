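import numpy as np
import pytest

from pulsedose import (
    FecalSeries,
    MarkerCurveParams,
    MarkerDose,
    excretion_concentration,
)


@pytest.fixture
def dose() -> MarkerDose:
    return MarkerDose.from_boluses(6, 756.0)


@pytest.fixture
def true_params() -> MarkerCurveParams:
    return MarkerCurveParams(lambda1=0.3, k2=0.05, tau=12.0, c2=1000.0)


@pytest.fixture
def noiseless_series(true_params, dose) -> FecalSeries:
    """16 exact model evaluations spanning the sampling window."""
    t = np.linspace(14.0, 90.0, 16)
    conc = excretion_concentration(t, true_params)
    return FecalSeries.from_arrays(t, conc, dose)


def random_valid_params(rng: np.random.Generator) -> MarkerCurveParams:
    """One draw inside the observed field envelopes."""
    return MarkerCurveParams(
        lambda1=rng.uniform(0.10, 0.89),
        k2=rng.uniform(0.033, 0.061),
        tau=rng.uniform(5.5, 20.7),
        c2=rng.uniform(459.0, 1677.0),
    )
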