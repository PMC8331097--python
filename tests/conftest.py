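import pytest

from bgtremor.circuit import (
    CircuitParameters,
    CircuitState,
    DEFAULT_PARAMS,
    REFERENCE_STATE,
)


@pytest.fixture(scope="session")
def reference() -> CircuitState:
    return REFERENCE_STATE


@pytest.fixture(scope="session")
def balanced_params() -> CircuitParameters:
    """A parameter vector whose analytic fixed point is the reference state.

    Built from the published vector by solving each equation's steady-state
    condition for one coefficient (drives and gains), so the reference
    state is an exact zero of the deterministic part of the system.  Used
    where tests need a well-behaved operating point independent of the GA.
    """
    p = DEFAULT_PARAMS
    r = REFERENCE_STATE
    return p.replace(
        tauM1=p.a1Thal * r.Thal / r.M1,
        a2Ex=p.tauThal * r.Thal - p.a2DP * r.DP + p.a2IP * r.IP,
        a3Ex=p.tauDRN * r.DRN + p.a3M1 * r.M1 - p.a3SNc * r.SNc,
        a4DRN=p.tau5HT * r.fiveHT / r.DRN,
        a5Ex=p.tauSNc * r.SNc + p.a5DRN * r.DRN,
        G=p.tauDA * r.DA / (r.fiveHT * r.SNc),
        a7Ex=p.tauDP * r.DP - p.a7DA * r.DA,
        a8Ex=p.tauIP * r.IP,
    )


@pytest.fixture(scope="session")
def quiet_params(balanced_params) -> CircuitParameters:
    """The balanced vector with the oscillatory drive silenced."""
    return balanced_params.replace(alphaIP=0.0)
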