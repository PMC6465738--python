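import numpy as np
import pytest

from fcrnkinetics import (
    FcrCurveParameters,
    KineticParameters,
    SynthesisProfile,
    linearize,
    literature_parameters,
)


@pytest.fixture(scope="session")
def lit_params() -> KineticParameters:
    """Literature-sourced parameter values of the four-compartment model."""
    return literature_parameters()


@pytest.fixture(scope="session")
def lit_theta(lit_params):
    """Linearized tracer rates at the normal synthesis rate (15 μmol/day)."""
    return linearize(lit_params, 15.0)


@pytest.fixture(scope="session")
def psi_ref() -> FcrCurveParameters:
    """Cohort-fit estimates of the identifiable FCR-curve triple."""
    return FcrCurveParameters(k31=0.154, psi1=7.47, psi2=25.7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_kinetic_parameters(rng: np.random.Generator) -> KineticParameters:
    """Random positive parameter vector, rates log-uniform over ~4 decades."""

    def draw(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return KineticParameters(
        k21=draw(0.01, 10),
        k31=draw(0.01, 10),
        k12=draw(0.01, 10),
        k14=draw(0.1, 100),
        k03=draw(0.1, 100),
        kon=draw(1, 1e4),
        koff=draw(1, 1e3),
        Rtot=draw(0.1, 100),
        v1=2.9,
        v3=0.34,
    )


@pytest.fixture(scope="session")
def constant_synthesis() -> SynthesisProfile:
    return SynthesisProfile.constant(15.0)
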