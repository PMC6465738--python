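"""Four-compartment model of FcRn-mediated recycling of endogenous IgG.

The model tracks quantities (μmol) of IgG in plasma (x1), in a peripheral
tissue compartment (x2), unbound in intracellular endosomes (x3) and bound
to FcRn receptors in endosomes (x4).  Plasma IgG enters endosomes by
pinocytosis (k31); unbound endosomal IgG is either degraded (k03) or bound
by free FcRn (kon/v3 mass-action association against the free receptor pool
Rtot − x4); bound IgG dissociates (koff) or is recycled intact back to
plasma (k14).  Synthesis enters plasma at a rate I(t) μmol/day.

This module houses the physiological parameterization, the nonlinear
right-hand side and its analytic Jacobian, the closed-form steady state for
constant synthesis, a numerical stability assessment of that equilibrium,
and a stiff-solver wrapper used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from importlib import resources

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParameters",
    "SynthesisProfile",
    "SteadyState",
    "StabilityReport",
    "InvalidStateError",
    "IntegrationError",
    "nonlinear_rhs",
    "nonlinear_jacobian",
    "steady_state",
    "assess_stability",
    "simulate_nonlinear",
    "literature_parameters",
    "load_parameters",
]


class InvalidStateError(ValueError):
    """A state vector passed to the model is non-finite or inadmissible."""


class IntegrationError(RuntimeError):
    """The ODE solver failed; the message carries solver diagnostics."""


@dataclass(frozen=True)
class KineticParameters:
    """Physiological parameters of the four-compartment IgG model.

    Rate constants are in day⁻¹, ``kon`` in l μmol⁻¹ day⁻¹, ``Rtot`` in
    μmol and volumes in litres.  ``v2`` (peripheral volume) is carried for
    completeness but is never used by the dynamics: the peripheral
    compartment is specified in amounts, not concentrations, and no value
    for it is available in the source literature.
    """

    k21: float
    k31: float
    k12: float
    k14: float
    k03: float
    kon: float
    koff: float
    Rtot: float
    v1: float
    v3: float
    v2: float | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name == "v2":
                if value is not None and not (np.isfinite(value) and value > 0):
                    raise ValueError("v2, when given, must be positive and finite")
                continue
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"parameter {f.name} must be strictly positive, got {value!r}")

    @property
    def binding_ratio(self) -> float:
        """Volume-normalized association constant kon/v3 (l⁻¹... day⁻¹ μmol⁻¹·l)."""
        return self.kon / self.v3

    def replace(self, **changes: float) -> "KineticParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if d["v2"] is None:
            d.pop("v2")
        return d

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "KineticParameters":
        return cls(**d)


@dataclass(frozen=True)
class SynthesisProfile:
    """IgG synthesis input I(t).

    ``constant`` profiles synthesize at ``I0`` μmol/day indefinitely.
    ``myeloma-exponential`` profiles describe a tumour IgG output decaying
    under therapy, I(t) = (I0 − Iinf)·exp(−kkill·t) + Iinf.
    """

    kind: str
    I0: float
    Iinf: float = 0.0
    kkill: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "myeloma-exponential"):
            raise ValueError(f"unknown synthesis profile kind {self.kind!r}")
        if self.I0 < 0 or self.Iinf < 0 or self.kkill < 0:
            raise ValueError("synthesis profile parameters must be nonnegative")

    @classmethod
    def constant(cls, I0: float) -> "SynthesisProfile":
        return cls(kind="constant", I0=I0)

    @classmethod
    def myeloma(cls, I0: float, Iinf: float, kkill: float) -> "SynthesisProfile":
        return cls(kind="myeloma-exponential", I0=I0, Iinf=Iinf, kkill=kkill)

    @property
    def IE(self) -> float:
        """Constant-profile synthesis rate alias (endogenous production)."""
        return self.I0

    def rate(self, t):
        if self.kind == "constant":
            return self.I0 if np.isscalar(t) else np.full(np.shape(t), self.I0)
        return (self.I0 - self.Iinf) * np.exp(-self.kkill * np.asarray(t)) + self.Iinf

    __call__ = rate


@dataclass(frozen=True)
class SteadyState:
    """Equilibrium compartment quantities (μmol) for constant synthesis."""

    x1_hat: float
    x2_hat: float
    x3_hat: float
    x4_hat: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x1_hat, self.x2_hat, self.x3_hat, self.x4_hat])


@dataclass(frozen=True)
class StabilityReport:
    eigenvalues: np.ndarray  # 4 complex eigenvalues of the Jacobian at equilibrium
    stable: bool
    steady_state: SteadyState
    defective: bool = False  # eigenvector matrix numerically singular; no modal claims


def nonlinear_rhs(
    state: np.ndarray, t: float, params: KineticParameters, synth: SynthesisProfile
) -> np.ndarray:
    """Time derivative of (x1, x2, x3, x4) in μmol/day.

    The binding flux is (kon/v3)·x3·(Rtot − x4); summing all four equations
    collapses every internal exchange, leaving d/dt Σxᵢ = I(t) − k03·x3.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (4,) or not np.all(np.isfinite(state)):
        raise InvalidStateError(f"state must be a finite 4-vector, got {state!r}")
    x1, x2, x3, x4 = state
    br = params.binding_ratio
    bind = br * x3 * (params.Rtot - x4)
    return np.array(
        [
            -(params.k21 + params.k31) * x1 + params.k12 * x2 + params.k14 * x4 + synth.rate(t),
            params.k21 * x1 - params.k12 * x2,
            params.k31 * x1 - params.k03 * x3 - bind + params.koff * x4,
            bind - (params.k14 + params.koff) * x4,
        ]
    )


def nonlinear_jacobian(state: np.ndarray, params: KineticParameters) -> np.ndarray:
    """Analytic Jacobian ∂ẋ/∂x of the nonlinear model (synthesis is state-free)."""
    x1, x2, x3, x4 = np.asarray(state, dtype=float)
    br = params.binding_ratio
    free = params.Rtot - x4
    return np.array(
        [
            [-(params.k21 + params.k31), params.k12, 0.0, params.k14],
            [params.k21, -params.k12, 0.0, 0.0],
            [params.k31, 0.0, -params.k03 - br * free, br * x3 + params.koff],
            [0.0, 0.0, br * free, -br * x3 - (params.k14 + params.koff)],
        ]
    )


def steady_state(params: KineticParameters, I0: float) -> SteadyState:
    """Closed-form equilibrium under constant synthesis I0 ≥ 0.

    The bound pool saturates below capacity: x4_hat < Rtot for any finite
    I0, approaching Rtot only as I0 → ∞.
    """
    if I0 < 0:
        raise ValueError("I0 must be nonnegative")
    if I0 == 0.0:
        return SteadyState(0.0, 0.0, 0.0, 0.0)
    kon, v3, k03, k14, koff = params.kon, params.v3, params.k03, params.k14, params.koff
    den = k03 * v3 * (k14 + koff) + kon * I0
    x1 = I0 * (k03 * k14 * v3 + k03 * koff * v3 + kon * I0 + k14 * kon * params.Rtot) / (
        params.k31 * den
    )
    x2 = params.k21 / params.k12 * x1
    x3 = I0 / k03
    x4 = kon * I0 * params.Rtot / den
    return SteadyState(x1, x2, x3, x4)


def assess_stability(params: KineticParameters, I0: float) -> StabilityReport:
    """Eigenvalues of the Jacobian at the constant-synthesis equilibrium.

    The equilibrium is declared stable iff every eigenvalue has a strictly
    negative real part.  If the eigenvector matrix is numerically singular
    the eigenvalues are still reported but flagged ``defective`` so callers
    make no modal (eigen-basis) claims.
    """
    if I0 <= 0:
        raise ValueError("I0 must be strictly positive for a stability assessment")
    ss = steady_state(params, I0)
    jac = nonlinear_jacobian(ss.as_array(), params)
    eigvals, eigvecs = np.linalg.eig(jac)
    defective = np.linalg.cond(eigvecs) > 1e12
    stable = bool(np.all(eigvals.real < 0))
    return StabilityReport(eigenvalues=eigvals, stable=stable, steady_state=ss, defective=defective)


def simulate_nonlinear(
    params: KineticParameters,
    synth: SynthesisProfile,
    x0: np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
) -> np.ndarray:
    """Integrate the four-compartment model over ``times`` (shape (n, 4)).

    Uses a stiff method with the analytic Jacobian: the endosomal exchange
    rates (binding, dissociation) can exceed the plasma turnover rates by
    several orders of magnitude.
    """
    times = np.asarray(times, dtype=float)
    sol = solve_ivp(
        lambda t, x: nonlinear_rhs(x, t, params, synth),
        (times[0], times[-1]),
        np.asarray(x0, dtype=float),
        t_eval=times,
        method=method,
        jac=lambda t, x: nonlinear_jacobian(x, params),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return sol.y.T


def literature_parameters() -> KineticParameters:
    """Literature-sourced parameter values bundled with the package."""
    with resources.files("fcrnkinetics.data").joinpath("literature_parameters.yaml").open() as fh:
        return KineticParameters.from_dict(yaml.safe_load(fh))


def load_parameters(path) -> KineticParameters:
    """Read a flat key→value parameter file (YAML / ``key: value`` text)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {path} must be a flat key: value mapping")
    return KineticParameters.from_dict({k: float(v) for k, v in data.items()})
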