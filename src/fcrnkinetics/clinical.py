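"""Clinical-scenario simulation and model-order reduction.

The FCR-curve fit pins down only (k31, ψ1, ψ2); the endosomal parameters
{k03, Rtot, koff, k14, kon/v3} remain free on a 2-dimensional manifold.
This module asks whether that freedom matters for the plasma response:

* ``build_clinical_ensemble`` constructs parameter vectors spanning that
  manifold — three of the five free parameters are fixed to lognormal draws
  (excluding triples that contain both Rtot and k14, which would leave
  ψ2 = k14·Rtot over-determined) and the remaining two are solved from the
  ψ identities; 7 admissible triples × 10 draws gives 70 members.
* the members are simulated under a multiple-myeloma synthesis input
  I(t) = (I0 − I∞)·e^(−kkill·t) + I∞ (therapy killing tumour output),
  starting from the pre-treatment steady state, and compared pairwise.
* ``simulate_reduced_model`` integrates the two-compartment surrogate in
  which the whole endosomal subsystem is collapsed into a plasma-dependent
  elimination f(x1) equal to the steady-state FCR — a quasi-steady-state
  reduction valid while synthesis changes slowly relative to endosomal
  turnover.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core_model import (
    IntegrationError,
    KineticParameters,
    SynthesisProfile,
    literature_parameters,
    simulate_nonlinear,
    steady_state,
)
from .tracer import FcrCurveParameters, REFERENCE_PSI, fcr_endogenous

__all__ = [
    "CANDIDATE_PARAMETERS",
    "EnsembleSpec",
    "TrajectoryComparison",
    "enumerate_triples",
    "solve_remaining_parameters",
    "build_clinical_ensemble",
    "myeloma_input",
    "simulate_ensemble",
    "simulate_reduced_model",
    "compare_trajectories",
]

#: The five parameters left free by the FCR-curve fit.  ``binding_ratio``
#: is the lumped association constant kon/v3.
CANDIDATE_PARAMETERS = ("k03", "Rtot", "koff", "k14", "binding_ratio")


def enumerate_triples() -> tuple[tuple[str, str, str], ...]:
    """The 7 admissible triples of candidate parameters to fix.

    C(5,3) = 10 combinations, minus the 3 that contain both Rtot and k14
    (fixing both would conflict with ψ2 = k14·Rtot).
    """
    return tuple(
        t for t in combinations(CANDIDATE_PARAMETERS, 3) if not {"Rtot", "k14"} <= set(t)
    )


class ParameterRejectionError(ValueError):
    """The ψ identities force a nonpositive parameter for these fixed values."""


def solve_remaining_parameters(
    fixed: dict[str, float], psi: FcrCurveParameters
) -> dict[str, float]:
    """Complete {k03, Rtot, koff, k14, binding_ratio} from 3 fixed values.

    The two identities ψ1 = k03·(k14+koff)/(kon/v3) and ψ2 = k14·Rtot are
    solved for the two unfixed parameters.  Raises
    ``ParameterRejectionError`` when a solved value is nonpositive (the
    caller redraws).
    """
    if len(fixed) != 3 or not set(fixed) <= set(CANDIDATE_PARAMETERS):
        raise ValueError(f"fixed must name exactly 3 of {CANDIDATE_PARAMETERS}")
    if {"Rtot", "k14"} <= set(fixed):
        raise ValueError("a fixed triple may not contain both Rtot and k14")
    q = dict(fixed)
    unknown = [n for n in CANDIDATE_PARAMETERS if n not in q]
    if set(unknown) == {"Rtot", "k14"}:
        q["k14"] = psi.psi1 * q["binding_ratio"] / q["k03"] - q["koff"]
        if q["k14"] <= 0:
            raise ParameterRejectionError("solved k14 is nonpositive")
        q["Rtot"] = psi.psi2 / q["k14"]
    else:
        if "Rtot" in unknown:
            q["Rtot"] = psi.psi2 / q["k14"]
        elif "k14" in unknown:
            q["k14"] = psi.psi2 / q["Rtot"]
        other = next(n for n in unknown if n not in ("Rtot", "k14"))
        if other == "k03":
            q["k03"] = psi.psi1 * q["binding_ratio"] / (q["k14"] + q["koff"])
        elif other == "koff":
            q["koff"] = psi.psi1 * q["binding_ratio"] / q["k03"] - q["k14"]
        elif other == "binding_ratio":
            q["binding_ratio"] = q["k03"] * (q["k14"] + q["koff"]) / psi.psi1
    if any(v <= 0 or not np.isfinite(v) for v in q.values()):
        raise ParameterRejectionError(f"nonpositive solved parameter in {q}")
    return q


@dataclass(frozen=True)
class EnsembleSpec:
    """Configuration of the ψ-constrained parameter ensemble.

    ``lognormal_sigma`` is the SD of the underlying normal on the log scale
    (σ = 1 spans several orders of magnitude across draws); medians default
    to the literature values.
    """

    psi: FcrCurveParameters = REFERENCE_PSI
    k21: float = 0.51
    k12: float = 0.41
    draws_per_triple: int = 10
    lognormal_sigma: float = 1.0
    medians: dict[str, float] | None = None
    seed: int = 0
    max_redraws: int = 100

    def median_values(self) -> dict[str, float]:
        if self.medians is not None:
            return dict(self.medians)
        lit = literature_parameters()
        return {
            "k03": lit.k03,
            "Rtot": lit.Rtot,
            "koff": lit.koff,
            "k14": lit.k14,
            "binding_ratio": lit.binding_ratio,
        }


def build_clinical_ensemble(spec: EnsembleSpec) -> tuple[KineticParameters, ...]:
    """70 parameter vectors on the ψ manifold; deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    lit = literature_parameters()
    medians = spec.median_values()
    members = []
    for triple in enumerate_triples():
        n_kept = 0
        attempts = 0
        while n_kept < spec.draws_per_triple:
            attempts += 1
            if attempts > spec.max_redraws * spec.draws_per_triple:
                raise RuntimeError(f"repeated rejection while drawing triple {triple}")
            fixed = {
                name: medians[name] * float(np.exp(rng.normal(0.0, spec.lognormal_sigma)))
                for name in triple
            }
            try:
                q = solve_remaining_parameters(fixed, spec.psi)
            except ParameterRejectionError:
                continue
            members.append(
                KineticParameters(
                    k21=spec.k21,
                    k31=spec.psi.k31,
                    k12=spec.k12,
                    k14=q["k14"],
                    k03=q["k03"],
                    kon=q["binding_ratio"] * lit.v3,
                    koff=q["koff"],
                    Rtot=q["Rtot"],
                    v1=lit.v1,
                    v3=lit.v3,
                )
            )
            n_kept += 1
    return tuple(members)


def myeloma_input(t, I0: float = 76.0, Iinf: float = 26.5, kkill: float = 0.055):
    """Myeloma synthesis rate I(t) = (I0 − I∞)·e^(−kkill·t) + I∞ (μmol/day)."""
    return SynthesisProfile.myeloma(I0, Iinf, kkill).rate(t)


def default_time_grid(horizon: float = 150.0, step: float = 0.25) -> np.ndarray:
    """150-day horizon at 0.25-day output resolution: with kkill ≈ 0.055
    day⁻¹ the synthesis transition is ~98% complete by day 70."""
    return np.arange(0.0, horizon + step / 2, step)


def simulate_ensemble(
    members,
    synth: SynthesisProfile,
    times: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate every member from its I(0) steady state; returns (times, X).

    X has shape (n_members, n_times, 4).  All members share the same x1(0)
    and x2(0): the steady-state plasma and peripheral quantities depend on
    the parameters only through ψ.
    """
    if times is None:
        times = default_time_grid()
    X = np.empty((len(members), len(times), 4))
    for m, params in enumerate(members):
        x0 = steady_state(params, synth.rate(0.0)).as_array()
        X[m] = simulate_nonlinear(params, synth, x0, times, rtol=rtol, atol=atol)
    return times, X


def _reduced_rhs(t, x, psi, k21, k12, synth):
    x1, x2 = x
    if x1 <= 0:
        raise IntegrationError(f"reduced model left its domain: x1 = {x1} at t = {t}")
    f = fcr_endogenous(psi, x1)
    return [-(k21 + f) * x1 + k12 * x2 + synth.rate(t), k21 * x1 - k12 * x2]


def simulate_reduced_model(
    psi: FcrCurveParameters,
    k21: float,
    k12: float,
    synth: SynthesisProfile,
    x0: tuple[float, float] | None = None,
    times: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-compartment surrogate: elimination at the steady-state FCR.

    ẋ1 = −(k21 + f(x1))·x1 + k12·x2 + I(t), ẋ2 = k21·x1 − k12·x2 with
    f = fcr_endogenous(ψ, ·).  When ``x0`` is omitted the model starts at
    its own steady state for I(0): f(x1)·x1 = I(0), x2 = (k21/k12)·x1 —
    which coincides with the four-compartment plasma/peripheral steady
    state for any ψ-consistent member.  Returns (times, states (n, 2)).
    """
    if times is None:
        times = default_time_grid()
    if x0 is None:
        I0 = float(synth.rate(0.0))
        x1_0 = brentq(lambda x: fcr_endogenous(psi, x) * x - I0, 1e-9, 1e9, xtol=1e-12, rtol=1e-14)
        x0 = (x1_0, k21 / k12 * x1_0)
    sol = solve_ivp(
        _reduced_rhs,
        (times[0], times[-1]),
        np.asarray(x0, dtype=float),
        t_eval=times,
        args=(psi, k21, k12, synth),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"reduced-model integration failed: {sol.message}")
    return times, sol.y.T


@dataclass(frozen=True)
class TrajectoryComparison:
    """Maximal pointwise percent differences between trajectories."""

    times: np.ndarray
    profile: np.ndarray  # per-time maximal percent difference
    max_percent: float
    argmax_time: float


def compare_trajectories(
    runs: np.ndarray, times: np.ndarray, reference: str | int = "pairwise"
) -> TrajectoryComparison:
    """Maximal relative difference (in %) across a set of x(t) series.

    ``runs`` is (n_runs, n_times).  With ``reference="pairwise"`` the
    statistic is max over time and run pairs of |a − b| / min(a, b) · 100;
    with an integer reference it is max over time and runs of
    |x − x_ref| / x_ref · 100.
    """
    runs = np.asarray(runs, dtype=float)
    times = np.asarray(times, dtype=float)
    if runs.ndim != 2 or runs.shape[1] != len(times):
        raise ValueError("runs must be (n_runs, n_times) on the common time grid")
    if np.any(runs <= 0):
        raise ValueError("trajectory values must be positive for relative comparison")
    if reference == "pairwise":
        profile = (runs.max(axis=0) - runs.min(axis=0)) / runs.min(axis=0) * 100.0
    else:
        ref = runs[int(reference)]
        profile = np.max(np.abs(runs - ref) / ref, axis=0) * 100.0
    i = int(np.argmax(profile))
    return TrajectoryComparison(
        times=times,
        profile=profile,
        max_percent=float(profile[i]),
        argmax_time=float(times[i]),
    )
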