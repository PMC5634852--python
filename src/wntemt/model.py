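"""Core ODE model of the Wnt-driven epithelial-mesenchymal transition.

Three species form a double-negative feedback loop with one positive leg:
membrane-bound E-cadherin (E) sequesters free cytosolic beta-catenin (B);
beta-catenin translocates to the nucleus and upregulates the transcription
factor Slug (S); Slug represses E-cadherin transcription.  Dishevelled (Dvl,
the input signal D) inactivates the GSK-3beta/Axin degradation complex and
thereby spares beta-catenin from degradation.  All interactions saturate and
are modelled with Hill functions; the net sign of the loop
(S -| E) * (E -| B) * (B -> S) is positive, which together with the
ultrasensitive Hill exponents makes the circuit a candidate bistable switch.

Two frames are supported: the dimensional system (nM, minutes) and its
nondimensionalization.  States and Dvl levels are rescaled by the half-maximal
constants (epsilon = IC_E, lambda = IC_B, sigma = IC_S, delta = IC_D) and time
by T = IC_B / k1, which collapses the 13 kinetic constants into 8 grouped
dimensionless parameters A1-A3, C1-C3, F1, F2.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Literal

import numpy as np

Frame = Literal["dimensional", "nondimensional"]

#: Names of the Hill exponents, shared by both frames.
HILL_NAMES = ("n1", "n2", "n3", "n4")

#: Kinetic / half-maximal constants of the dimensional system, in file order.
DIMENSIONAL_NAMES = (
    "alpha1", "alpha2", "alpha3",
    "beta1", "beta2", "beta3",
    "k0", "k1", "k2",
    "IC_S", "IC_B", "IC_E", "IC_D",
)

#: Grouped constants of the nondimensional system.
NONDIM_NAMES = ("A1", "A2", "A3", "C1", "C2", "C3", "F1", "F2")


class ParameterError(ValueError):
    """A parameter value violates the model's invariants."""


class FrameError(ValueError):
    """Dimensional and nondimensional quantities were mixed."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

def _check_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ParameterError(f"parameter {name!r} is not finite: {value!r}")


@dataclass(frozen=True)
class DimensionalParams:
    """Rate constants of the dimensional system (nM and minutes).

    alpha1-alpha3 are basal production rates (nM/min) of E-cadherin,
    beta-catenin and Slug; beta1-beta3 the first-order loss rates (1/min):
    degradation for E-cadherin and Slug, binding to the GSK-3beta degradation
    complex for beta-catenin.  k0, k1, k2 (nM/min) are the maximal rates of
    the three saturating interactions (Dvl inactivating the degradation
    complex, E-cadherin sequestering beta-catenin, beta-catenin inducing
    Slug), with half-maximal constants IC_D, IC_E, IC_B and IC_S (nM) and
    Hill exponents n4, n2, n3, n1 respectively.
    """

    alpha1: float
    alpha2: float
    alpha3: float
    beta1: float
    beta2: float
    beta3: float
    k0: float
    k1: float
    k2: float
    IC_S: float
    IC_B: float
    IC_E: float
    IC_D: float
    n1: float
    n2: float
    n3: float
    n4: float

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            _check_finite(f.name, value)
            if f.name in HILL_NAMES:
                if value < 1:
                    raise ParameterError(
                        f"Hill coefficient {f.name!r} must be >= 1, got {value}"
                    )
            elif f.name.startswith("IC_"):
                if value <= 0:
                    raise ParameterError(
                        f"half-maximal constant {f.name!r} must be > 0, got {value}"
                    )
            elif value < 0:
                raise ParameterError(
                    f"rate parameter {f.name!r} must be >= 0, got {value}"
                )

    @property
    def hill(self) -> tuple[float, float, float, float]:
        return (self.n1, self.n2, self.n3, self.n4)


@dataclass(frozen=True)
class NondimParams:
    """Grouped constants of the nondimensional system.

    A1-A3 are scaled basal production rates, C1-C3 scaled first-order loss
    rates, F1 the Dvl action strength relative to beta-catenin sequestration
    (k0/k1) and F2 the scaled Slug-induction rate (k2*IC_B/(k1*IC_S)).  The
    Hill exponents carry over unchanged from the dimensional frame.
    """

    A1: float
    A2: float
    A3: float
    C1: float
    C2: float
    C3: float
    F1: float
    F2: float
    n1: float
    n2: float
    n3: float
    n4: float

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            _check_finite(f.name, value)
            if f.name in HILL_NAMES and value < 1:
                raise ParameterError(
                    f"Hill coefficient {f.name!r} must be >= 1, got {value}"
                )
            if f.name not in HILL_NAMES and value < 0:
                raise ParameterError(
                    f"parameter {f.name!r} must be >= 0, got {value}"
                )

    @property
    def hill(self) -> tuple[float, float, float, float]:
        return (self.n1, self.n2, self.n3, self.n4)

    def replace(self, **changes: float) -> "NondimParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class ScalingConstants:
    """Characteristic scales mapping between the two frames.

    E = epsilon*e, B = lam*b, S = sigma*s, D = delta*d, t = T*tau, with
    epsilon = IC_E, lam = IC_B, sigma = IC_S, delta = IC_D and T = IC_B/k1
    (minutes) -- the time to accumulate half the beta-catenin needed to
    activate Slug at the sequestration-limited rate.
    """

    epsilon: float
    lam: float
    sigma: float
    delta: float
    T: float

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            _check_finite(f.name, value)
            if value <= 0:
                raise ParameterError(f"scaling constant {f.name!r} must be > 0")


@dataclass(frozen=True)
class CellState:
    """Concentrations of the three species at one instant.

    In the dimensional frame the components are nM; nondimensionally they are
    fractions of the corresponding half-maximal constants.  Negative values
    can arise from the verbatim equations (the sequestration term is not
    proportional to B); they are carried through unclamped and reported via
    :attr:`nonphysical`.
    """

    ecad: float
    bcat: float
    slug: float
    frame: Frame = "nondimensional"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError(f"non-finite cell state: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.ecad, self.bcat, self.slug], dtype=float)

    @property
    def nonphysical(self) -> bool:
        return bool(self.ecad < 0 or self.bcat < 0 or self.slug < 0)

    @classmethod
    def from_array(cls, y: np.ndarray, frame: Frame) -> "CellState":
        return cls(float(y[0]), float(y[1]), float(y[2]), frame)


@dataclass(frozen=True)
class DvlInput:
    """Level of membrane-bound Dishevelled, the model's input signal."""

    level: float
    frame: Frame = "nondimensional"

    def __post_init__(self) -> None:
        if not np.isfinite(self.level) or self.level < 0:
            raise ValueError(f"Dvl level must be finite and >= 0, got {self.level}")


# ---------------------------------------------------------------------------
# Hill functions
# ---------------------------------------------------------------------------

def hill_act(x, n):
    """Saturating activation x^n / (1 + x^n), in [0, 1) for finite x >= 0."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("hill_act requires finite input")
    xn = x**n
    return xn / (1.0 + xn)


def hill_rep(x, n):
    """Saturating repression 1 / (1 + x^n), in (0, 1] for finite x >= 0."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("hill_rep requires finite input")
    return 1.0 / (1.0 + x**n)


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------

def _rhs_dim(y: np.ndarray, p: DimensionalParams, D: float) -> np.ndarray:
    """Array-based dimensional RHS; y = (E, B, S) in nM, rates in nM/min."""
    E, B, S = y[0], y[1], y[2]
    dE = p.alpha1 * hill_rep(S / p.IC_S, p.n1) - p.beta1 * E
    dB = (
        p.alpha2
        - p.k1 * hill_act(E / p.IC_E, p.n2)
        - (p.beta2 * B - p.k0 * hill_act(D / p.IC_D, p.n4))
    )
    dS = p.alpha3 + p.k2 * hill_act(B / p.IC_B, p.n3) - p.beta3 * S
    return np.array([dE, dB, dS])


def _rhs_nondim(y: np.ndarray, q: NondimParams, d: float) -> np.ndarray:
    """Array-based nondimensional RHS; y = (e, b, s), rates per unit tau."""
    e, b, s = y[0], y[1], y[2]
    de = q.A1 * hill_rep(s, q.n1) - q.C1 * e
    db = q.A2 - hill_act(e, q.n2) - (q.C2 * b - q.F1 * hill_act(d, q.n4))
    ds = q.A3 + q.F2 * hill_act(b, q.n3) - q.C3 * s
    return np.array([de, db, ds])


def rhs_dimensional(
    state: CellState, p: DimensionalParams, dvl: DvlInput
) -> tuple[float, float, float]:
    """(dE/dt, dB/dt, dS/dt) in nM/min for a dimensional state and Dvl level."""
    if state.frame != "dimensional" or dvl.frame != "dimensional":
        raise FrameError("rhs_dimensional requires dimensional state and Dvl")
    dE, dB, dS = _rhs_dim(state.as_array(), p, dvl.level)
    return float(dE), float(dB), float(dS)


def rhs_nondimensional(
    state: CellState, q: NondimParams, dvl: DvlInput
) -> tuple[float, float, float]:
    """(de/dtau, db/dtau, ds/dtau) for a nondimensional state and Dvl level."""
    if state.frame != "nondimensional" or dvl.frame != "nondimensional":
        raise FrameError("rhs_nondimensional requires nondimensional state and Dvl")
    de, db, ds = _rhs_nondim(state.as_array(), q, dvl.level)
    return float(de), float(db), float(ds)


# ---------------------------------------------------------------------------
# Frame conversion
# ---------------------------------------------------------------------------

def nondimensionalize(p: DimensionalParams) -> tuple[NondimParams, ScalingConstants]:
    """Collapse the dimensional constants into the grouped nondimensional ones.

    A1 = alpha1*IC_B/(k1*IC_E), A2 = alpha2/k1, A3 = alpha3*IC_B/(k1*IC_S),
    Ci = betai*IC_B/k1, F1 = k0/k1, F2 = k2*IC_B/(k1*IC_S); Hill exponents
    pass through.  The scaling constants are epsilon = IC_E, lam = IC_B,
    sigma = IC_S, delta = IC_D, T = IC_B/k1.
    """
    if p.k1 <= 0:
        raise ParameterError("nondimensionalization requires k1 > 0")
    sc = ScalingConstants(
        epsilon=p.IC_E, lam=p.IC_B, sigma=p.IC_S, delta=p.IC_D, T=p.IC_B / p.k1
    )
    q = NondimParams(
        A1=p.alpha1 * p.IC_B / (p.k1 * p.IC_E),
        A2=p.alpha2 / p.k1,
        A3=p.alpha3 * p.IC_B / (p.k1 * p.IC_S),
        C1=p.beta1 * p.IC_B / p.k1,
        C2=p.beta2 * p.IC_B / p.k1,
        C3=p.beta3 * p.IC_B / p.k1,
        F1=p.k0 / p.k1,
        F2=p.k2 * p.IC_B / (p.k1 * p.IC_S),
        n1=p.n1, n2=p.n2, n3=p.n3, n4=p.n4,
    )
    return q, sc


def to_nondim_state(state: CellState, sc: ScalingConstants) -> CellState:
    if state.frame != "dimensional":
        raise FrameError("to_nondim_state expects a dimensional state")
    return CellState(
        state.ecad / sc.epsilon, state.bcat / sc.lam, state.slug / sc.sigma,
        "nondimensional",
    )


def to_dim_state(state: CellState, sc: ScalingConstants) -> CellState:
    if state.frame != "nondimensional":
        raise FrameError("to_dim_state expects a nondimensional state")
    return CellState(
        state.ecad * sc.epsilon, state.bcat * sc.lam, state.slug * sc.sigma,
        "dimensional",
    )


# ---------------------------------------------------------------------------
# Analytic Jacobians
# ---------------------------------------------------------------------------

def _hill_act_deriv(x: float, n: float) -> float:
    # d/dx [x^n/(1+x^n)] = n x^(n-1) / (1+x^n)^2; x >= 0 enforced by callers
    return n * x ** (n - 1.0) / (1.0 + x**n) ** 2


def jacobian(
    state: CellState,
    params: DimensionalParams | NondimParams,
    dvl: DvlInput,
    frame: Frame | None = None,
) -> np.ndarray:
    """3x3 matrix of partial derivatives of the RHS at ``state``.

    The loop structure is cyclic: d(de)/ds < 0 (Slug represses E-cadherin),
    d(db)/de < 0 (E-cadherin sequesters beta-catenin), d(ds)/db > 0
    (beta-catenin induces Slug); the diagonal holds the linear loss rates.
    Negative state components are rejected: x^(n-1) is not defined for the
    model's intent there.
    """
    if frame is None:
        frame = state.frame
    if frame != state.frame or frame != dvl.frame:
        raise FrameError("jacobian: state, Dvl and requested frame disagree")
    y = state.as_array()
    if np.any(y < 0):
        raise ValueError("jacobian requires nonnegative state components")

    if frame == "dimensional":
        if not isinstance(params, DimensionalParams):
            raise FrameError("dimensional jacobian requires DimensionalParams")
        p = params
        E, B, S = y
        J = np.zeros((3, 3))
        J[0, 0] = -p.beta1
        # d/dS [alpha1/(1+(S/IC_S)^n1)] shares its kernel with the
        # activation slope, up to sign and the 1/IC_S chain factor.
        J[0, 2] = -p.alpha1 * _hill_act_deriv(S / p.IC_S, p.n1) / p.IC_S
        J[1, 0] = -p.k1 * _hill_act_deriv(E / p.IC_E, p.n2) / p.IC_E
        J[1, 1] = -p.beta2
        J[2, 1] = p.k2 * _hill_act_deriv(B / p.IC_B, p.n3) / p.IC_B
        J[2, 2] = -p.beta3
        return J

    if not isinstance(params, NondimParams):
        raise FrameError("nondimensional jacobian requires NondimParams")
    q = params
    e, b, s = y
    J = np.zeros((3, 3))
    J[0, 0] = -q.C1
    J[0, 2] = -q.A1 * _hill_act_deriv(s, q.n1)
    J[1, 0] = -_hill_act_deriv(e, q.n2)
    J[1, 1] = -q.C2
    J[2, 1] = q.F2 * _hill_act_deriv(b, q.n3)
    J[2, 2] = -q.C3
    return J
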