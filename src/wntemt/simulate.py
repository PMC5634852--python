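"""Time integration, steady-state detection and equilibrium enumeration.

The switch experiments drive the cell with a piecewise-constant Dvl signal
(Wnt on / Wnt off); trajectories are integrated segment by segment with a
stiff-capable adaptive solver.  Equilibria are enumerated exactly through a
one-dimensional reduction: at steady state the E-cadherin and Slug equations
give e* and s* as explicit functions of b, leaving a scalar residual g(b)
from the beta-catenin equation whose roots are the system's fixed points.
The same reduction applies verbatim to the dimensional frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    CellState,
    DimensionalParams,
    DvlInput,
    Frame,
    FrameError,
    NondimParams,
    _rhs_dim,
    _rhs_nondim,
    hill_act,
    hill_rep,
    jacobian,
)

#: Infinity-norm of the RHS below which a state counts as stationary.
STEADY_STATE_TOL = 1e-9

#: Default integration tolerances (well inside the required 1e-8 / 1e-10).
RTOL = 1e-10
ATOL = 1e-12

#: Roots of the scalar residual closer than this in b are merged (near-fold).
ROOT_MERGE_TOL = 1e-6


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced a non-finite state."""


class ConvergenceError(RuntimeError):
    """A steady state was not reached within the time cap."""


class LimitCycleError(RuntimeError):
    """The trajectory settles onto a periodic orbit instead of a fixed point."""


# ---------------------------------------------------------------------------
# Signal protocols and trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalProtocol:
    """Piecewise-constant, right-continuous Dvl signal.

    ``segments`` is an ordered list of (switch_time, level) pairs; the first
    segment must start at time 0 and switch times must strictly increase.
    """

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        times = [t for t, _ in self.segments]
        if times[0] != 0:
            raise ValueError("first protocol segment must start at time 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("protocol switch times must strictly increase")
        if any(level < 0 for _, level in self.segments):
            raise ValueError("Dvl levels must be >= 0")

    @classmethod
    def constant(cls, level: float) -> "SignalProtocol":
        return cls(((0.0, float(level)),))

    def level_at(self, t: float) -> float:
        level = self.segments[0][1]
        for t_sw, lv in self.segments:
            if t >= t_sw:
                level = lv
            else:
                break
        return level

    def switch_times(self) -> list[float]:
        return [t for t, _ in self.segments[1:]]


@dataclass
class Trajectory:
    """Dense solution of one protocol run."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), 3), columns (e, b, s) or (E, B, S)
    dvl: np.ndarray
    frame: Frame
    nonphysical: bool

    def final_state(self) -> CellState:
        return CellState.from_array(self.states[-1], self.frame)


@dataclass
class Equilibrium:
    """A fixed point of the model with its local stability and phenotype."""

    state: CellState
    stable: bool
    max_real_eig: float
    phenotype: str = "unlabeled"  # epithelial | mesenchymal | unlabeled
    nonphysical: bool = False
    near_fold: bool = False


def _rhs_for(params, frame: Frame):
    if frame == "dimensional":
        if not isinstance(params, DimensionalParams):
            raise FrameError("dimensional run requires DimensionalParams")
        return _rhs_dim
    if not isinstance(params, NondimParams):
        raise FrameError("nondimensional run requires NondimParams")
    return _rhs_nondim


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def simulate(
    params,
    protocol: SignalProtocol,
    init: CellState,
    t_end: float,
    frame: Frame = "nondimensional",
    n_points: int = 2000,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the model under a piecewise-constant Dvl protocol.

    The integrator restarts at each switch time so the discontinuous input
    never crosses a solver step.  Output is sampled on a uniform grid of
    ``n_points`` over [0, t_end].
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if init.frame != frame:
        raise FrameError("initial state frame does not match run frame")
    rhs = _rhs_for(params, frame)

    t_grid = np.linspace(0.0, t_end, n_points)
    breaks = [0.0] + [t for t in protocol.switch_times() if t < t_end] + [t_end]
    out_states = np.empty((n_points, 3))
    out_dvl = np.empty(n_points)
    y = init.as_array()
    for a, b in zip(breaks, breaks[1:]):
        d = protocol.level_at(a)
        mask = (t_grid >= a) & (t_grid <= b)
        t_eval = np.unique(np.concatenate([t_grid[mask], [a, b]]))
        sol = solve_ivp(
            lambda t, yy: rhs(yy, params, d),
            (a, b), y, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"integrator failed near t = {sol.t[-1]:g}: {sol.message}")
        if not np.all(np.isfinite(sol.y)):
            raise IntegrationError(f"non-finite state in segment [{a:g}, {b:g}]")
        idx = np.searchsorted(sol.t, t_grid[mask])
        out_states[mask] = sol.y[:, idx].T
        out_dvl[mask] = d
        y = sol.y[:, -1]

    return Trajectory(
        t=t_grid,
        states=out_states,
        dvl=out_dvl,
        frame=frame,
        nonphysical=bool(np.any(out_states < 0)),
    )


def _stability(y: np.ndarray, params, dvl_level: float, frame: Frame) -> float:
    """Largest eigenvalue real part of the Jacobian at y.

    Nonnegative states use the analytic Jacobian; states with a negative
    component (nonphysical fixed points the verbatim equations admit) fall
    back to a central-difference Jacobian of the RHS.
    """
    if np.all(y >= 0):
        J = jacobian(
            CellState.from_array(y, frame), params, DvlInput(dvl_level, frame), frame
        )
    else:
        rhs = _rhs_for(params, frame)
        J = np.empty((3, 3))
        h = 1e-7 * max(1.0, float(np.max(np.abs(y))))
        for j in range(3):
            dy = np.zeros(3)
            dy[j] = h
            J[:, j] = (rhs(y + dy, params, dvl_level) - rhs(y - dy, params, dvl_level)) / (2 * h)
    return float(np.max(np.real(np.linalg.eigvals(J))))


def steady_state(
    params,
    dvl: float,
    init: CellState,
    frame: Frame = "nondimensional",
    tol: float = STEADY_STATE_TOL,
    t_cap: float = 1e4,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Equilibrium:
    """Long-run limit of the model at constant Dvl, from a given start.

    Integrates in growing chunks until the RHS infinity-norm drops below
    ``tol``; raises :class:`ConvergenceError` past ``t_cap``, or
    :class:`LimitCycleError` if the residual plateaus while the state keeps
    moving (not expected for this monotone circuit, but detected).
    """
    rhs = _rhs_for(params, frame)
    y = init.as_array()
    t, chunk = 0.0, 50.0
    res_hist: list[float] = []
    while t < t_cap:
        sol = solve_ivp(
            lambda tt, yy: rhs(yy, params, dvl),
            (t, min(t + chunk, t_cap)), y, method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            raise IntegrationError(f"integrator failed near t = {sol.t[-1]:g}")
        y_prev, y = y, sol.y[:, -1]
        t = sol.t[-1]
        res = float(np.max(np.abs(rhs(y, params, dvl))))
        if res < tol:
            lead = _stability(y, params, dvl, frame)
            return Equilibrium(
                state=CellState.from_array(y, frame),
                stable=lead < 0,
                max_real_eig=lead,
                nonphysical=bool(np.any(y < 0)),
            )
        res_hist.append(res)
        if (
            len(res_hist) >= 4
            and res_hist[-1] > 0.5 * res_hist[-4]
            and np.max(np.abs(y - y_prev)) > 100 * res_hist[-1]
        ):
            raise LimitCycleError(
                f"residual plateau at {res:g} with a moving state: "
                "possible periodic orbit"
            )
        chunk = min(2 * chunk, 2000.0)
    raise ConvergenceError(f"no steady state within t = {t_cap:g} (residual {res:g})")


# ---------------------------------------------------------------------------
# Scalar equilibrium reduction
# ---------------------------------------------------------------------------

def scalar_reduction(params, dvl_level: float, frame: Frame = "nondimensional"):
    """Return (g, reconstruct, b_lo, b_hi, b_scale) for the 1-D fixed-point
    residual.

    Setting de/dt = ds/dt = 0 expresses e* and s* in terms of b; g(b) is the
    remaining beta-catenin balance whose zeros are the model's fixed points.
    ``reconstruct(b)`` maps a root back to the full (e, b, s) state.  The
    default scan bracket extends below b = 0 so the nonphysical negative-b
    fixed points the verbatim equations admit are found, not dropped.
    """
    if frame == "nondimensional":
        q: NondimParams = params
        if q.C1 <= 0 or q.C3 <= 0:
            raise ValueError("scalar reduction requires C1 > 0 and C3 > 0")
        if q.C2 <= 0:
            raise ValueError("scalar reduction requires C2 > 0")
        drive = q.F1 * float(hill_act(dvl_level, q.n4))

        def s_of_b(b):
            return (q.A3 + q.F2 * _signed_hill(b, q.n3)) / q.C3

        def e_of_s(s):
            return q.A1 * hill_rep(s, q.n1) / q.C1

        def g(b):
            return q.A2 - _signed_hill(e_of_s(s_of_b(b)), q.n2) - q.C2 * np.asarray(b) + drive

        b_lo = -0.5
        b_hi = q.A2 / q.C2 + q.F1 / q.C2 + 0.5
        b_scale = 1.0
    else:
        p: DimensionalParams = params
        if p.beta1 <= 0 or p.beta3 <= 0:
            raise ValueError("scalar reduction requires beta1 > 0 and beta3 > 0")
        if p.beta2 <= 0:
            raise ValueError("scalar reduction requires beta2 > 0")
        drive = p.k0 * float(hill_act(dvl_level / p.IC_D, p.n4))

        def s_of_b(b):
            return (p.alpha3 + p.k2 * _signed_hill(np.asarray(b) / p.IC_B, p.n3)) / p.beta3

        def e_of_s(s):
            return p.alpha1 * hill_rep(s / p.IC_S, p.n1) / p.beta1

        def g(b):
            return (
                p.alpha2
                - p.k1 * _signed_hill(e_of_s(s_of_b(b)) / p.IC_E, p.n2)
                - p.beta2 * np.asarray(b)
                + drive
            )

        b_lo = -0.5 * p.IC_B
        b_hi = (p.alpha2 + p.k0) / p.beta2 + 0.5 * p.IC_B
        b_scale = p.IC_B

    def reconstruct(b: float) -> np.ndarray:
        s = float(s_of_b(b))
        e = float(e_of_s(s))
        return np.array([e, b, s])

    return g, reconstruct, b_lo, b_hi, b_scale


def _scan_grid(b_lo: float, b_hi: float, b_scale: float, n_scan: int) -> np.ndarray:
    """Scan grid for g(b): dense where the Hill terms vary, coarse beyond.

    Both saturating terms of the residual vary on the b_scale scale; past
    ~25 scales g is strictly decreasing (slope -C2 plus vanishing tails), so
    at most one root lies out there and a coarse linear tail suffices.  This
    keeps small loss rates -- which push the bracket far out -- from diluting
    the dense grid where the fold structure lives.
    """
    dense_hi = min(b_hi, max(25.0 * b_scale, b_lo + b_scale))
    grid = np.linspace(b_lo, dense_hi, n_scan)
    if b_hi > dense_hi:
        grid = np.concatenate([grid, np.linspace(dense_hi, b_hi, 513)[1:]])
    return grid


def _signed_hill(x, n):
    """Hill activation evaluated verbatim, defined for negative x when the
    exponent is an (even/odd) integer -- matching the raw equations."""
    x = np.asarray(x, dtype=float)
    xn = np.power(x, n)
    return xn / (1.0 + xn)


def _bisect(g, a: float, b: float, fa: float, fb: float) -> float:
    """Bisection to |g| < 1e-12 (or machine-width interval), then one Newton
    polish with a numerical derivative."""
    for _ in range(200):
        m = 0.5 * (a + b)
        fm = float(g(m))
        if abs(fm) < 1e-12 or (b - a) < 1e-15 * max(1.0, abs(m)):
            break
        if fa * fm <= 0:
            b, fb = m, fm
        else:
            a, fa = m, fm
    h = 1e-8 * max(1.0, abs(m))
    slope = (float(g(m + h)) - float(g(m - h))) / (2 * h)
    if slope != 0 and np.isfinite(slope):
        step = fm / slope
        if abs(step) < (b - a) + h:
            m = m - step
    return m


def find_equilibria(
    params,
    dvl: float,
    frame: Frame = "nondimensional",
    n_scan: int = 10001,
    b_range: tuple[float, float] | None = None,
) -> list[Equilibrium]:
    """All fixed points at a constant Dvl level, sorted by b.

    Scans the scalar residual g(b) on a dense grid, bisects every sign
    change, reconstructs the full states and classifies local stability from
    Jacobian eigenvalues.  For this circuit the result is one or three
    equilibria; when two stable ones coexist the high-e point is labeled
    epithelial and the low-e point mesenchymal.  Roots closer than
    ``ROOT_MERGE_TOL`` in b are merged and flagged near-fold; negative-b
    fixed points are returned flagged nonphysical.
    """
    g, reconstruct, b_lo, b_hi, b_scale = scalar_reduction(params, dvl, frame)
    if b_range is not None:
        b_lo, b_hi = b_range
    bs = _scan_grid(b_lo, b_hi, b_scale, n_scan)
    gs = np.asarray(g(bs), dtype=float)
    finite = np.isfinite(gs)

    roots: list[float] = []
    for i in range(len(bs) - 1):
        if not (finite[i] and finite[i + 1]):
            continue
        if gs[i] == 0.0:
            roots.append(float(bs[i]))
        elif gs[i] * gs[i + 1] < 0:
            roots.append(_bisect(g, float(bs[i]), float(bs[i + 1]), float(gs[i]), float(gs[i + 1])))
    if finite[-1] and gs[-1] == 0.0:
        roots.append(float(bs[-1]))

    if not roots:
        raise RuntimeError(
            "no equilibrium found -- impossible for positive loss rates; "
            "check parameters"
        )

    # merge near-coincident roots (fold in formation)
    merged: list[tuple[float, bool]] = []
    for r in sorted(roots):
        if merged and abs(r - merged[-1][0]) < ROOT_MERGE_TOL:
            merged[-1] = (0.5 * (r + merged[-1][0]), True)
        else:
            merged.append((r, False))

    out: list[Equilibrium] = []
    for b_root, near_fold in merged:
        y = reconstruct(b_root)
        lead = _stability(y, params, dvl, frame)
        out.append(
            Equilibrium(
                state=CellState.from_array(y, frame),
                stable=lead < 0,
                max_real_eig=lead,
                nonphysical=bool(np.any(y < 0)),
                near_fold=near_fold,
            )
        )
    out.sort(key=lambda eq: eq.state.bcat)
    _auto_label(out)
    return out


def _auto_label(eqs: list[Equilibrium]) -> None:
    stable = [eq for eq in eqs if eq.stable]
    if len(stable) >= 2:
        for eq in stable:
            eq.phenotype = label_phenotype(eq, eqs)


def label_phenotype(eq: Equilibrium, context: list[Equilibrium]) -> str:
    """Phenotype of one stable fixed point among its coexisting alternatives.

    With two stable states the high-E-cadherin point is the epithelial
    phenotype and the low one mesenchymal.  A unique stable point cannot be
    labeled from a single Dvl level (branch continuation in the bifurcation
    module does that) and stays unlabeled; an exact E-cadherin tie is
    reported as an error.
    """
    stable = [c for c in context if c.stable]
    if len(stable) < 2:
        return "unlabeled"
    es = [c.state.ecad for c in stable]
    if len(set(es)) < len(es):
        raise ValueError("degenerate equal-E-cadherin stable pair; cannot label")
    if eq.state.ecad == max(es):
        return "epithelial"
    if eq.state.ecad == min(es):
        return "mesenchymal"
    return "unlabeled"
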