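"""Shared fixtures: reference parameter sets, an independent Newton-multistart
equilibrium oracle, and one session-scoped sensitivity run reused by several
tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import root as scipy_root

import wntemt as w
from wntemt.model import _rhs_dim, _rhs_nondim
from wntemt import sensitivity as sens


@pytest.fixture(scope="session")
def table1():
    return w.load_params(w.fixture_path("table1"), "dimensional")


@pytest.fixture(scope="session")
def table2():
    return w.load_params(w.fixture_path("table2"), "nondimensional")


@pytest.fixture(scope="session")
def table2_exact():
    return w.load_params(w.fixture_path("table2_exact"), "nondimensional")


@pytest.fixture(scope="session")
def table4_ranges():
    return w.sampled_ranges(w.load_ranges(w.fixture_path("table4"), "nondimensional"))


@pytest.fixture
def epithelial_init():
    return w.CellState(10.0, 0.0, 0.0, "nondimensional")


def newton_equilibria(params, dvl, frame="nondimensional", n_grid=4):
    """Independent equilibrium finder: damped-Newton (hybr) refinement of the
    full 3-D system from a lattice of starting points, deduplicated.

    Deliberately shares nothing with the scalar-scan reduction it is used to
    cross-check.
    """
    rhs = _rhs_nondim if frame == "nondimensional" else _rhs_dim
    if frame == "nondimensional":
        e_max = params.A1 / max(params.C1, 1e-3) + 1.0
        b_max = (params.A2 + params.F1) / max(params.C2, 1e-3) + 1.0
        s_max = (params.A3 + params.F2) / max(params.C3, 1e-3) + 1.0
    else:
        e_max = params.alpha1 / max(params.beta1, 1e-4) + 1.0
        b_max = (params.alpha2 + params.k0) / max(params.beta2, 1e-4) + 1.0
        s_max = (params.alpha3 + params.k2) / max(params.beta3, 1e-4) + 1.0
    starts = [
        np.array([e, b, s])
        for e in np.linspace(0, e_max, n_grid)
        for b in np.linspace(-0.4, b_max, n_grid + 1)
        for s in np.linspace(0, s_max, n_grid)
    ]
    found = []
    for y0 in starts:
        sol = scipy_root(lambda y: rhs(y, params, dvl), y0, method="hybr",
                         options={"xtol": 1e-13})
        if not sol.success:
            continue
        y = sol.x
        if np.max(np.abs(rhs(y, params, dvl))) > 1e-9:
            continue
        if not any(np.allclose(y, f, rtol=1e-6, atol=1e-8) for f in found):
            found.append(y)
    return sorted(found, key=lambda y: y[1])


@pytest.fixture(scope="session")
def newton_oracle():
    return newton_equilibria


def run_sensitivity(frame, dvl, N, seed, method="partial"):
    tbl = "table3" if frame == "dimensional" else "table4"
    dflt = "table1" if frame == "dimensional" else "table2"
    ranges = w.sampled_ranges(w.load_ranges(w.fixture_path(tbl), frame))
    defaults = w.load_params(w.fixture_path(dflt), frame)
    design = sens.lhs_sample(ranges, N, seed)
    outputs = sens.evaluate_outputs(design, dvl, frame, defaults)
    return design, outputs


@pytest.fixture(scope="session")
def sensitivity_runs():
    """LHS designs and steady-state outputs for the four Fig-4 analyses at
    N = 1e4 (computed once per session; the heavy part of the suite)."""
    runs = {}
    for frame, dvl in [
        ("dimensional", 0.0), ("dimensional", 4.0),
        ("nondimensional", 0.0), ("nondimensional", 6.0),
    ]:
        runs[(frame, dvl)] = run_sensitivity(frame, dvl, N=10_000, seed=1)
    return runs
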