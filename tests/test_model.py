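"""Model core: Hill functions, right-hand sides, scaling, Jacobians."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wntemt as w
from wntemt.model import FrameError, ParameterError, _rhs_nondim


class TestHill:
    @pytest.mark.parametrize(
        "x, n, expected",
        [
            (0.0, 5, 0.0),
            (1.0, 2, 0.5),
            (1.0, 7, 0.5),
            (1.2, 5, 1.2**5 / (1 + 1.2**5)),  # ~0.71333, the Dvl drive kernel
        ],
    )
    def test_activation_values(self, x, n, expected):
        assert w.hill_act(x, n) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "x, n, expected", [(0.0, 3, 1.0), (1.0, 3, 0.5), (2.0, 3, 1 / 9)]
    )
    def test_repression_values(self, x, n, expected):
        assert w.hill_rep(x, n) == pytest.approx(expected, abs=1e-12)

    @given(
        x=st.floats(0, 50, allow_nan=False),
        n=st.floats(1, 8, allow_nan=False),
    )
    @settings(deadline=None, max_examples=100)
    def test_activation_and_repression_are_complementary(self, x, n):
        assert w.hill_act(x, n) + w.hill_rep(x, n) == pytest.approx(1.0)

    def test_activation_monotone_and_bounded(self):
        x = np.linspace(0, 100, 2001)
        y = w.hill_act(x, 3)
        assert np.all(np.diff(y) > 0)
        assert y[0] == 0 and np.all(y < 1)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            w.hill_act(np.nan, 2)
        with pytest.raises(ValueError):
            w.hill_rep(np.inf, 2)


class TestRHS:
    def test_dimensional_ecadherin_balance_at_baseline(self, table1):
        # at (E, B, S) = (0.33, 0, 0), D = 0: dE/dt = alpha1 - beta1*0.33
        state = w.CellState(0.33, 0.0, 0.0, "dimensional")
        dE, dB, dS = w.rhs_dimensional(state, table1, w.DvlInput(0.0, "dimensional"))
        assert dE == pytest.approx(1.0e-4, rel=1e-9)

    def test_dimensional_slug_halfmax(self, table1):
        # B = IC_B sits at the half-maximal point of the induction term
        state = w.CellState(0.0, table1.IC_B, 2.0, "dimensional")
        _, _, dS = w.rhs_dimensional(state, table1, w.DvlInput(0.0, "dimensional"))
        expected = table1.alpha3 + table1.k2 / 2 - table1.beta3 * 2.0
        assert dS == pytest.approx(expected, rel=1e-12)

    def test_dimensional_rhs_vanishes_at_epithelial_fixed_point(self, table1):
        eq = w.find_equilibria(table1, 0.0, frame="dimensional")[0]
        rates = w.rhs_dimensional(eq.state, table1, w.DvlInput(0.0, "dimensional"))
        assert np.max(np.abs(rates)) < 1e-8

    def test_nondimensional_values(self, table2):
        state = w.CellState(10.0, 0.0, 0.0)
        de, db, ds = w.rhs_nondimensional(state, table2, w.DvlInput(0.0))
        assert de == pytest.approx(0.0, abs=1e-12)
        assert db == pytest.approx(1 - 100 / 101, rel=1e-12)
        assert ds == pytest.approx(0.01, rel=1e-12)

    def test_origin_rates_are_basal_productions(self, table2):
        state = w.CellState(0.0, 0.0, 0.0)
        rates = w.rhs_nondimensional(state, table2, w.DvlInput(0.0))
        assert rates == pytest.approx((table2.A1, table2.A2, table2.A3))

    def test_dvl_drive_term(self, table2):
        # the F1 * hill(d) drive behind the supra-threshold pulse
        drive = table2.F1 * w.hill_act(5.4, table2.n4)
        assert drive == pytest.approx(0.36992, abs=5e-5)

    def test_production_terms_bounded(self, table2):
        rng = np.random.default_rng(0)
        for _ in range(200):
            e, b, s = rng.uniform(0, 20, 3)
            assert 0 <= table2.A1 * w.hill_rep(s, table2.n1) <= table2.A1
            assert 0 <= table2.F2 * w.hill_act(b, table2.n3) <= table2.F2

    def test_frame_mismatch_rejected(self, table2):
        with pytest.raises(FrameError):
            w.rhs_nondimensional(
                w.CellState(1, 1, 1, "dimensional"), table2, w.DvlInput(0.0)
            )


class TestParameters:
    def test_negative_ic50_rejected(self):
        with pytest.raises(ParameterError):
            w.NondimParams(10, 1, 0.01, 1, 1, 1, -0.37, 10, 3, 2, 2, 5)
        kwargs = dict(
            alpha1=0.01, alpha2=0.01, alpha3=0.001, beta1=0.03, beta2=0.03,
            beta3=0.03, k0=3.7e-3, k1=0.01, k2=1.0, IC_S=3.3, IC_B=0.33,
            IC_E=0.033, IC_D=-0.67, n1=3, n2=2, n3=2, n4=5,
        )
        with pytest.raises(ParameterError):
            w.DimensionalParams(**kwargs)

    def test_hill_coefficient_below_one_rejected(self):
        with pytest.raises(ParameterError):
            w.NondimParams(10, 1, 0.01, 1, 1, 1, 0.37, 10, 0.5, 2, 2, 5)

    def test_nonphysical_flag(self):
        assert w.CellState(1.0, -0.01, 2.0).nonphysical
        assert not w.CellState(1.0, 0.0, 2.0).nonphysical


class TestNondimensionalization:
    def test_grouped_constants_match_published_values(self, table1):
        q, sc = w.nondimensionalize(table1)
        assert q.F1 == pytest.approx(0.37, rel=1e-12)
        assert q.A1 == pytest.approx(10.0, rel=1e-12)
        assert q.A2 == pytest.approx(1.0, rel=1e-12)
        assert q.A3 == pytest.approx(0.01, rel=1e-12)
        assert q.F2 == pytest.approx(10.0, rel=1e-12)
        # the loss rates are 0.99 exactly; the published table rounds to 1
        for c in (q.C1, q.C2, q.C3):
            assert c == pytest.approx(0.99, rel=1e-12)
        assert (sc.epsilon, sc.lam, sc.sigma, sc.delta) == (
            table1.IC_E, table1.IC_B, table1.IC_S, table1.IC_D,
        )
        assert sc.T == pytest.approx(33.0, rel=1e-12)

    def test_zero_k1_rejected(self, table1):
        from dataclasses import replace

        with pytest.raises(ParameterError):
            w.nondimensionalize(replace(table1, k1=0.0))

    def test_state_scaling_examples(self, table1):
        _, sc = w.nondimensionalize(table1)
        e = w.to_nondim_state(w.CellState(0.33, 0, 0, "dimensional"), sc).ecad
        assert e == pytest.approx(10.0, rel=1e-12)
        S = w.to_dim_state(w.CellState(0, 0, 6.5), sc).slug
        assert S == pytest.approx(21.45, rel=1e-12)

    @given(
        e=st.floats(0, 100), b=st.floats(0, 10), s=st.floats(0, 50),
    )
    @settings(deadline=None, max_examples=50)
    def test_scaling_round_trip(self, e, b, s):
        sc = w.ScalingConstants(0.033, 0.33, 3.3, 0.67, 33.0)
        state = w.CellState(e, b, s, "dimensional")
        back = w.to_dim_state(w.to_nondim_state(state, sc), sc)
        assert back.as_array() == pytest.approx(state.as_array(), rel=1e-14)

    def test_frame_mismatch_rejected(self, table1):
        _, sc = w.nondimensionalize(table1)
        with pytest.raises(FrameError):
            w.to_nondim_state(w.CellState(1, 1, 1), sc)


class TestJacobian:
    def test_structure_at_origin(self, table2):
        # n >= 2 kills every off-diagonal slope at the origin
        J = w.jacobian(w.CellState(0, 0, 0), table2, w.DvlInput(0.0))
        off = J - np.diag(np.diag(J))
        assert np.all(off == 0)
        assert np.diag(J) == pytest.approx([-table2.C1, -table2.C2, -table2.C3])

    def test_matches_finite_differences(self, table2):
        rng = np.random.default_rng(7)
        for _ in range(20):
            y = rng.uniform(0.05, 8.0, 3)
            J = w.jacobian(w.CellState(*y), table2, w.DvlInput(1.5))
            Jfd = np.empty((3, 3))
            h = 1e-6
            for j in range(3):
                dy = np.zeros(3)
                dy[j] = h
                Jfd[:, j] = (
                    _rhs_nondim(y + dy, table2, 1.5)
                    - _rhs_nondim(y - dy, table2, 1.5)
                ) / (2 * h)
            assert J == pytest.approx(Jfd, rel=1e-6, abs=1e-8)

    def test_feedback_loop_sign_product_positive(self, table2):
        # (s -| e) * (e -| b) * (b -> s) > 0: the bistability prerequisite
        rng = np.random.default_rng(11)
        for _ in range(50):
            y = rng.uniform(0.01, 10.0, 3)
            J = w.jacobian(w.CellState(*y), table2, w.DvlInput(0.0))
            assert J[0, 2] < 0 and J[1, 0] < 0 and J[2, 1] > 0
            assert J[0, 2] * J[1, 0] * J[2, 1] > 0

    def test_negative_state_rejected(self, table2):
        with pytest.raises(ValueError):
            w.jacobian(w.CellState(1.0, -0.1, 1.0), table2, w.DvlInput(0.0))


class TestFrameEquivalence:
    def test_dimensional_and_nondimensional_trajectories_agree(
        self, table1, table2_exact
    ):
        """Simulating table1 at D = delta*d and rescaling states and time
        reproduces the nondimensional trajectory at d (exact C = 0.99)."""
        q, sc = w.nondimensionalize(table1)
        d = 2.0
        tau_end = 40.0
        proto_nd = w.SignalProtocol.constant(d)
        traj_nd = w.simulate(
            table2_exact, proto_nd, w.CellState(10, 0, 0), tau_end
        )
        proto_dim = w.SignalProtocol.constant(d * sc.delta)
        traj_dim = w.simulate(
            table1,
            proto_dim,
            w.CellState(10 * sc.epsilon, 0, 0, "dimensional"),
            tau_end * sc.T,
            frame="dimensional",
        )
        scaled = traj_dim.states / np.array([sc.epsilon, sc.lam, sc.sigma])
        assert np.allclose(scaled, traj_nd.states, rtol=1e-6, atol=1e-8)
        assert np.allclose(traj_dim.t / sc.T, traj_nd.t)
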