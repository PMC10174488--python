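"""Deterministic three-state engine: updates, eigensystem, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cytocycle.state_network import (
    DeathRates,
    PopulationState,
    TransitionParams,
    doubling_time,
    growth_eigensystem,
    simulate,
    step,
    update_matrix,
)

U87_TABLE = TransitionParams(0.05, 0.11, 0.14)


def matrix_oracle(params, death, x, steps):
    """Independent update-matrix construction for cross-checking."""
    m1, m2, m3 = params.m1, params.m2, params.m3
    p1, p2, p3 = death.phi1, death.phi2, death.phi3
    A = np.array(
        [
            [1 - m1 - p1, 0, 2 * m3],
            [m1, 1 - m2 - p2, 0],
            [0, m2, 1 - m3 - p3],
        ]
    )
    return np.linalg.matrix_power(A, steps) @ x


class TestStep:
    def test_zero_rates_freeze_population(self):
        out = step(PopulationState(10, 5, 5), TransitionParams(0, 0, 0))
        assert (out.x1, out.x2, out.x3, out.t) == (10, 5, 5, 1)

    def test_division_edge_doubles_transitioning_cells(self):
        out = step(PopulationState(0, 0, 8), TransitionParams(0, 0, 1))
        assert (out.x1, out.x2, out.x3) == (16, 0, 0)

    def test_matches_matrix_oracle_and_preserves_stationary_proportions(self):
        x = np.array([60.2, 23.5, 16.3])
        out = step(PopulationState(*x), U87_TABLE)
        expected = matrix_oracle(U87_TABLE, DeathRates(), x, 1)
        np.testing.assert_allclose(out.as_array(), expected, rtol=1e-14)
        # near-stationary input: one step changes proportions only slightly
        assert np.abs(out.proportions - x / x.sum()).max() < 5e-3

    def test_rejects_rate_plus_death_above_one(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            step(PopulationState(1, 1, 1), TransitionParams(0.9, 0, 0), DeathRates(phi1=0.2))

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            PopulationState(-1, 0, 0)


class TestSimulate:
    def test_72h_total_matches_doubling_time_closed_form(self, u87_base):
        traj = simulate(u87_base, x0=100 * np.array([0.602, 0.235, 0.163]), horizon=72)
        expected = 100 * math.exp(72 * math.log(2) / 31.13)
        assert traj.totals[-1] == pytest.approx(expected, rel=1e-3)
        assert traj.totals[-1] == pytest.approx(497, abs=1.0)

    def test_zero_params_constant_trajectory(self):
        traj = simulate(TransitionParams(0, 0, 0), x0=(3, 2, 1), horizon=10)
        assert np.all(traj.counts == traj.counts[0])

    def test_matches_matrix_power_oracle(self):
        x0 = np.array([7.0, 11.0, 13.0])
        death = DeathRates(0.01, 0.02, 0.0)
        traj = simulate(U87_TABLE, death, x0, horizon=72)
        expected = matrix_oracle(U87_TABLE, death, x0, 72)
        np.testing.assert_allclose(traj.counts[-1], expected, rtol=1e-12)

    @given(c=st.floats(0.01, 1000.0))
    def test_linear_in_seeding_number(self, c):
        x0 = np.array([5.0, 3.0, 2.0])
        base = simulate(U87_TABLE, x0=x0, horizon=24).counts[-1]
        scaled = simulate(U87_TABLE, x0=c * x0, horizon=24).counts[-1]
        np.testing.assert_allclose(scaled, c * base, rtol=1e-12)

    def test_total_conserved_without_division_edge_or_death(self):
        traj = simulate(TransitionParams(0.3, 0.2, 0.0), x0=(10, 5, 5), horizon=50)
        np.testing.assert_allclose(traj.totals, 20.0, rtol=1e-12)

    def test_monotone_growth_without_death(self):
        traj = simulate(U87_TABLE, x0=(10, 5, 5), horizon=50)
        assert np.all(np.diff(traj.totals) >= -1e-12)

    def test_trajectory_frame_schema(self):
        frame = simulate(U87_TABLE, x0=(60, 24, 16), horizon=5).to_frame()
        assert list(frame.columns) == [
            "time_h", "x_g0g1", "x_lateg1s", "x_g2m", "total",
            "p_g0g1", "p_lateg1s", "p_g2m",
        ]
        assert len(frame) == 6
        np.testing.assert_allclose(
            frame[["p_g0g1", "p_lateg1s", "p_g2m"]].sum(axis=1), 1.0
        )

    def test_rejects_non_integer_horizon(self):
        with pytest.raises(ValueError):
            simulate(U87_TABLE, x0=(1, 1, 1), horizon=1.5)


class TestEigensystem:
    def test_u87_stationary_proportions_match_reported_ratios(self):
        _, vec = growth_eigensystem(U87_TABLE)
        np.testing.assert_allclose(vec, [0.60, 0.24, 0.16], atol=0.02)

    def test_symmetric_cycle_growth_factor(self):
        lam, vec = growth_eigensystem(TransitionParams(1, 1, 1))
        assert lam == pytest.approx(2 ** (1 / 3), rel=1e-12)
        np.testing.assert_allclose(vec.sum(), 1.0)

    def test_long_simulation_converges_to_eigenvector(self, u87_base):
        lam, vec = growth_eigensystem(u87_base)
        traj = simulate(u87_base, x0=(100, 0, 0), horizon=400)
        np.testing.assert_allclose(traj.proportions[-1], vec, atol=1e-8)
        # growth factor over the last step
        assert traj.totals[-1] / traj.totals[-2] == pytest.approx(lam, rel=1e-8)

    def test_broken_cycle_reports_non_growing_population(self):
        lam, _ = growth_eigensystem(TransitionParams(0.3, 0.0, 0.2))
        assert lam <= 1.0 + 1e-12
        assert doubling_time(lam) == math.inf


class TestDoublingTime:
    @pytest.mark.parametrize(
        "lam, expected",
        [(2.0, 1.0), (2 ** (1 / 31.13), 31.13)],
    )
    def test_inverse_identities(self, lam, expected):
        assert doubling_time(lam) == pytest.approx(expected, rel=1e-12)

    def test_u251_fitted_params_reproduce_reported_doubling_time(self, u251_calib):
        lam, _ = growth_eigensystem(u251_calib.params)
        assert doubling_time(lam) == pytest.approx(24.93, rel=1e-3)
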