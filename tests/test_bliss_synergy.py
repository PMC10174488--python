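"""Robust excess-over-Bliss: 4PL smoothing, Bliss null, EOB summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cytocycle.bliss_synergy import (
    bliss_independence,
    eob_from_grid,
    eob_surface,
    fit_4pl,
    fitted_surface,
    four_pl,
    inhibition_from_counts,
)
from cytocycle.combination_prediction import DoseGrid

DOSES = np.array([0.0, 1.22, 4.88, 19.53, 78.13, 312.5, 1250.0, 5000.0]) / 1000.0


class TestInhibition:
    def test_definition(self):
        grid = DoseGrid("A", "B", [0, 1], [0, 1], [[1.0, 0.25], [1.2, 0.5]])
        np.testing.assert_allclose(
            inhibition_from_counts(grid), [[0.0, 0.75], [-0.2, 0.5]], atol=1e-15
        )


class TestBlissIndependence:
    @pytest.mark.parametrize(
        "ya, yb, expected", [(0.5, 0.5, 0.75), (0.0, 0.3, 0.3), (1.0, 0.3, 1.0)]
    )
    def test_formula(self, ya, yb, expected):
        assert bliss_independence(ya, yb) == pytest.approx(expected)

    @given(ya=st.floats(0, 1), yb=st.floats(0, 1))
    def test_stays_in_unit_interval_and_symmetric(self, ya, yb):
        v = bliss_independence(ya, yb)
        assert -1e-12 <= v <= 1 + 1e-12
        assert v == pytest.approx(bliss_independence(yb, ya))
        assert v >= max(ya, yb) - 1e-12


class TestFit4PL:
    def test_exact_recovery_from_4pl_curve(self):
        truth = dict(e_min=0.05, e_max=0.8, ec50=0.03, hill_n=1.7)
        y = four_pl(DOSES, **truth)
        fit = fit_4pl(DOSES, y, seed=1)
        assert fit.sse < 1e-12
        assert fit.e_min == pytest.approx(truth["e_min"], abs=1e-4)
        assert fit.e_max == pytest.approx(truth["e_max"], rel=1e-3)
        assert fit.ec50 == pytest.approx(truth["ec50"], rel=1e-3)
        assert fit.hill_n == pytest.approx(truth["hill_n"], rel=1e-3)
        assert fit(0.0) == fit.e_min

    def test_constant_series_flat_and_flagged(self):
        fit = fit_4pl(DOSES, np.full(8, 0.21), seed=1)
        assert fit.degenerate
        np.testing.assert_allclose(fit.fitted, 0.21)
        np.testing.assert_allclose(fit(123.0), 0.21)

    def test_multistart_no_worse_than_single_start(self):
        rng = np.random.default_rng(3)
        y = four_pl(DOSES, 0.0, 0.6, 0.02, 0.9) + rng.normal(0, 0.05, 8)
        multi = fit_4pl(DOSES, y, seed=2, n_starts=10)
        for k in range(5):
            single = fit_4pl(DOSES, y, seed=100 + k, n_starts=1)
            assert multi.sse <= single.sse + 1e-10


class TestFittedSurface:
    def test_separable_bliss_surface_reproduced(self):
        ya = four_pl(DOSES, 0.0, 0.7, 0.05, 1.2)
        yb = four_pl(DOSES, 0.0, 0.5, 0.02, 0.8)
        truth = bliss_independence(ya[:, None], yb[None, :])
        surface, row_fits, col_fits = fitted_surface(truth, DOSES, DOSES, seed=4)
        assert np.abs(surface - truth).max() < 0.02
        assert len(row_fits) == len(col_fits) == 8

    def test_symmetric_matrix_gives_symmetric_surface(self):
        ya = four_pl(DOSES, 0.0, 0.6, 0.04, 1.0)
        sym = np.minimum(ya[:, None] + ya[None, :], 0.95)
        surface, _, _ = fitted_surface(sym, DOSES, DOSES, seed=5)
        np.testing.assert_allclose(surface, surface.T, atol=1e-6)

    def test_cell_value_is_mean_of_row_and_column_fits(self):
        rng = np.random.default_rng(6)
        matrix = np.clip(
            bliss_independence(
                four_pl(DOSES, 0, 0.6, 0.05, 1.0)[:, None],
                four_pl(DOSES, 0, 0.4, 0.02, 1.5)[None, :],
            )
            + rng.normal(0, 0.02, (8, 8)),
            -0.4,
            0.99,
        )
        surface, row_fits, col_fits = fitted_surface(matrix, DOSES, DOSES, seed=7)
        i, j = 3, 5
        manual = 0.5 * (row_fits[i].fitted[j] + col_fits[j].fitted[i])
        assert surface[i, j] == pytest.approx(manual, rel=1e-12)


class TestEOB:
    def test_bliss_consistent_surface_has_near_zero_mean(self):
        ya = four_pl(DOSES, 0.0, 0.7, 0.05, 1.2)
        yb = four_pl(DOSES, 0.0, 0.5, 0.02, 0.8)
        truth = bliss_independence(ya[:, None], yb[None, :])
        surface, rf, cf = fitted_surface(truth, DOSES, DOSES, seed=8)
        result = eob_surface(surface, DOSES, DOSES, row_fits=rf, col_fits=cf)
        assert abs(result.mean_eob) < 0.01

    def test_uniform_excess_recovered_exactly(self):
        ya = four_pl(DOSES, 0.0, 0.7, 0.05, 1.2)
        yb = four_pl(DOSES, 0.0, 0.5, 0.02, 0.8)
        shifted = bliss_independence(ya[:, None], yb[None, :]) + 0.1
        result = eob_surface(shifted, DOSES, DOSES, y_a=ya, y_b=yb)
        assert result.mean_eob == pytest.approx(0.10, abs=1e-12)

    def test_zero_dose_cells_near_zero_by_construction(self):
        ya = four_pl(DOSES, 0.0, 0.6, 0.03, 1.0)
        yb = four_pl(DOSES, 0.0, 0.4, 0.01, 1.3)
        surface = bliss_independence(ya[:, None], yb[None, :]) * 1.05
        result = eob_surface(surface, DOSES, DOSES)
        # first row/column read off the surface itself, so their EOB is 0
        np.testing.assert_allclose(result.eob[0, :], 0.0, atol=1e-12)
        np.testing.assert_allclose(result.eob[:, 0], 0.0, atol=1e-12)

    def test_antisymmetric_for_equal_magnitude_synergy_and_antagonism(self):
        ya = four_pl(DOSES, 0.0, 0.6, 0.05, 1.1)
        yb = four_pl(DOSES, 0.0, 0.5, 0.02, 0.9)
        bliss = bliss_independence(ya[:, None], yb[None, :])
        up = eob_surface(bliss + 0.05, DOSES, DOSES, y_a=ya, y_b=yb)
        down = eob_surface(bliss - 0.05, DOSES, DOSES, y_a=ya, y_b=yb)
        assert up.mean_eob == pytest.approx(-down.mean_eob, rel=1e-12)

    def test_pipeline_on_model_grids_is_deterministic_and_antagonistic(self, u87_model):
        from cytocycle.combination_prediction import predict_grid
        from cytocycle.datasets import combination_doses_uM

        grid = predict_grid(
            u87_model, "Abemaciclib", "PD0325901",
            combination_doses_uM("Abemaciclib"), combination_doses_uM("PD0325901"),
        )
        a = eob_from_grid(grid, seed=9)
        b = eob_from_grid(grid, seed=9)
        assert a.mean_eob == b.mean_eob  # bit-for-bit determinism
        assert a.mean_eob < 0  # sequential cell-cycle blockade: mild antagonism
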