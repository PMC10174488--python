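"""Dose-response fitting, likelihood bookkeeping and AIC comparison."""

import math

import numpy as np
import pytest

from cytocycle.datasets import drug_params, single_drug_doses_uM
from cytocycle.pharmacodynamics import relative_cell_counts
from cytocycle.single_drug_fit import (
    DoseResponseData,
    compare_aic,
    fit_drug_params,
    goodness_of_fit,
    log_likelihood_normalized,
)


def noise_free_data(model, drug_name, doses=None, sd=0.05):
    doses = single_drug_doses_uM() if doses is None else np.asarray(doses)
    truth = model.drug(drug_name)
    curve = relative_cell_counts(
        model.with_drugs([truth]), [{drug_name: d} for d in doses]
    )
    return DoseResponseData(
        drug_name, model.name, doses, curve, sd=np.full(doses.size, sd)
    )


class TestLogLikelihood:
    def test_zero_residuals_analytic(self):
        ll = log_likelihood_normalized(np.zeros(7), np.full(7, 0.3))
        assert ll == pytest.approx(7 * math.log(1 / math.sqrt(2 * math.pi)))

    def test_one_sigma_residual_contribution(self):
        base = log_likelihood_normalized([0.0], [0.2])
        one_sigma = log_likelihood_normalized([0.2], [0.2])
        assert one_sigma - base == pytest.approx(-0.5)

    def test_matches_density_product_oracle(self):
        rng = np.random.default_rng(42)
        res = rng.normal(size=5)
        sds = rng.uniform(0.1, 1.0, size=5)
        brute = math.log(
            np.prod(
                [
                    math.exp(-0.5 * (r / s) ** 2) / math.sqrt(2 * math.pi)
                    for r, s in zip(res, sds)
                ]
            )
        )
        assert log_likelihood_normalized(res, sds) == pytest.approx(brute, rel=1e-12)

    def test_zero_sd_rejected_without_floor(self):
        with pytest.raises(ValueError):
            log_likelihood_normalized([0.1], [0.0])
        assert np.isfinite(log_likelihood_normalized([0.1], [0.0], sd_floor=0.01))


class TestFitDrugParams:
    def test_noise_free_recovery_u87_pd(self, u87_model):
        data = noise_free_data(u87_model, "PD0325901")
        fit = fit_drug_params(data, u87_model.base, include_death=True, seed=3)
        truth = drug_params("U87", "PD0325901")
        assert fit.sse < 1e-10
        assert fit.params.ec50 == pytest.approx(truth.ec50, rel=0.01)
        assert fit.params.hill_n == pytest.approx(truth.hill_n, rel=0.01)
        assert fit.params.emax_phi == pytest.approx(truth.emax_phi, rel=0.01)
        assert fit.params.ec50_phi == pytest.approx(truth.ec50_phi, rel=0.01)
        assert round(fit.params.ec50, 2) == 0.10

    def test_noise_free_recovery_arbitrary_params(self, u87_model):
        from cytocycle.pharmacodynamics import DrugParams

        truth = DrugParams("custom", 2, ec50=0.05, hill_n=1.4, emax_phi=0.008, ec50_phi=0.6)
        doses = single_drug_doses_uM()
        curve = relative_cell_counts(
            u87_model.with_drugs([truth]), [{"custom": d} for d in doses]
        )
        data = DoseResponseData("custom", "U87", doses, curve)
        fit = fit_drug_params(
            data, u87_model.base, include_death=True, seed=5, target_state=2
        )
        for attr in ("ec50", "hill_n", "emax_phi", "ec50_phi"):
            assert getattr(fit.params, attr) == pytest.approx(
                getattr(truth, attr), rel=0.01
            ), attr

    def test_flat_data_fits_flat_curve(self, u87_base):
        doses = single_drug_doses_uM()
        data = DoseResponseData("PD0325901", "U87", doses, np.ones(doses.size))
        fit = fit_drug_params(data, u87_base, include_death=False, seed=1, n_starts=10)
        assert fit.sse < 1e-6
        np.testing.assert_allclose(fit.predicted, 1.0, atol=1e-3)

    def test_reproducible_given_seed(self, u87_model):
        data = noise_free_data(u87_model, "Abemaciclib")
        a = fit_drug_params(data, u87_model.base, seed=11, n_starts=5)
        b = fit_drug_params(data, u87_model.base, seed=11, n_starts=5)
        assert a.params == b.params
        assert a.sse == b.sse

    def test_death_model_never_fits_worse_than_nested_no_death(self, u87_model):
        rng = np.random.default_rng(0)
        doses = single_drug_doses_uM()
        truth = u87_model.drug("TAK-960")
        curve = relative_cell_counts(
            u87_model.with_drugs([truth]), [{"TAK-960": d} for d in doses]
        )
        noisy = curve * rng.lognormal(0, 0.05, size=curve.size)
        data = DoseResponseData("TAK-960", "U87", doses, noisy, sd=np.full(10, 0.05))
        with_death = fit_drug_params(data, u87_model.base, include_death=True, seed=2)
        without = fit_drug_params(data, u87_model.base, include_death=False, seed=2)
        assert with_death.sse <= without.sse + 1e-12
        assert with_death.log_likelihood >= without.log_likelihood - 1e-9

    def test_data_validation(self):
        with pytest.raises(ValueError, match="4 distinct"):
            DoseResponseData("d", "c", [0, 1, 2], [1, 0.9, 0.8])
        with pytest.raises(ValueError, match="control"):
            DoseResponseData("d", "c", [1, 2, 3, 4], [1, 0.9, 0.8, 0.7])


class TestCompareAIC:
    def test_penalty_only_case_is_plus_24(self, u87_model):
        # six fits with identical likelihoods: ΔAIC = 2*(24-12) = +24
        fits = []
        for cell in ("U87", "U87"):
            for drug in ("PD0325901", "Abemaciclib", "TAK-960"):
                data = noise_free_data(u87_model, drug)
                fits.append(data)
        import dataclasses

        from cytocycle.single_drug_fit import DrugFitResult

        def fake(data, k, ll):
            return DrugFitResult(
                params=drug_params("U87", data.drug), sse=0.0, log_likelihood=ll,
                aic=2 * k - 2 * ll, n_free_params=k, residuals=np.zeros(10),
                predicted=data.mean_counts, include_death=(k == 4), data=data,
                n_starts=1, all_sse=(0.0,),
            )

        death = [fake(d, 4, -3.0) for d in fits]
        nodeath = [fake(d, 2, -3.0) for d in fits]
        assert compare_aic(death, nodeath) == pytest.approx(24.0)
        # likelihood improvement of exactly 12 log-units cancels the penalty
        death_improved = [fake(d, 4, -3.0 + 2.0) for d in fits]
        assert compare_aic(death_improved, nodeath) == pytest.approx(0.0)

    def test_mismatched_data_rejected(self, u87_model):
        a = noise_free_data(u87_model, "PD0325901")
        b = noise_free_data(u87_model, "Abemaciclib")
        fit_a = fit_drug_params(a, u87_model.base, include_death=True, seed=1, n_starts=3)
        fit_b = fit_drug_params(b, u87_model.base, include_death=False, seed=1, n_starts=3)
        with pytest.raises(ValueError, match="different data"):
            compare_aic([fit_a], [fit_b])


class TestGoodnessOfFit:
    def test_perfect_and_inverted_correlation(self):
        x = np.array([0.1, 0.4, 0.6, 0.9])
        assert goodness_of_fit(x, x) == pytest.approx(1.0)
        assert goodness_of_fit(x, -x + 1.0) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 3.0, 3.5, 6.0, 7.5])
        r_manual = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert goodness_of_fit(x, y) == pytest.approx(r_manual, rel=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero-variance"):
            goodness_of_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
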