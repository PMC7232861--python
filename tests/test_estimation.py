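"""Laplace likelihood, population fit, empirical Bayes, SIR and VPC.

Problem sizes here are kept small (tens of subjects) so the whole suite runs
quickly; the full 136-child recovery experiment lives in the acceptance
tests.
"""

import numpy as np
import pandas as pd
import pytest

from smcpk.estimation import (
    _as_works,
    empirical_bayes,
    fit_population,
    laplace_nll,
    sir_uncertainty,
    vpc,
)
from smcpk.io import SubjectData
from smcpk.params import Subject, VariabilityParameters
from smcpk.pk import build_regimen, individual_parameters, predict_profile
from smcpk.popsim import apply_etas
from smcpk.synthdata import CohortDesign, generate_pk_cohort


def _rich_subject(pop, etas, sigma, seed, n_times=16) -> SubjectData:
    """One densely sampled subject with known etas and log-scale noise."""
    rng = np.random.Generator(np.random.PCG64(seed))
    subject = Subject("rich", 30.0, 10.0)
    doses = build_regimen(subject.age_months)
    times = np.linspace(1.0, 600.0, n_times)
    ind = apply_etas(individual_parameters(pop, subject), etas)
    aq, deaq = predict_profile(ind, doses, times)
    obs_times = np.concatenate([times, times])
    analytes = np.array(["AQ"] * n_times + ["DEAQ"] * n_times)
    true = np.concatenate([aq, deaq])
    dv = true * np.exp(rng.normal(0.0, sigma, size=true.size))
    return SubjectData(
        subject=subject,
        dose_times=np.array([d.time for d in doses]),
        dose_amounts=np.array([d.amount for d in doses]),
        obs_times=obs_times,
        analytes=analytes,
        dv=dv,
        blq=np.zeros(true.size, dtype=bool),
    )


class TestLaplaceNll:
    def test_zero_omega_reduces_to_exact_residual_likelihood(self, pop):
        var = VariabilityParameters(
            omega={}, sigma_aq=0.5, sigma_deaq=0.3, lloq_aq=1.0, lloq_deaq=1.0
        )
        sd = _rich_subject(pop, {}, sigma=0.3, seed=1, n_times=5)
        ind = individual_parameters(pop, sd.subject)
        aq, deaq = predict_profile(ind, sd.doses, sd.obs_times)
        pred = np.where(sd.analytes == "AQ", aq, deaq)
        sigma = np.where(sd.analytes == "AQ", 0.5, 0.3)
        resid = (np.log(sd.dv) - np.log(pred)) / sigma
        expected = float(
            np.sum(resid**2)
            + 2 * np.sum(np.log(sigma))
            + len(pred) * np.log(2 * np.pi)
        )
        assert laplace_nll(pop, var, [sd]) == pytest.approx(expected, rel=1e-9)

    def test_additive_over_subjects(self, pop, var):
        ds, _ = generate_pk_cohort(CohortDesign(n_subjects=6), pop, var, seed=7)
        works = _as_works(ds)
        total = laplace_nll(pop, var, works)
        parts = sum(laplace_nll(pop, var, [w]) for w in works)
        assert total == pytest.approx(parts, rel=1e-12)

    def test_generating_parameters_beat_perturbed(self, pop, var):
        ds, _ = generate_pk_cohort(CohortDesign(n_subjects=40), pop, var, seed=8)
        works = _as_works(ds)
        nll_truth = laplace_nll(pop, var, works)
        nll_perturbed = laplace_nll(
            pop.with_updates(cl_deaq=2 * pop.cl_deaq), var, works
        )
        assert nll_truth < nll_perturbed

    def test_matches_gauss_hermite_on_two_eta_model(self, pop):
        """Laplace vs adaptive 9-node Gauss-Hermite quadrature, within 2 units
        of -2 log-likelihood on a reduced (2-eta) model."""
        from numpy.polynomial.hermite import hermgauss

        omega = {"cl_aq": 0.25, "cl_deaq": 0.2}
        var = VariabilityParameters(
            omega=omega, sigma_aq=0.4, sigma_deaq=0.25,
            lloq_aq=1.0, lloq_deaq=1.0,
        )
        subjects = [
            _rich_subject(
                pop,
                {"cl_aq": 0.2 * ((-1) ** k), "cl_deaq": -0.1 * k},
                sigma=0.25, seed=20 + k, n_times=4,
            )
            for k in range(3)
        ]

        from scipy import optimize

        nodes, weights = hermgauss(9)
        om = np.array([omega["cl_aq"], omega["cl_deaq"]])
        total_gh = 0.0
        for sd in subjects:
            base = individual_parameters(pop, sd.subject)
            sigma = np.where(sd.analytes == "AQ", var.sigma_aq, var.sigma_deaq)

            def neg_log_g(eta):
                """-log of (conditional likelihood x eta prior density)."""
                ind = apply_etas(base, {"cl_aq": eta[0], "cl_deaq": eta[1]})
                aq, deaq = predict_profile(ind, sd.doses, sd.obs_times)
                pred = np.where(sd.analytes == "AQ", aq, deaq)
                r = (np.log(sd.dv) - np.log(np.maximum(pred, 1e-290))) / sigma
                return float(
                    0.5 * np.sum(r**2)
                    + np.sum(np.log(sigma * np.sqrt(2 * np.pi)))
                    + 0.5 * np.sum((eta / om) ** 2)
                    + np.sum(np.log(om * np.sqrt(2 * np.pi)))
                )

            # adaptive quadrature: centre at the mode, scale by the local
            # curvature (both found independently of the package internals)
            mode = optimize.minimize(
                neg_log_g, np.zeros(2), method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12},
            ).x
            h = 1e-4
            H = np.zeros((2, 2))
            for a in range(2):
                for b in range(2):
                    epp = mode.copy(); epp[[a, b]] += h
                    epm = mode.copy(); epm[a] += h; epm[b] -= h
                    emp = mode.copy(); emp[a] -= h; emp[b] += h
                    emm = mode.copy(); emm[[a, b]] -= h
                    H[a, b] = (
                        neg_log_g(epp) - neg_log_g(epm)
                        - neg_log_g(emp) + neg_log_g(emm)
                    ) / (4 * h * h)
            L = np.linalg.cholesky(np.linalg.inv(H))
            lik = 0.0
            for xi, wi in zip(nodes, weights):
                for xj, wj in zip(nodes, weights):
                    x = np.array([xi, xj])
                    eta = mode + np.sqrt(2) * L @ x
                    lik += (
                        wi * wj * np.exp(-neg_log_g(eta)) * np.exp(x @ x)
                    )
            lik *= 2.0 * np.linalg.det(L)
            total_gh += -2.0 * np.log(lik)

        assert laplace_nll(pop, var, subjects) == pytest.approx(total_gh, abs=2.0)


class TestEmpiricalBayes:
    def test_rich_low_noise_recovers_etas(self, pop, var):
        truth = {"f_aq": 0.1, "ka": -0.2, "cl_aq": 0.15, "vc_aq": -0.1,
                 "cl_deaq": 0.12, "vp1_deaq": 0.2}
        low_noise = VariabilityParameters(
            omega=dict(var.omega), sigma_aq=1e-4, sigma_deaq=1e-4,
            lloq_aq=0.0, lloq_deaq=0.0,
        )
        sd = _rich_subject(pop, truth, sigma=1e-4, seed=31, n_times=24)
        result = empirical_bayes(pop, low_noise, [sd])
        row = result["etas"].iloc[0]
        for name, value in truth.items():
            assert row[f"eta_{name}"] == pytest.approx(value, abs=0.01)

    def test_no_usable_records_gives_prior_mode(self, pop, var):
        sd = _rich_subject(pop, {}, sigma=0.2, seed=32, n_times=3)
        sd.blq[:] = True
        result = empirical_bayes(pop, var, [sd])
        row = result["etas"].iloc[0]
        assert row["no_data"]
        assert all(row[f"eta_{k}"] == 0.0 for k in result["eta_names"])

    def test_shrinkage_positive_and_grows_with_sparsity(self, pop, var):
        rich, _ = generate_pk_cohort(
            CohortDesign(n_subjects=40, windows_per_subject=3), pop, var, seed=33
        )
        sparse, _ = generate_pk_cohort(
            CohortDesign(n_subjects=40, windows_per_subject=1), pop, var, seed=33
        )
        sh_rich = empirical_bayes(pop, var, rich)["shrinkage"]["cl_deaq"]
        sh_sparse = empirical_bayes(pop, var, sparse)["shrinkage"]["cl_deaq"]
        assert 0 < sh_rich < sh_sparse < 1


@pytest.fixture(scope="module")
def small_cohort(pop, var):
    return generate_pk_cohort(CohortDesign(n_subjects=25), pop, var, seed=40)[0]


class TestFit:
    def test_recovery_and_multistart_stability(self, pop, var, small_cohort):
        free = ("cl_deaq", "vc_deaq")
        fits = [
            fit_population(
                small_cohort, pop.with_updates(cl_deaq=init), var,
                free=free, maxiter=30,
            )
            for init in (1.2, 3.5)  # about +/-50% around the truth
        ]
        for fit in fits:
            assert fit.estimate("cl_deaq") == pytest.approx(2.33, rel=0.2)
        assert fits[0].estimate("cl_deaq") == pytest.approx(
            fits[1].estimate("cl_deaq"), rel=0.02
        )

    def test_fit_reports_etas_and_shrinkage(self, pop, var, small_cohort):
        fit = fit_population(small_cohort, pop, var, free=("cl_deaq",), maxiter=5)
        assert isinstance(fit.etas, pd.DataFrame)
        assert len(fit.etas) == 25
        assert 0 <= fit.shrinkage["cl_deaq"] <= 1


class TestSir:
    def test_resample_count_validation(self, pop, var):
        ds, _ = generate_pk_cohort(CohortDesign(n_subjects=3), pop, var, seed=50)
        fit = fit_population(ds, pop, var, free=("cl_deaq",), maxiter=3)
        with pytest.raises(ValueError):
            sir_uncertainty(ds, fit, n_samples=10, n_resamples=20)

    def test_interval_brackets_estimate(self, pop, var):
        ds, _ = generate_pk_cohort(CohortDesign(n_subjects=12), pop, var, seed=51)
        fit = fit_population(ds, pop, var, free=("cl_deaq",), maxiter=20)
        table = sir_uncertainty(
            ds, fit, n_samples=150, n_resamples=60, seed=52, proposal_rse=0.1
        )
        row = table.set_index("parameter").loc["cl_deaq"]
        assert row["ci2.5"] < fit.estimate("cl_deaq") < row["ci97.5"]
        # the SIR median stays near the point estimate
        assert row["median"] == pytest.approx(fit.estimate("cl_deaq"), rel=0.1)


class TestVpc:
    def test_self_generated_data_is_covered(self, pop, var):
        ds, _ = generate_pk_cohort(CohortDesign(n_subjects=40), pop, var, seed=60)
        result = vpc(ds, pop, var, n_sim=150, seed=61)
        assert result.coverage() >= 0.85

    def test_inflated_noise_flags_misfit(self, pop, var):
        bad_var = VariabilityParameters(
            omega=dict(var.omega), sigma_aq=var.sigma_aq,
            sigma_deaq=3 * var.sigma_deaq, lloq_aq=var.lloq_aq,
            lloq_deaq=var.lloq_deaq,
        )
        ds, _ = generate_pk_cohort(CohortDesign(n_subjects=40), pop, bad_var,
                                   seed=62)
        result = vpc(ds, pop, var, n_sim=150, seed=63)
        deaq_extremes = result.table[
            (result.table.analyte == "DEAQ")
            & (result.table.percentile.isin([5.0, 95.0]))
        ].dropna(subset=["observed"])
        outside = (
            (deaq_extremes.observed < deaq_extremes.ci_lo)
            | (deaq_extremes.observed > deaq_extremes.ci_hi)
        )
        assert outside.any()

    def test_deaq_never_censored_at_default_lloq(self, pop, var):
        ds, _ = generate_pk_cohort(CohortDesign(n_subjects=40), pop, var, seed=64)
        result = vpc(ds, pop, var, n_sim=50, seed=65)
        deaq_blq = result.blq[result.blq.analyte == "DEAQ"]
        assert (deaq_blq["observed_blq"] == 0.0).all()
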