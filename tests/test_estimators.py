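"""Likelihoods, fitters and variance machinery for the two BCRW models."""

import math

import numpy as np
import pytest

from movebias.circular import log_vm_density, mean_direction, wrap_angle
from movebias.estimators import (
    BCRWParams,
    StepSeries,
    UnidentifiableError,
    delta_method_beta_se,
    fit_angular,
    fit_consensus,
    loglik_angular,
    loglik_consensus,
    sandwich_vcov,
)
from movebias.simulate import simulate_angular, simulate_consensus


def make_series(y, psi, animal=None):
    y = np.asarray(y, dtype=float)
    return StepSeries(
        animal=np.asarray(animal) if animal is not None else np.repeat("a", y.size),
        t=np.arange(y.size) if animal is None else np.concatenate(
            [np.arange(np.sum(np.asarray(animal) == lab)) for lab in dict.fromkeys(animal)]
        ),
        y=y,
        psi1=np.asarray(psi, dtype=float),
    )


class TestStepSeries:
    def test_previous_bearing_lags_within_animal(self, random_series):
        m = random_series.usable
        lab = random_series.animal
        for a in ("a", "b"):
            idx = np.flatnonzero(lab == a)
            assert np.allclose(random_series.y_prev[idx[1:]], random_series.y[idx[:-1]])
        assert random_series.n_usable == m.sum() == random_series.y.size - 2

    def test_two_animals_61_steps_give_120_usable(self, consensus_replicate):
        assert consensus_replicate.n_usable == 120

    def test_non_monotone_t_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            StepSeries(animal=["a", "a"], t=[1, 0], y=[0.0, 0.1], psi1=[0.0, 0.0])


class TestLoglikAngular:
    def test_single_aligned_record(self):
        # one usable record with y == y_prev and beta = 0: kappa*cos(0) - log(2 pi I0(kappa))
        data = make_series([0.4, 0.4], [1.0, 1.0])
        ll = loglik_angular(BCRWParams(kappa1=1.0, kappa2=0.0), data)
        from movebias.circular import log_bessel_i0

        assert ll == pytest.approx(1.0 - math.log(2 * math.pi) - log_bessel_i0(1.0))

    def test_matches_per_record_oracle(self, random_series):
        beta, kappa = 0.7, 2.3
        ll = loglik_angular(BCRWParams(kappa1=kappa, kappa2=kappa * beta), random_series)
        total = 0.0
        m = random_series.usable
        for y, yp, psi in zip(
            random_series.y[m], random_series.y_prev[m], random_series.psi1[m]
        ):
            mu = mean_direction(yp, psi, beta).direction
            total += log_vm_density(y, mu, kappa)
        assert ll == pytest.approx(total, abs=1e-10)

    def test_requires_positive_concentration(self, random_series):
        with pytest.raises(ValueError):
            loglik_angular(BCRWParams(kappa1=0.0, kappa2=0.0), random_series)


class TestLoglikConsensus:
    def test_reduces_to_crw_when_bias_zero(self, random_series):
        kappa = 1.7
        ll_c = loglik_consensus(BCRWParams(kappa1=kappa, kappa2=0.0), random_series)
        ll_a = loglik_angular(BCRWParams(kappa1=kappa, kappa2=0.0), random_series)
        assert ll_c == pytest.approx(ll_a, abs=1e-10)

    def test_two_parameterizations_agree(self, random_series):
        # exponential-family form vs vM(mu_t, kappa1 * l_t)
        k1, k2 = 1.4, 0.6
        ll = loglik_consensus(BCRWParams(kappa1=k1, kappa2=k2), random_series)
        m = random_series.usable
        total = 0.0
        for y, yp, psi in zip(
            random_series.y[m], random_series.y_prev[m], random_series.psi1[m]
        ):
            cv = mean_direction(yp, psi, k2 / k1)
            total += log_vm_density(y, cv.direction, k1 * cv.length)
        assert ll == pytest.approx(total, abs=1e-10)

    def test_uniform_when_all_concentrations_zero(self, random_series):
        ll = loglik_consensus(BCRWParams(kappa1=0.0, kappa2=0.0), random_series)
        assert ll == pytest.approx(random_series.n_usable * math.log(1 / (2 * math.pi)))

    def test_constant_agreement_links_the_two_models(self):
        # psi == y_prev makes l = 1 + beta constant, so the angular model at
        # kappa equals the consensus model at kappa1 = kappa / l
        rng = np.random.default_rng(5)
        y = rng.uniform(-math.pi, math.pi, 40)
        data = make_series(y, np.r_[y[0], y[:-1]])
        beta, kappa = 0.5, 2.0
        l = 1 + beta
        ll_ang = loglik_angular(BCRWParams(kappa1=kappa, kappa2=kappa * beta), data)
        k1 = kappa / l
        ll_con = loglik_consensus(BCRWParams(kappa1=k1, kappa2=k1 * beta), data)
        assert ll_ang == pytest.approx(ll_con, abs=1e-10)


class TestFitAngular:
    def test_large_sample_recovery(self):
        rng = np.random.default_rng(7)
        tr = simulate_angular(
            2001, beta=1.0, error_kappa=3.0, start=(0, 0), target=(50_000, 20_000), rng=rng
        )
        fit = fit_angular(tr.to_step_series())
        assert fit.converged and not fit.at_bound
        assert fit.beta["beta1"] == pytest.approx(1.0, rel=0.1)
        assert fit.estimates[-1] == pytest.approx(3.0, rel=0.1)

    def test_noise_free_data_hits_concentration_bound(self):
        rng = np.random.default_rng(3)
        y_prev = rng.uniform(-math.pi, math.pi, 80)
        psi = rng.uniform(-math.pi, math.pi, 80)
        beta = 0.8
        mu = np.array([mean_direction(a, b, beta).direction for a, b in zip(y_prev, psi)])
        # craft a series whose observed angles equal the model mean exactly
        data = StepSeries(
            animal=np.repeat("a", 81),
            t=np.arange(81),
            y=np.r_[y_prev[0], mu],
            psi1=np.r_[psi[0], psi],
        )
        data.y_prev[1:] = y_prev  # override the lag to the crafted anchors
        fit = fit_angular(data)
        assert fit.at_bound and fit.converged

    def test_null_bias_coverage(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            tr = simulate_consensus(
                121, kappa=2.0, beta=0.0, start=(0, 0), target=(1e9, 0), rng=rng
            )
            fit = fit_angular(tr.to_step_series())
            se = fit.beta_se["beta1"]
            if np.isfinite(se) and abs(fit.beta["beta1"]) < 3 * max(se, 1e-12):
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_collinear_targets_unidentifiable(self):
        y = np.linspace(-3, 3, 40)
        data = make_series(y, np.r_[y[0], y[:-1]])  # psi == y_prev everywhere
        with pytest.raises(UnidentifiableError):
            fit_angular(data)


class TestFitConsensus:
    def test_large_sample_recovery(self):
        rng = np.random.default_rng(13)
        tr = simulate_consensus(
            2001, kappa=2.0, beta=0.25, start=(0, 0), target=(50_000, 20_000), rng=rng
        )
        fit = fit_consensus(tr.to_step_series())
        assert fit.converged
        assert fit.params.kappa1 == pytest.approx(2.0, rel=0.1)
        assert fit.params.kappa2 == pytest.approx(0.5, rel=0.2)

    def test_optimum_dominates_truth(self):
        rng = np.random.default_rng(17)
        truth = BCRWParams(kappa1=2.0, kappa2=0.5)
        for _ in range(5):
            tr = simulate_consensus(
                121, kappa=2.0, beta=0.25, start=(0, 0), target=(3000, 1000), rng=rng
            )
            data = tr.to_step_series()
            fit = fit_consensus(data)
            assert fit.loglik >= loglik_consensus(truth, data) - 1e-8

    def test_null_bias_coverage(self):
        rng = np.random.default_rng(19)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            tr = simulate_consensus(
                121, kappa=2.0, beta=0.0, start=(0, 0), target=(1e9, 0), rng=rng
            )
            fit = fit_consensus(tr.to_step_series())
            if abs(fit.params.kappa2) < 3 * math.sqrt(fit.vcov_sandwich[1, 1]):
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_estimates_invariant_to_reference_rotation(self, consensus_replicate):
        base = fit_consensus(consensus_replicate)
        shift = 1.234
        rotated = StepSeries(
            animal=consensus_replicate.animal,
            t=consensus_replicate.t,
            y=wrap_angle(consensus_replicate.y + shift),
            psi1=wrap_angle(consensus_replicate.psi1 + shift),
        )
        fit = fit_consensus(rotated)
        assert np.allclose(fit.estimates, base.estimates, atol=1e-6)


class TestSandwich:
    def test_scalar_case_exact(self):
        g = np.array([0.5, -1.0, 0.25, 0.25])
        h = np.array([[-2.0]])
        expected = (g**2).sum() / 4.0
        assert sandwich_vcov(g, h)[0, 0] == pytest.approx(expected)

    def test_information_equality_when_correctly_specified(self):
        rng = np.random.default_rng(23)
        tr = simulate_consensus(
            5001, kappa=2.0, beta=0.25, start=(0, 0), target=(200_000, 50_000), rng=rng
        )
        fit = fit_consensus(tr.to_step_series(), cluster=False)
        se_model = np.sqrt(np.diag(fit.vcov_model))
        se_sand = np.sqrt(np.diag(fit.vcov_sandwich))
        assert np.all(np.abs(se_sand / se_model - 1) < 0.15)

    def test_positive_semidefinite_under_misspecification(self, consensus_replicate):
        # angular fit to data from a different generating process
        fit = fit_angular(consensus_replicate)
        eig = np.linalg.eigvalsh(fit.vcov_sandwich)
        assert np.all(eig > -1e-10)


class TestDeltaMethod:
    def test_diagonal_vcov_reduces_to_ratio(self):
        kappas = np.array([2.0, 0.0])
        vcov = np.diag([0.3, 0.09])
        se = delta_method_beta_se(kappas, vcov)
        assert se[0] == pytest.approx(0.3 / 2.0)

    def test_matches_monte_carlo_propagation(self, rng):
        kappas = np.array([2.0, 0.5])
        vcov = np.array([[0.04, 0.012], [0.012, 0.02]])
        draws = rng.multivariate_normal(kappas, vcov, size=1_000_000)
        mc_sd = np.std(draws[:, 1] / draws[:, 0], ddof=1)
        se = delta_method_beta_se(kappas, vcov)[0]
        assert se == pytest.approx(mc_sd, rel=0.02)

    def test_scale_free_in_kappa(self):
        kappas = np.array([1.5, 0.9])
        vcov = np.array([[0.05, 0.01], [0.01, 0.03]])
        se = delta_method_beta_se(kappas, vcov)
        c = 7.0
        se_scaled = delta_method_beta_se(c * kappas, c**2 * vcov)
        assert np.allclose(se, se_scaled)
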