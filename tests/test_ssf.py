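"""Case-control construction and conditional-logistic SSF fitting."""

import math

import numpy as np
import pytest

from movebias.circular import consensus_length, kuiper_test, log_bessel_i0, wrap_angle
from movebias.estimators import StepSeries, fit_consensus
from movebias.simulate import simulate_consensus, simulate_pixel_trail
from movebias.ssf import (
    CaseControlStratum,
    DesignMismatchError,
    build_design,
    fit_ssf,
    sample_controls,
    ssf_loglik,
    strata_to_frame,
    trail_ssf_design,
    _stack_design,
)


class TestSampleControls:
    def test_uniform_controls_pass_uniformity(self, rng):
        controls = sample_controls(np.zeros(1), 2_000, scheme="uniform", rng=rng)
        _, p = kuiper_test(controls[0])
        assert p > 0.01

    def test_degenerate_pool(self, rng):
        controls = sample_controls(np.array([0.42]), 5, scheme="empirical", rng=rng)
        assert np.all(controls == 0.42)

    def test_seed_reproducibility(self):
        pool = np.linspace(-3, 3, 50)
        a = sample_controls(pool, 7, rng=np.random.default_rng(9))
        b = sample_controls(pool, 7, rng=np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_empirical_draws_come_from_pool(self, rng):
        pool = np.array([0.1, -0.5, 2.0])
        controls = sample_controls(pool, 40, rng=rng)
        assert set(np.unique(controls)) <= set(pool)


class TestBuildDesign:
    def test_aligned_record_covariates(self):
        s = CaseControlStratum(0, y=0.5, controls=[1.0], y_prev=0.5, psi1=0.5)
        cov = s.covariates()
        assert cov[0] == pytest.approx([1.0, 1.0])

    def test_antipodal_control_covariate(self):
        s = CaseControlStratum(0, y=0.0, controls=[0.3 + math.pi], y_prev=0.3, psi1=0.0)
        assert s.covariates()[1, 0] == pytest.approx(-1.0)

    def test_stratum_count_matches_usable_records(self, consensus_replicate, rng):
        controls = sample_controls(
            consensus_replicate.y[consensus_replicate.usable], 10, rng=rng
        )
        strata = build_design(consensus_replicate, controls)
        assert len(strata) == 120

    def test_misaligned_controls_rejected(self, consensus_replicate, rng):
        with pytest.raises(DesignMismatchError):
            build_design(consensus_replicate, np.zeros((7, 3)))


class TestFitSSF:
    def test_uninformative_design_flagged(self):
        strata = [
            CaseControlStratum(i, y=0.2, controls=[0.2, 0.2], y_prev=0.1, psi1=0.4)
            for i in range(12)
        ]
        fit = fit_ssf(strata)
        assert not fit.converged
        assert "unidentifiable" in fit.message
        assert fit.loglik == pytest.approx(-12 * math.log(3))

    def test_matches_statsmodels_conditional_logit(self, rng):
        tr = simulate_consensus(151, kappa=2.0, beta=0.25, target=(5000, 2000), rng=rng)
        data = tr.to_step_series()
        controls = sample_controls(data.y[data.usable], 30, scheme="uniform", rng=rng)
        strata = build_design(data, controls)
        fit = fit_ssf(strata)
        sm = pytest.importorskip("statsmodels.discrete.conditional_models")
        df = strata_to_frame(strata)
        model = sm.ConditionalLogit(
            df["is_case"], df[["cos_turn", "cos_target1"]], groups=df["stratum_id"]
        )
        res = model.fit(disp=False)
        assert np.allclose(fit.estimates, res.params, rtol=1e-3)
        assert np.allclose(np.sqrt(np.diag(fit.vcov_model)), res.bse, rtol=1e-3)

    def test_rotation_invariance(self, rng):
        tr = simulate_consensus(101, kappa=2.0, beta=0.5, target=(4000, 0), rng=rng)
        data = tr.to_step_series()
        controls = sample_controls(data.y[data.usable], 20, rng=np.random.default_rng(3))
        base = fit_ssf(build_design(data, controls))
        shift = 0.77
        rotated = StepSeries(
            animal=data.animal, t=data.t, y=wrap_angle(data.y + shift),
            psi1=wrap_angle(data.psi1 + shift),
        )
        fit = fit_ssf(build_design(rotated, wrap_angle(controls + shift)))
        assert np.allclose(fit.estimates, base.estimates, atol=1e-8)

    def test_loglik_matches_direct_formula(self, rng):
        # hand-rolled per-stratum evaluation of the case/controls ratio
        strata = [
            CaseControlStratum(
                i,
                y=rng.uniform(-math.pi, math.pi),
                controls=rng.uniform(-math.pi, math.pi, 3),
                y_prev=rng.uniform(-math.pi, math.pi),
                psi1=rng.uniform(-math.pi, math.pi),
            )
            for i in range(11)
        ]
        k1, k2 = 1.2, 0.4
        total = 0.0
        for s in strata:
            etas = [
                k1 * math.cos(a - s.y_prev) + k2 * math.cos(a - s.psi1)
                for a in s.angles()
            ]
            total += etas[0] - math.log(sum(math.exp(e) for e in etas))
        assert ssf_loglik([k1, k2], _stack_design(strata)) == pytest.approx(total)


class TestLargeJEquivalence:
    def test_log_denominator_converges_to_bessel(self, rng):
        """LLN: mean over uniform controls of exp(eta) approaches I0(kappa1 * l_t)."""
        k1, k2 = 2.0, 0.5
        gaps = []
        for _ in range(100):
            y_prev = rng.uniform(-math.pi, math.pi)
            psi = rng.uniform(-math.pi, math.pi)
            delta = rng.uniform(-math.pi, math.pi, 10_000)
            terms = np.exp(k1 * np.cos(delta - y_prev) + k2 * np.cos(delta - psi))
            log_mean = math.log(terms.mean())
            l = consensus_length(y_prev, psi, k2 / k1)
            gaps.append(abs(log_mean - log_bessel_i0(k1 * l)))
        assert np.mean(gaps) < 0.01


class TestTrailDesign:
    def straight_path(self, n=6):
        # east-going: constant row, increasing col
        return np.column_stack([np.full(n, 5), np.arange(2, 2 + n)])

    def test_seven_alternatives_per_interior_position(self):
        path = self.straight_path()
        targets = {"psi1": np.zeros(path.shape[0])}
        strata = trail_ssf_design(path, targets, grid_shape=(20, 20))
        assert len(strata) == path.shape[0] - 2
        assert all(s.n_alternatives == 7 for s in strata)

    def test_straight_east_case_has_unit_persistence_covariate(self):
        path = self.straight_path()
        strata = trail_ssf_design(path, {"psi1": np.zeros(path.shape[0])})
        for s in strata:
            assert s.covariates()[0, 0] == pytest.approx(1.0)  # cos(turn) = 1
            assert s.y == pytest.approx(0.0)  # east in the angle convention

    def test_out_of_bounds_path_rejected(self):
        path = np.array([[0, 0], [0, 1], [1, 2]])
        with pytest.raises(ValueError, match="out of bounds|8-neighbors"):
            trail_ssf_design(path, {"psi1": np.zeros(3)}, grid_shape=(1, 2))

    def test_backtracking_rejected(self):
        path = np.array([[2, 2], [2, 3], [2, 2], [2, 3]])
        with pytest.raises(ValueError, match="backtrack"):
            trail_ssf_design(path, {"psi1": np.zeros(4)})

    def test_trail_fit_recovers_generating_concentrations(self):
        """Trails simulated by 7-neighbor discrete choice are refitted
        consistently by the conditional-logistic SSF."""
        rng = np.random.default_rng(101)
        truth = (3.0, 1.0, 0.4)
        strata = []
        for trail in range(60):
            start = (int(rng.integers(150, 250)), int(rng.integers(150, 250)))
            path, targets = simulate_pixel_trail(
                (400, 400), start, (200, 350),
                gap_pixels=rng.integers(100, 300, size=(15, 2)),
                n_steps=28, kappa1=truth[0], kappa2=truth[1], kappa3=truth[2], rng=rng,
            )
            strata.extend(trail_ssf_design(path, targets, grid_shape=(400, 400)))
        fit = fit_ssf(strata, n_biases=2)
        assert fit.converged
        assert np.allclose(fit.estimates, truth, rtol=0.2)


def test_strata_round_trip_long_format(rng):
    strata = [
        CaseControlStratum(
            i, y=rng.uniform(-3, 3), controls=rng.uniform(-3, 3, 4),
            y_prev=rng.uniform(-3, 3), psi1=rng.uniform(-3, 3), psi2=rng.uniform(-3, 3),
        )
        for i in range(5)
    ]
    df = strata_to_frame(strata)
    assert df.shape == (25, 5)
    assert df.groupby("stratum_id")["is_case"].sum().eq(1).all()
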