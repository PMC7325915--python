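"""Conditional-likelihood estimator: oracle equivalence, parameter
recovery, crude ORs, and the covariate screening/elimination procedure."""

import math

import numpy as np
import pytest
from scipy import optimize

from gxe.estimation import (
    DesignError,
    DesignMatrix,
    TwoByTwo,
    backward_eliminate,
    conditional_loglik,
    crude_or,
    fit_conditional_logistic,
    fit_logistic_fixed_strata,
    screen_covariates,
)
from gxe.interaction import JOINT_TERMS
from gxe.pipeline import build_design
from gxe.simulate import SimConfig, simulate_cohort


def brute_loglik(beta, X, y, stratum):
    """Independent oracle: direct summation of the conditional probability
    that the observed case is the case, per stratum, in plain Python."""
    beta = np.asarray(beta, float)
    total = 0.0
    for sid in sorted(set(stratum)):
        rows = [i for i, s in enumerate(stratum) if s == sid]
        case = [i for i in rows if y[i] == 1]
        assert len(case) == 1
        num = math.exp(float(X[case[0]] @ beta))
        den = sum(math.exp(float(X[i] @ beta)) for i in rows)
        total += math.log(num / den)
    return total


def _toy_design():
    # 3 strata of 1 case : 3 controls with two binary terms
    X = np.array(
        [[1, 0], [0, 0], [1, 1], [0, 0],
         [0, 0], [1, 0], [0, 1], [0, 0],
         [0, 1], [0, 0], [1, 0], [1, 1]], dtype=float)
    y = np.array([1, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0])
    stratum = np.repeat([0, 1, 2], 4)
    return DesignMatrix(X, y, stratum, ["expo", "carr"])


class TestConditionalLoglik:
    def test_uniform_at_beta_zero(self):
        d = _toy_design()
        one = DesignMatrix(d.X[:4], d.y[:4], d.stratum[:4], d.terms)
        value, _, _ = conditional_loglik(np.zeros(2), one)
        assert value == pytest.approx(math.log(1 / 4))

    def test_stratum_constant_covariate_absorbed(self):
        d = _toy_design()
        const = np.repeat([1.0, 5.0, -2.0], 4)[:, None]  # constant within stratum
        d2 = DesignMatrix(np.hstack([d.X, const]), d.y, d.stratum, d.terms + ["z"])
        for gamma in (-3.0, 0.0, 2.5):
            v1, _, _ = conditional_loglik(np.array([0.4, -0.2, 0.0]), d2)
            v2, _, _ = conditional_loglik(np.array([0.4, -0.2, gamma]), d2)
            assert v2 == pytest.approx(v1, abs=1e-12)

    @pytest.mark.parametrize("b0", [-1.0, 0.0, 0.7])
    @pytest.mark.parametrize("b1", [-0.5, 0.3, 1.2])
    def test_matches_brute_force_on_grid(self, b0, b1):
        d = _toy_design()
        beta = np.array([b0, b1])
        value, grad, hess = conditional_loglik(beta, d)
        assert value == pytest.approx(brute_loglik(beta, d.X, d.y, d.stratum), abs=1e-10)
        num_grad = optimize.approx_fprime(beta, lambda b: brute_loglik(b, d.X, d.y, d.stratum), 1e-6)
        assert np.allclose(grad, num_grad, atol=1e-4)
        num_hess = optimize.approx_fprime(
            beta, lambda b: conditional_loglik(b, d)[1], 1e-6
        )
        assert np.allclose(hess, num_hess, atol=1e-4)

    def test_multi_case_stratum_rejected(self):
        d = _toy_design()
        y = d.y.copy()
        y[1] = 1
        with pytest.raises(DesignError, match="stratum"):
            conditional_loglik(np.zeros(2), DesignMatrix(d.X, y, d.stratum, d.terms))


class TestFitConditionalLogistic:
    def test_mle_matches_derivative_free_optimizer(self):
        d = _toy_design()
        fit = fit_conditional_logistic(d)
        res = optimize.minimize(
            lambda b: -brute_loglik(b, d.X, d.y, d.stratum),
            np.zeros(2), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12},
        )
        assert np.allclose(fit.beta, res.x, atol=1e-4)

    def test_matches_statsmodels_conditional_logit(self, effect_cohort):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.conditional_models import ConditionalLogit

        cohort, _ = effect_cohort
        d = build_design(cohort, "rs0001")
        sub = d.subset_terms(list(JOINT_TERMS))
        fit = fit_conditional_logistic(sub)
        codes = {s: i for i, s in enumerate(np.unique(sub.stratum))}
        groups = np.array([codes[s] for s in sub.stratum])
        ref = ConditionalLogit(sub.y, sub.X, groups=groups).fit(disp=False)
        # statsmodels' default optimizer stops with |score| ~ 1e-3; our
        # Newton drives it below 1e-8, so compare at statsmodels' precision
        assert np.allclose(fit.beta, ref.params, atol=1e-4)
        assert np.allclose(fit.vcov, ref.cov_params(), atol=1e-4, rtol=1e-3)

    def test_null_recovery(self, null_cohort):
        cohort, _ = null_cohort
        d = build_design(cohort, "rs0001")
        fit = fit_conditional_logistic(d.subset_terms(list(JOINT_TERMS)))
        assert np.all(np.abs(fit.beta) < 3 * fit.se())

    def test_effect_recovery(self, effect_cohort):
        cohort, _ = effect_cohort
        d = build_design(cohort, "rs0001")
        fit = fit_conditional_logistic(d.subset_terms(list(JOINT_TERMS)))
        i = fit.terms.index("exp_only")
        assert abs(fit.beta[i] - math.log(2.0)) < 3 * fit.se()[i]

    def test_vcov_symmetric_psd(self, effect_cohort):
        cohort, _ = effect_cohort
        d = build_design(cohort, "rs0001")
        fit = fit_conditional_logistic(d.subset_terms(list(JOINT_TERMS)))
        assert np.allclose(fit.vcov, fit.vcov.T)
        assert np.all(np.linalg.eigvalsh(fit.vcov) > -1e-12)

    def test_permutation_invariance(self):
        d = _toy_design()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(d.y))
        d2 = DesignMatrix(d.X[perm], d.y[perm], d.stratum[perm], d.terms)
        f1, f2 = fit_conditional_logistic(d), fit_conditional_logistic(d2)
        assert np.allclose(f1.beta, f2.beta, atol=1e-9)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-10)

    def test_separation_reported(self):
        # the single term perfectly predicts the case in every stratum
        X = np.array([[1], [0], [0], [1], [0], [0]], dtype=float)
        y = np.array([1, 0, 0, 1, 0, 0])
        stratum = np.repeat([0, 1], 3)
        fit = fit_conditional_logistic(DesignMatrix(X, y, stratum, ["expo"]))
        assert fit.separation == ["expo"]

    def test_agrees_with_fixed_strata_logistic_direction(self, effect_cohort):
        """The unconditional fixed-strata cross-check recovers the same
        effect directions (it is biased away from the null, so only sign
        and ordering are compared)."""
        cohort, _ = effect_cohort
        d = build_design(cohort, "rs0001")
        sub = d.subset_terms(list(JOINT_TERMS))
        cond = fit_conditional_logistic(sub)
        fixed = fit_logistic_fixed_strata(sub)
        assert np.all(np.sign(fixed.beta) == np.sign(cond.beta))


class TestCrudeOr:
    def test_hand_arithmetic(self):
        out = crude_or(TwoByTwo(14, 5, 143, 358))
        assert out["or"] == pytest.approx(7.01, abs=0.005)
        assert not out["corrected"]

    def test_balanced_table_is_null(self):
        assert crude_or(TwoByTwo(10, 10, 10, 10))["or"] == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        out = crude_or(TwoByTwo(0, 5, 10, 20))
        assert out["corrected"]
        assert out["or"] == pytest.approx((0.5 * 20.5) / (5.5 * 10.5))

    def test_double_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            crude_or(TwoByTwo(0, 0, 10, 20))


@pytest.fixture(scope="module")
def confounded_design():
    cfg = SimConfig(
        n_strata=500, exposure_prev_controls=0.15,
        or10=3.0, or01=1.0, target_reri=0.0, seed=77,
        confounder_spec=[("arthrosis", 0.3, 2.5, 3.0), ("ppi", 0.2, 1.0, 1.0)],
    )
    cohort, _ = simulate_cohort(cfg)
    return build_design(cohort, "rs0001", covariates=["arthrosis", "ppi"])


class TestScreenCovariates:
    def test_true_confounder_retained_noise_depends_on_data(self, confounded_design):
        kept, log = screen_covariates(confounded_design, ["arthrosis", "ppi"])
        assert "arthrosis" in kept
        assert log == []

    def test_alpha_one_retains_everything(self, confounded_design):
        kept, _ = screen_covariates(confounded_design, ["arthrosis", "ppi"], alpha=1.0)
        assert kept == ["arthrosis", "ppi"]

    def test_noise_retained_at_alpha_rate(self):
        """A pure-noise covariate passes the P < 0.2 screen in ~20% of
        replicates."""
        rng = np.random.default_rng(12)
        n_strata, m = 150, 4
        stratum = np.repeat(np.arange(n_strata), m)
        y = np.tile([1, 0, 0, 0], n_strata)
        hits = 0
        reps = 400
        for _ in range(reps):
            X = rng.binomial(1, 0.3, size=(n_strata * m, 1)).astype(float)
            d = DesignMatrix(X, y, stratum, ["noise"])
            kept, _ = screen_covariates(d, ["noise"], alpha=0.2)
            hits += bool(kept)
        rate = hits / reps
        se = math.sqrt(0.2 * 0.8 / reps)
        assert abs(rate - 0.2) < 3.5 * se


class TestBackwardEliminate:
    def test_noise_dropped_confounder_kept(self, confounded_design):
        fit, log = backward_eliminate(
            confounded_design, list(JOINT_TERMS), ["arthrosis", "ppi"]
        )
        assert "arthrosis" in fit.terms  # dropping it shifts exposure betas
        assert "ppi" not in fit.terms  # pure noise improves BIC when dropped
        assert any(e["candidate"] == "ppi" and e["dropped"] for e in log)

    def test_cie_zero_blocks_any_shifting_drop(self, confounded_design):
        fit, _ = backward_eliminate(
            confounded_design, list(JOINT_TERMS), ["arthrosis", "ppi"], cie=0.0
        )
        assert set(fit.terms) >= {"arthrosis", "ppi"}

    def test_exposure_terms_never_dropped(self, confounded_design):
        fit, _ = backward_eliminate(
            confounded_design, list(JOINT_TERMS), ["arthrosis", "ppi"]
        )
        assert all(t in fit.terms for t in JOINT_TERMS)
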