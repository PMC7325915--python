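"""RERI, synergy index, stratum ORs, delta/bootstrap CIs, Knol tables."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gxe.estimation import FittedModel, fit_conditional_logistic
from gxe.interaction import (
    JOINT_TERMS,
    attributable_proportion,
    interaction_ci,
    joint_recode,
    knol_table,
    reri,
    stratum_ors,
    synergy_index,
)
from gxe.pipeline import build_design, cell_counts


def _model(b10, b01, b11, vcov=None):
    return FittedModel(
        terms=list(JOINT_TERMS),
        beta=np.log([b10, b01, b11]),
        vcov=np.zeros((3, 3)) if vcov is None else np.asarray(vcov),
        loglik=0.0, n_strata_used=10, converged=True, iterations=1,
    )


class TestJointRecode:
    @pytest.mark.parametrize(
        "exposed,carrier,expected",
        [(0, 0, "ref"), (1, 0, "exp-only"), (0, 1, "carrier-only"), (1, 1, "both")],
    )
    def test_mapping(self, exposed, carrier, expected):
        assert joint_recode(exposed, carrier) == expected

    def test_missing_input_rejected(self):
        with pytest.raises(ValueError):
            joint_recode(None, 1)


class TestReri:
    @pytest.mark.parametrize(
        "ors,expected",
        [
            ((8.22, 3.42, 0.85), 4.95),
            ((4.83, 3.26, 0.82), 1.75),
            ((1.0, 1.0, 1.0), 0.0),
            ((3.09, 5.86, 0.97), -2.74),
        ],
    )
    def test_worked_examples(self, ors, expected):
        assert round(reri(*ors), 2) == expected

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError):
            reri(2.0, -1.0, 1.0)

    @given(
        o10=st.floats(min_value=1.01, max_value=10),
        o01=st.floats(min_value=1.01, max_value=10),
    )
    def test_multiplicative_null_gives_positive_reri(self, o10, o01):
        """With both factors harmful, a multiplicative (no-interaction-on-
        OR-scale) joint effect still departs from additivity."""
        val = reri(o10 * o01, o10, o01)
        assert val == pytest.approx((o10 - 1) * (o01 - 1), rel=1e-9)
        assert val > 0


class TestSynergyIndex:
    @pytest.mark.parametrize(
        "ors,expected",
        [((8.22, 3.42, 0.85), 3.18), ((4.03, 5.02, 0.96), 0.76)],
    )
    def test_worked_examples(self, ors, expected):
        assert round(synergy_index(*ors), 2) == expected

    def test_zero_denominator_undefined(self):
        assert synergy_index(3.0, 1.5, 0.5) is None

    @given(
        o10=st.floats(min_value=0.2, max_value=8),
        o01=st.floats(min_value=0.2, max_value=8),
        o11=st.floats(min_value=0.2, max_value=20),
    )
    def test_sign_coherence_with_reri(self, o10, o01, o11):
        """When the single-factor excesses sum positive, RERI > 0 iff S > 1."""
        denom = (o10 - 1) + (o01 - 1)
        if denom <= 1e-9:
            return
        r, s = reri(o11, o10, o01), synergy_index(o11, o10, o01)
        assert (r > 0) == (s > 1) or abs(r) < 1e-12

    def test_ap_is_reri_over_or11(self):
        assert attributable_proportion(8.0, 2.0, 1.5) == pytest.approx(
            reri(8.0, 2.0, 1.5) / 8.0
        )


class TestStratumORs:
    def test_joint_model_ratio_identity(self):
        m = _model(b10=2.0, b01=2.0, b11=8.0)
        ors = stratum_ors(m, "snp", mode="joint-model")
        assert ors.rereferenced["exposure_within_carrier"][0] == pytest.approx(4.0)
        assert ors.rereferenced["carrier_within_exposed"][0] == pytest.approx(4.0)

    def test_null_model_all_unity(self):
        ors = stratum_ors(_model(1.0, 1.0, 1.0), "snp", mode="joint-model")
        assert all(v[0] == pytest.approx(1.0) for v in ors.ors.values())

    def test_missing_term_rejected(self):
        m = _model(1, 1, 1)
        m.terms = ["a", "b", "c"]
        with pytest.raises(ValueError, match="joint-category"):
            stratum_ors(m, "snp", mode="joint-model")

    def test_refit_agrees_with_joint_on_large_cohort(self, effect_cohort):
        """Without covariate-by-stratum interaction the stratified refit and
        the joint-model contrast estimate the same within-stratum OR."""
        cohort, _ = effect_cohort
        d = build_design(cohort, "rs0001")
        fit = fit_conditional_logistic(d.subset_terms(list(JOINT_TERMS)))
        joint = stratum_ors(fit, "rs0001", mode="joint-model")
        refit = stratum_ors(fit, "rs0001", mode="stratified-refit", design=d)
        for key in ("exposure_within_wildtype", "exposure_within_carrier"):
            j, lo, hi = joint.rereferenced[key]
            se = (math.log(hi) - math.log(lo)) / (2 * 1.96)
            r = refit.rereferenced[key][0]
            assert abs(math.log(r) - math.log(j)) < 3 * se


class TestInteractionCI:
    def test_degenerate_vcov_gives_point_interval(self):
        m = _model(2.0, 1.5, 4.0)
        est = interaction_ci(m, "snp", method="delta")
        assert est.reri == pytest.approx(est.reri_ci[0]) == pytest.approx(est.reri_ci[1])
        assert est.s_ci[0] == pytest.approx(est.s) == pytest.approx(est.s_ci[1])

    def test_reri_identity_from_coefficients(self, effect_cohort):
        cohort, _ = effect_cohort
        d = build_design(cohort, "rs0001")
        fit = fit_conditional_logistic(d.subset_terms(list(JOINT_TERMS)))
        est = interaction_ci(fit, "rs0001")
        o10, o01, o11 = (math.exp(fit.beta[fit.terms.index(t)]) for t in JOINT_TERMS)
        assert est.reri == pytest.approx(reri(o11, o10, o01), abs=1e-14)

    def test_negative_s_flagged_ci_undefined(self):
        vc = 0.01 * np.eye(3)
        m = _model(b10=0.5, b01=0.6, b11=1.5, vcov=vc)  # denom < 0, S < 0
        est = interaction_ci(m, "snp", method="delta")
        assert "s_negative_denominator" in est.flags
        assert est.s_ci is None
        assert est.reri_ci[0] < est.reri < est.reri_ci[1]

    def test_bootstrap_reproducible_with_seed(self, null_cohort):
        cohort, _ = null_cohort
        d = build_design(cohort, "rs0001")
        fit = fit_conditional_logistic(d.subset_terms(list(JOINT_TERMS)))
        a = interaction_ci(fit, "rs0001", method="bootstrap", design=d, n_boot=50, seed=4)
        b = interaction_ci(fit, "rs0001", method="bootstrap", design=d, n_boot=50, seed=4)
        assert a.reri_ci == b.reri_ci


class TestKnolTable:
    def _pair(self, snp_id, cell_n):
        m = _model(2.0, 1.5, 4.0, vcov=0.01 * np.eye(3))
        ors = stratum_ors(m, snp_id, mode="joint-model", cell_n=cell_n)
        return ors, interaction_ci(m, snp_id)

    def test_small_cell_segregated_as_inconclusive(self):
        good_n = {"ref": (100, 300), "exp-only": (20, 30), "carrier-only": (80, 250), "both": (10, 12)}
        small_n = dict(good_n, both=(3, 1))  # 4 exposed carriers
        table = knol_table([self._pair("ok", good_n), self._pair("sparse", small_n)])
        assert [r["snp_id"] for r in table["main"]] == ["ok"]
        assert [r["snp_id"] for r in table["inconclusive"]] == ["sparse"]
        assert "inconclusive_small_cell" in table["inconclusive"][0]["flags"]

    def test_reference_cell_printed_as_one(self):
        n = {"ref": (10, 30), "exp-only": (10, 10), "carrier-only": (10, 10), "both": (10, 10)}
        table = knol_table([self._pair("x", n)])
        assert table["main"][0]["ref_or"] == 1.00

    def test_empty_input_gives_empty_table(self):
        assert knol_table([]) == {"main": [], "inconclusive": []}
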