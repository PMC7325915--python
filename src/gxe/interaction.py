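"""Additive-scale exposure x genotype interaction: RERI and synergy index.

Subjects are classified into four joint categories against the doubly
unexposed reference (aspirin(-), wild-type): exposure only, carrier only,
and both.  The three non-reference categories enter the matched model as
indicators, so exp(beta) are the cell odds ratios OR10, OR01, OR11.
Departure from additivity is summarized by

    RERI = OR11 - OR10 - OR01 + 1
    S    = (OR11 - 1) / ((OR10 - 1) + (OR01 - 1))

with confidence intervals by the multivariate delta method on the model
coefficient covariance (RERI on the natural scale, S on the log scale), or
by stratum-level bootstrap resampling as an independent check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimation import DesignMatrix, FittedModel, fit_conditional_logistic

__all__ = [
    "JOINT_TERMS",
    "StratumORs",
    "InteractionEstimate",
    "joint_recode",
    "stratum_ors",
    "reri",
    "synergy_index",
    "attributable_proportion",
    "interaction_ci",
    "knol_table",
]

#: design-matrix names of the three non-reference joint-category indicators
JOINT_TERMS = ("exp_only", "carrier_only", "both")

_CATEGORY = {(0, 0): "ref", (1, 0): "exp-only", (0, 1): "carrier-only", (1, 1): "both"}


def joint_recode(exposed: int, carrier: int) -> str:
    """Map (exposed, carrier) to the four-category label; reference is
    (unexposed, wild-type).  Missing inputs must be handled upstream (the
    subject is excluded from that SNP's analysis)."""
    if exposed is None or carrier is None:
        raise ValueError("joint_recode requires non-missing exposure and carrier status")
    return _CATEGORY[(int(exposed), int(carrier))]


def joint_indicators(exposed: int, carrier: int) -> tuple[int, int, int]:
    """Indicator columns (exp_only, carrier_only, both) for the design matrix."""
    cat = joint_recode(exposed, carrier)
    return (int(cat == "exp-only"), int(cat == "carrier-only"), int(cat == "both"))


def reri(or11: float, or10: float, or01: float) -> float:
    """Relative excess risk due to interaction: OR11 - OR10 - OR01 + 1.

    Zero under exact additivity of odds-ratio excesses; under a
    multiplicative null (OR11 = OR10*OR01 with both factors harmful) RERI
    equals (OR10-1)(OR01-1) > 0, so the additive and multiplicative nulls
    differ.
    """
    if min(or11, or10, or01) <= 0:
        raise ValueError("odds ratios must be positive")
    return or11 - or10 - or01 + 1


def synergy_index(or11: float, or10: float, or01: float) -> float | None:
    """Synergy index S = (OR11 - 1) / ((OR10 - 1) + (OR01 - 1)).

    The ratio of the joint excess to the sum of the single-factor excesses;
    S > 1 indicates positive additive interaction.  Returns None when the
    denominator is zero (S undefined).
    """
    if min(or11, or10, or01) <= 0:
        raise ValueError("odds ratios must be positive")
    denom = (or10 - 1) + (or01 - 1)
    if denom == 0:
        return None
    return (or11 - 1) / denom


def attributable_proportion(or11: float, or10: float, or01: float) -> float:
    """Attributable proportion due to interaction: RERI / OR11."""
    return reri(or11, or10, or01) / or11


@dataclass
class StratumORs:
    """Four-cell OR layout plus re-referenced within-stratum ORs."""

    snp_id: str
    ors: dict[str, tuple[float, float, float]]  # term -> (OR, lo, hi); ref == 1.0
    cell_n: dict[str, tuple[int, int]]  # category -> (n_cases, n_controls)
    rereferenced: dict[str, tuple[float, float, float]]
    rereference_mode: str

    @property
    def or10(self) -> float:
        return self.ors["exp_only"][0]

    @property
    def or01(self) -> float:
        return self.ors["carrier_only"][0]

    @property
    def or11(self) -> float:
        return self.ors["both"][0]


@dataclass
class InteractionEstimate:
    snp_id: str
    reri: float
    reri_ci: tuple[float, float]
    s: float | None
    s_ci: tuple[float, float] | None
    ap: float
    method: str
    n_boot: int | None = None
    seed: int | None = None
    flags: list[str] = field(default_factory=list)


def _contrast_ci(model: FittedModel, plus: str, minus: str, level: float = 0.95):
    """exp(beta_plus - beta_minus) with a delta (exact, linear) Wald CI."""
    i, j = model.terms.index(plus), model.terms.index(minus)
    diff = model.beta[i] - model.beta[j]
    var = model.vcov[i, i] + model.vcov[j, j] - 2 * model.vcov[i, j]
    z = stats.norm.ppf(0.5 + level / 2)
    se = math.sqrt(max(var, 0.0))
    return (math.exp(diff), math.exp(diff - z * se), math.exp(diff + z * se))


def stratum_ors(
    model: FittedModel,
    snp_id: str = "",
    mode: str = "stratified-refit",
    design: DesignMatrix | None = None,
    cell_n: dict[str, tuple[int, int]] | None = None,
) -> StratumORs:
    """Cell ORs vs the (unexposed, wild-type) reference plus re-referenced
    within-stratum ORs.

    mode='joint-model' derives within-stratum ORs as coefficient contrasts
    of the joint fit (OR(exposure | carrier) = OR11/OR01 exactly, CI from
    the contrast variance).  mode='stratified-refit' refits the matched
    model within each genotype (and exposure) stratum subset, which is how
    within-stratum ORs are usually tabulated; it requires ``design`` with
    columns 'exposed' and 'carrier' alongside the joint terms.
    """
    for t in JOINT_TERMS:
        if t not in model.terms:
            raise ValueError(f"model lacks joint-category term {t!r}")
    ors = {t: model.or_ci(t) for t in JOINT_TERMS}
    reref: dict[str, tuple[float, float, float]] = {}
    if mode == "joint-model":
        reref["exposure_within_wildtype"] = model.or_ci("exp_only")
        reref["exposure_within_carrier"] = _contrast_ci(model, "both", "carrier_only")
        reref["carrier_within_unexposed"] = model.or_ci("carrier_only")
        reref["carrier_within_exposed"] = _contrast_ci(model, "both", "exp_only")
    elif mode == "stratified-refit":
        if design is None:
            raise ValueError("stratified-refit mode requires the design matrix")
        reref.update(_stratified_refit(design))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return StratumORs(
        snp_id=snp_id,
        ors=ors,
        cell_n=cell_n or {},
        rereferenced=reref,
        rereference_mode=mode,
    )


def _subset_fit_or(design: DesignMatrix, keep_mask, term: str):
    """Refit the matched model for one term on a subject subset.

    Strata losing their case or all controls under the subset are dropped."""
    sub_strata = []
    for s in np.unique(design.stratum):
        rows = (design.stratum == s) & keep_mask
        if design.y[rows].sum() == 1 and rows.sum() >= 2:
            sub_strata.append(s)
    mask = np.isin(design.stratum, sub_strata) & keep_mask
    i = design.terms.index(term)
    sub = DesignMatrix(design.X[mask][:, [i]], design.y[mask], design.stratum[mask], [term])
    fit = fit_conditional_logistic(sub)
    return fit.or_ci(term)


def _stratified_refit(design: DesignMatrix):
    exposed = design.X[:, design.terms.index("exposed")]
    carrier = design.X[:, design.terms.index("carrier")]
    return {
        "exposure_within_wildtype": _subset_fit_or(design, carrier == 0, "exposed"),
        "exposure_within_carrier": _subset_fit_or(design, carrier == 1, "exposed"),
        "carrier_within_unexposed": _subset_fit_or(design, exposed == 0, "carrier"),
        "carrier_within_exposed": _subset_fit_or(design, exposed == 1, "carrier"),
    }


# ---------------------------------------------------------------------------
# confidence intervals for RERI and S


def _reri_delta(model: FittedModel, level: float):
    idx = [model.terms.index(t) for t in JOINT_TERMS]
    b10, b01, b11 = (model.beta[i] for i in idx)
    V = model.vcov[np.ix_(idx, idx)]
    o10, o01, o11 = math.exp(b10), math.exp(b01), math.exp(b11)
    est = o11 - o10 - o01 + 1
    grad = np.array([-o10, -o01, o11])
    var = float(grad @ V @ grad)
    z = stats.norm.ppf(0.5 + level / 2)
    se = math.sqrt(max(var, 0.0))
    return est, (est - z * se, est + z * se)


def _s_delta(model: FittedModel, level: float):
    idx = [model.terms.index(t) for t in JOINT_TERMS]
    b10, b01, b11 = (model.beta[i] for i in idx)
    V = model.vcov[np.ix_(idx, idx)]
    o10, o01, o11 = math.exp(b10), math.exp(b01), math.exp(b11)
    denom = o10 + o01 - 2
    if denom == 0 or (o11 - 1) / denom <= 0:
        return (None if denom == 0 else (o11 - 1) / denom), None
    s = (o11 - 1) / denom
    # d lnS / d beta = dS/dbeta / S
    ds = np.array([-(o11 - 1) * o10 / denom**2, -(o11 - 1) * o01 / denom**2, o11 / denom])
    grad = ds / s
    var = float(grad @ V @ grad)
    z = stats.norm.ppf(0.5 + level / 2)
    se = math.sqrt(max(var, 0.0))
    return s, (s * math.exp(-z * se), s * math.exp(z * se))


def interaction_ci(
    model: FittedModel,
    snp_id: str = "",
    method: str = "delta",
    design: DesignMatrix | None = None,
    n_boot: int = 2000,
    seed: int | None = None,
    level: float = 0.95,
) -> InteractionEstimate:
    """RERI and S with confidence intervals.

    method='delta' (default): RERI variance from the gradient
    (-e^{b10}, -e^{b01}, e^{b11}) against the 3x3 coefficient covariance; S
    interval on the log scale (undefined, with a flag, when S <= 0).
    method='bootstrap': matched strata resampled with replacement, model
    refit per replicate, percentile intervals; requires ``design`` and a
    seed for reproducibility.
    """
    idx = [model.terms.index(t) for t in JOINT_TERMS]
    o10, o01, o11 = (math.exp(model.beta[i]) for i in idx)
    flags: list[str] = []
    est_reri = reri(o11, o10, o01)
    est_s = synergy_index(o11, o10, o01)
    ap = attributable_proportion(o11, o10, o01)
    if est_s is None:
        flags.append("s_undefined")
    elif (o10 - 1) + (o01 - 1) < 0:
        flags.append("s_negative_denominator")

    if method == "delta":
        _, reri_ci = _reri_delta(model, level)
        _, s_ci = _s_delta(model, level)
        if est_s is not None and est_s > 0 and s_ci is None:
            s_ci = None
        if est_s is not None and est_s <= 0:
            flags.append("s_ci_undefined_log_scale")
        return InteractionEstimate(snp_id, est_reri, reri_ci, est_s, s_ci, ap,
                                   "delta", flags=flags)
    if method == "bootstrap":
        if design is None:
            raise ValueError("bootstrap method requires the design matrix")
        from .estimation import _newton, _Padded

        pad = _Padded(design.subset_terms(list(model.terms)))
        rng = np.random.default_rng(seed)
        jidx = [model.terms.index(t) for t in JOINT_TERMS]
        reris, ss = [], []
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        for _ in range(n_boot):
            draw = rng.integers(pad.S, size=pad.S)
            try:
                beta, _, _, _, conv, _ = _newton(pad.take(draw), start=model.beta)
            except np.linalg.LinAlgError:
                continue
            if not conv or np.max(np.abs(beta)) > 15:
                continue
            b10, b01, b11 = (math.exp(beta[i]) for i in jidx)
            reris.append(b11 - b10 - b01 + 1)
            d = (b10 - 1) + (b01 - 1)
            if d != 0:
                ss.append((b11 - 1) / d)
        reri_ci = tuple(float(q) for q in np.quantile(reris, [lo_q, hi_q]))
        s_ci = (tuple(float(q) for q in np.quantile(ss, [lo_q, hi_q]))
                if ss and est_s is not None else None)
        return InteractionEstimate(snp_id, est_reri, reri_ci, est_s, s_ci, ap,
                                   "bootstrap", n_boot=n_boot, seed=seed, flags=flags)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# presentation


def knol_table(results, min_cell: int = 5):
    """Assemble per-SNP interaction results in the recommended joint-
    classification layout.

    ``results`` is an iterable of (StratumORs, InteractionEstimate) pairs.
    Returns {'main': rows, 'inconclusive': rows}: any SNP with fewer than
    ``min_cell`` subjects (cases + controls) in one of the four analysis
    cells is segregated as inconclusive rather than interpreted.
    """
    main, inconclusive = [], []
    for ors, inter in results:
        row = {
            "snp_id": ors.snp_id,
            "ref_or": 1.00,
            "or10": ors.ors["exp_only"],
            "or01": ors.ors["carrier_only"],
            "or11": ors.ors["both"],
            "cell_n": dict(ors.cell_n),
            "rereferenced": dict(ors.rereferenced),
            "reri": inter.reri,
            "reri_ci": inter.reri_ci,
            "s": inter.s,
            "s_ci": inter.s_ci,
            "flags": list(inter.flags),
        }
        small = any(
            (nc + nn) < min_cell for nc, nn in ors.cell_n.values()
        ) if ors.cell_n else False
        if small:
            row["flags"].append("inconclusive_small_cell")
            inconclusive.append(row)
        else:
            main.append(row)
    return {"main": main, "inconclusive": inconclusive}
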