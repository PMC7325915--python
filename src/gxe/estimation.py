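"""Matched-set conditional logistic regression and covariate selection.

The estimator is the conditional likelihood for 1:m matched case-control
strata: conditioning on each stratum containing exactly one case gives

    logL(beta) = sum_s [ x_case . beta - log sum_{j in s} exp(x_j . beta) ],

which absorbs every stratum-constant effect (age band, sex, center,
recruitment period).  The score and Hessian are the exact derivatives of
this expression and the fit is Newton-Raphson with step-halving.

Also provided: crude 2x2 odds ratios with Woolf intervals, the P < alpha
bivariate covariate screen, and change-in-estimate backward elimination
under a BIC-improvement constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DesignMatrix",
    "FittedModel",
    "TwoByTwo",
    "DesignError",
    "FitError",
    "conditional_loglik",
    "fit_conditional_logistic",
    "crude_or",
    "screen_covariates",
    "backward_eliminate",
]


class DesignError(ValueError):
    """The design violates the 1-case-per-stratum contract."""


class FitError(RuntimeError):
    """Newton-Raphson failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class DesignMatrix:
    """Subject-level design for the conditional fit.

    X rows align with ``y`` (case indicator) and ``stratum`` (integer
    stratum index).  Columns are named model terms; stratum-constant terms
    are legal but uninformative (absorbed by the conditioning).
    """

    X: np.ndarray
    y: np.ndarray
    stratum: np.ndarray
    terms: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.stratum = np.asarray(self.stratum)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise DesignError("X/y shape mismatch")
        if self.X.shape[1] != len(self.terms):
            raise DesignError("term names do not match X columns")
        if np.isnan(self.X).any():
            raise DesignError("design matrix contains missing values")

    def subset_terms(self, terms: list[str]) -> "DesignMatrix":
        idx = [self.terms.index(t) for t in terms]
        return DesignMatrix(self.X[:, idx], self.y, self.stratum, list(terms))

    def subset_strata(self, strata_ids) -> "DesignMatrix":
        mask = np.isin(self.stratum, strata_ids)
        return DesignMatrix(self.X[mask], self.y[mask], self.stratum[mask], list(self.terms))

    @property
    def n_strata(self) -> int:
        return len(np.unique(self.stratum))


@dataclass
class FittedModel:
    terms: list[str]
    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_strata_used: int
    converged: bool
    iterations: int
    separation: list[str] = field(default_factory=list)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def odds_ratio(self, term: str) -> float:
        return float(np.exp(self.beta[self.terms.index(term)]))

    def wald_p(self, term: str) -> float:
        i = self.terms.index(term)
        se = math.sqrt(self.vcov[i, i])
        if se == 0:
            return 1.0
        z = self.beta[i] / se
        return float(2 * stats.norm.sf(abs(z)))

    def or_ci(self, term: str, level: float = 0.95) -> tuple[float, float, float]:
        i = self.terms.index(term)
        se = math.sqrt(self.vcov[i, i])
        z = stats.norm.ppf(0.5 + level / 2)
        return (
            float(np.exp(self.beta[i])),
            float(np.exp(self.beta[i] - z * se)),
            float(np.exp(self.beta[i] + z * se)),
        )

    def bic(self) -> float:
        return -2.0 * self.loglik + len(self.terms) * math.log(max(self.n_strata_used, 1))


@dataclass(frozen=True)
class TwoByTwo:
    """Exposed-case a, exposed-control b, unexposed-case c, unexposed-control d."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")


# ---------------------------------------------------------------------------
# padded stratum representation


class _Padded:
    """Strata padded to a common size for vectorized likelihood evaluation."""

    def take(self, idx) -> "_Padded":
        """Resampled copy holding the strata indexed by ``idx`` (bootstrap)."""
        out = _Padded.__new__(_Padded)
        out.Xp = self.Xp[idx]
        out.mask = self.mask[idx]
        out.caseX = self.caseX[idx]
        out.S, out.m, out.p = len(idx), self.m, self.p
        return out

    def __init__(self, design: DesignMatrix):
        ids, inverse = np.unique(design.stratum, return_inverse=True)
        S = len(ids)
        cases_per = np.bincount(inverse, weights=design.y, minlength=S)
        if not np.all(cases_per == 1):
            bad = ids[np.nonzero(cases_per != 1)[0][0]]
            raise DesignError(
                f"stratum {bad!r} has {int(cases_per[cases_per != 1][0])} cases; "
                "exactly one case per stratum is required"
            )
        sizes = np.bincount(inverse, minlength=S)
        m = int(sizes.max())
        p = design.X.shape[1]
        self.Xp = np.zeros((S, m, p))
        self.mask = np.zeros((S, m), dtype=bool)
        self.caseX = np.zeros((S, p))
        slot = np.zeros(S, dtype=int)
        for i in range(design.X.shape[0]):
            s = inverse[i]
            j = slot[s]
            self.Xp[s, j] = design.X[i]
            self.mask[s, j] = True
            slot[s] += 1
            if design.y[i] == 1:
                self.caseX[s] = design.X[i]
        self.S, self.m, self.p = S, m, p

    def loglik(self, beta: np.ndarray, order: int = 2):
        eta = self.Xp @ beta  # (S, m)
        eta = np.where(self.mask, eta, -np.inf)
        emax = eta.max(axis=1, keepdims=True)
        w = np.exp(eta - emax)
        denom = w.sum(axis=1, keepdims=True)
        lse = (emax + np.log(denom)).ravel()
        value = float((self.caseX @ beta).sum() - lse.sum())
        if order == 0:
            return value
        w = w / denom  # softmax weights within stratum
        xbar = np.einsum("sm,smp->sp", w, self.Xp)
        grad = self.caseX.sum(axis=0) - xbar.sum(axis=0)
        if order == 1:
            return value, grad
        exx = np.einsum("sm,smp,smq->pq", w, self.Xp, self.Xp)
        hess = -(exx - xbar.T @ xbar)
        return value, grad, hess


def conditional_loglik(beta, design: DesignMatrix):
    """Conditional log-likelihood with its exact gradient and Hessian.

    Strata whose members all share identical covariate rows contribute a
    beta-independent constant (-log m_s); such terms cancel in the score.
    """
    beta = np.asarray(beta, dtype=float)
    return _Padded(design).loglik(beta, order=2)


def fit_conditional_logistic(
    design: DesignMatrix,
    tol: float = 1e-8,
    rel_tol: float = 1e-10,
    max_iter: int = 100,
    separation_bound: float = 15.0,
    start: np.ndarray | None = None,
) -> FittedModel:
    """Newton-Raphson (step-halving) maximization of the conditional likelihood.

    Convergence when max |score| < ``tol`` or the relative log-likelihood
    change falls below ``rel_tol``.  Coefficients drifting beyond
    ``separation_bound`` on the log-odds scale are reported as separated
    (the term names are listed on the returned model), never silently
    returned as finite estimates of an infinite MLE.
    """
    pad = _Padded(design)
    beta, vcov, ll, it, converged, trace = _newton(
        pad, start, tol, rel_tol, max_iter
    )
    if not converged:
        raise FitError(f"no convergence after {max_iter} iterations", trace)
    separated = [t for t, b in zip(design.terms, beta) if abs(b) > separation_bound]
    return FittedModel(
        terms=list(design.terms),
        beta=beta,
        vcov=vcov,
        loglik=ll,
        n_strata_used=pad.S,
        converged=converged,
        iterations=it,
        separation=separated,
    )


def _newton(pad: _Padded, start, tol=1e-8, rel_tol=1e-10, max_iter=100):
    p = pad.p
    beta = np.zeros(p) if start is None else np.array(start, dtype=float)
    trace: list[float] = []
    ll, grad, hess = pad.loglik(beta)
    trace.append(ll)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        # ridge the Hessian if singular (e.g. stratum-constant columns)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(-hess + 1e-8 * np.eye(p), grad)
        # step-halving line search
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = pad.loglik(cand, order=0)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2
        beta = beta + scale * step
        ll_prev = ll
        ll, grad, hess = pad.loglik(beta)
        trace.append(ll)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        if abs(ll - ll_prev) < rel_tol * (abs(ll_prev) + 1e-12):
            converged = True
            break
    try:
        vcov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(-hess)
    vcov = (vcov + vcov.T) / 2
    return beta, vcov, ll, it, converged, trace


def fit_logistic_fixed_strata(
    design: DesignMatrix, tol: float = 1e-8, max_iter: int = 100
) -> FittedModel:
    """Unconditional logistic regression with one fixed intercept per
    stratum — the cross-check companion to the conditional fit.

    The reported terms/vcov cover only the shared covariate terms; stratum
    intercepts are nuisance parameters.  With many small strata this
    estimator is biased away from the null (the classical many-nuisance
    problem), so it is a sanity check, not the primary estimator.
    """
    ids, inverse = np.unique(design.stratum, return_inverse=True)
    S = len(ids)
    Z = np.zeros((design.X.shape[0], S))
    Z[np.arange(len(inverse)), inverse] = 1.0
    X = np.hstack([design.X, Z])
    y = design.y.astype(float)
    p = X.shape[1]
    beta = np.zeros(p)
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        grad = X.T @ (y - mu)
        W = mu * (1 - mu)
        hess = -(X * W[:, None]).T @ X
        step = np.linalg.solve(-hess + 1e-10 * np.eye(p), grad)
        beta = beta + step
        if np.max(np.abs(grad)) < tol:
            break
    vcov_full = np.linalg.pinv((X * W[:, None]).T @ X)
    k = design.X.shape[1]
    ll = float(y @ (X @ beta) - np.sum(np.log1p(np.exp(X @ beta))))
    return FittedModel(
        terms=list(design.terms),
        beta=beta[:k],
        vcov=(vcov_full[:k, :k] + vcov_full[:k, :k].T) / 2,
        loglik=ll,
        n_strata_used=S,
        converged=it < max_iter,
        iterations=it,
        separation=[t for t, b in zip(design.terms, beta[:k]) if abs(b) > 15],
    )


# ---------------------------------------------------------------------------
# crude odds ratio


def crude_or(t: TwoByTwo, level: float = 0.95):
    """Crude OR = ad/bc with the Woolf (log-scale) confidence interval.

    A single zero cell triggers the Haldane-Anscombe +0.5 correction and the
    result is flagged ``corrected``.  Two zero cells in the same row or
    column leave the OR undefined.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    zero_pairs = [(a, b), (c, d), (a, c), (b, d)]
    if any(x == 0 and y == 0 for x, y in zero_pairs):
        raise ValueError("odds ratio undefined: two zero cells share a row/column")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return {
        "or": math.exp(log_or),
        "ci": (math.exp(log_or - z * se), math.exp(log_or + z * se)),
        "corrected": corrected,
    }


# ---------------------------------------------------------------------------
# covariate selection


def screen_covariates(design: DesignMatrix, candidates: list[str], alpha: float = 0.2):
    """Bivariate screen: keep candidates whose matched single-term model has
    Wald p < alpha.  Order preserved; unestimable candidates are logged and
    excluded."""
    kept: list[str] = []
    log: list[tuple[str, str]] = []
    for cand in candidates:
        sub = design.subset_terms([cand])
        try:
            fit = fit_conditional_logistic(sub)
        except (FitError, np.linalg.LinAlgError) as e:
            log.append((cand, f"unestimable: {e}"))
            continue
        if fit.separation:
            log.append((cand, "separation"))
            continue
        if fit.wald_p(cand) < alpha:
            kept.append(cand)
    return kept, log


def backward_eliminate(
    design: DesignMatrix,
    exposure_terms: list[str],
    candidates: list[str],
    cie: float = 0.10,
    scale: str = "coefficient",
):
    """Backward elimination with a change-in-estimate guard and BIC gate.

    Starting from exposure_terms + candidates, repeatedly consider dropping
    the remaining candidate with the largest Wald p.  A drop is accepted
    only if (i) every exposure-term coefficient moves by at most ``cie``
    relative (log-odds scale by default; ``scale='or'`` compares odds
    ratios) and (ii) the BIC = -2 logL + k log(n_strata) decreases.  Stops
    when no candidate satisfies both.  Returns the final model and the full
    decision log.
    """
    current = list(exposure_terms) + [c for c in candidates if c not in exposure_terms]
    fit = fit_conditional_logistic(design.subset_terms(current))
    log: list[dict] = []
    while True:
        in_play = [t for t in current if t not in exposure_terms]
        if not in_play:
            break
        by_p = sorted(in_play, key=fit.wald_p, reverse=True)
        accepted = None
        for cand in by_p:
            reduced_terms = [t for t in current if t != cand]
            reduced = fit_conditional_logistic(design.subset_terms(reduced_terms))
            deltas = _exposure_shift(fit, reduced, exposure_terms, scale)
            ok_cie = all(d <= cie for d in deltas.values())
            ok_bic = reduced.bic() < fit.bic()
            log.append(
                {
                    "candidate": cand,
                    "wald_p": fit.wald_p(cand),
                    "max_shift": max(deltas.values()) if deltas else 0.0,
                    "bic_before": fit.bic(),
                    "bic_after": reduced.bic(),
                    "dropped": ok_cie and ok_bic,
                }
            )
            if ok_cie and ok_bic:
                accepted = (cand, reduced)
                break
        if accepted is None:
            break
        cand, fit = accepted
        current.remove(cand)
    return fit, log


def _exposure_shift(full: FittedModel, reduced: FittedModel, exposure_terms, scale):
    out = {}
    for t in exposure_terms:
        b0 = full.beta[full.terms.index(t)]
        b1 = reduced.beta[reduced.terms.index(t)]
        if scale == "or":
            o0, o1 = math.exp(b0), math.exp(b1)
            out[t] = abs(o1 - o0) / abs(o0)
        else:
            out[t] = abs(b1 - b0) / abs(b0) if b0 != 0 else abs(b1 - b0)
    return out
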