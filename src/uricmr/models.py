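"""Association models: Hardy–Weinberg test, linear/logistic fits, Cox PH.

The Cox proportional-hazards estimator is implemented here directly
(Newton–Raphson on the partial likelihood with Efron tie correction and
step-halving) because the partial-likelihood machinery is the quantity the
surrounding causal analysis consumes and validates; the linear and logistic
fits delegate to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "EffectEstimate",
    "HWEResult",
    "hwe_test",
    "linear_fit",
    "logistic_fit",
    "cox_fit",
    "cox_partial_loglik",
]

Z95 = 1.96  # two-sided 95% multiplier, fixed at the conventional 1.96


@dataclass
class EffectEstimate:
    """A single regression coefficient with its uncertainty.

    ``beta`` lives on the model's linear scale (log-hazard for Cox,
    log-odds for logistic, exposure-SD units for a linear fit).  For the
    exponentiated scales the confidence bounds are reported on the ratio
    scale, ``exp(beta +/- 1.96*se)``.
    """

    term: str
    beta: float
    se: float
    scale: str          # "linear" | "log_hazard" | "log_odds"
    n: int
    events: int | None = None
    converged: bool = True
    p_value: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self):
        if self.se > 0:
            z = self.beta / self.se
            self.p_value = 2.0 * stats.norm.sf(abs(z))
        else:
            self.p_value = 0.0 if self.beta != 0 else 1.0
        low = self.beta - Z95 * self.se
        high = self.beta + Z95 * self.se
        if self.scale in ("log_hazard", "log_odds"):
            low, high = np.exp(low), np.exp(high)
        self.ci_low = float(low)
        self.ci_high = float(high)

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "scale": self.scale,
            "n": self.n,
            "events": self.events,
            "converged": self.converged,
        }


@dataclass
class HWEResult:
    """Pearson chi-square test of Hardy–Weinberg proportions (1 df)."""

    observed: tuple
    allele_freq: float
    expected: tuple
    chi2: float
    p_value: float
    df: int = 1

    def to_dict(self) -> dict:
        return {
            "observed": list(self.observed),
            "allele_freq": self.allele_freq,
            "expected": list(self.expected),
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
        }


def hwe_test(n0: int, n1: int, n2: int) -> HWEResult:
    """Pearson chi-square test for deviation from Hardy–Weinberg equilibrium.

    ``n0, n1, n2`` are genotype counts for 0, 1, 2 copies of the effect
    allele.  Expected counts use the estimated allele frequency
    ``p = (2 n2 + n1) / 2n``; the statistic is referred to chi-square with
    one degree of freedom, no continuity correction.
    """
    counts = np.array([n0, n1, n2], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one genotyped subject")
    p = (2 * counts[2] + counts[1]) / (2 * n)
    if p == 0.0 or p == 1.0:
        raise ValueError("monomorphic genotypes: HWE test undefined")
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return HWEResult(
        observed=(int(n0), int(n1), int(n2)),
        allele_freq=float(p),
        expected=tuple(expected),
        chi2=chi2,
        p_value=float(stats.chi2.sf(chi2, 1)),
    )


def _as_design(x, covariates):
    x = np.asarray(x, dtype=float)
    cols = [x.reshape(-1, 1)]
    names = ["x"]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C.reshape(-1, 1)
        cols.append(C)
        if isinstance(covariates, pd.DataFrame):
            names += list(covariates.columns)
        else:
            names += [f"cov{i}" for i in range(C.shape[1])]
    X = np.hstack(cols)
    return X, names


def _check_rank(X: np.ndarray, names, with_intercept: bool) -> None:
    M = np.hstack([np.ones((X.shape[0], 1)), X]) if with_intercept else X
    if np.linalg.matrix_rank(M) < M.shape[1]:
        # name the columns involved via near-zero R diagonal of a QR factorization
        _, R = np.linalg.qr(M)
        diag = np.abs(np.diag(R))
        tol = diag.max() * 1e-10
        offset = 1 if with_intercept else 0
        bad = [names[i - offset] for i in np.flatnonzero(diag < tol) if i >= offset]
        label = ", ".join(bad) if bad else "intercept"
        raise ValueError(f"rank-deficient design; collinear columns: {label}")


def linear_fit(y, x, covariates=None, term: str = "x") -> EffectEstimate:
    """Ordinary least squares; returns the coefficient on ``x``.

    ``covariates`` (array or DataFrame) are adjusted for; an intercept is
    always included.  The SE comes from the residual variance in the usual
    way, CI = beta +/- 1.96 se.
    """
    y = np.asarray(y, dtype=float)
    X, names = _as_design(x, covariates)
    if np.ptp(X[:, 0]) == 0:
        raise ValueError("x is constant")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("not enough observations for the requested model")
    _check_rank(X, names, with_intercept=True)

    res = sm.OLS(y, sm.add_constant(X)).fit()
    return EffectEstimate(
        term=term,
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        scale="linear",
        n=len(y),
    )


def logistic_fit(y, x, covariates=None, term: str = "x") -> EffectEstimate:
    """Maximum-likelihood logistic regression; log-odds per unit of ``x``.

    Complete or quasi-complete separation is flagged by returning an
    estimate with ``converged=False`` (from a bounded quasi-Newton refit)
    rather than raising.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X, names = _as_design(x, covariates)
    _check_rank(X, names, with_intercept=True)
    design = sm.add_constant(X)

    model = sm.Logit(y, design)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(disp=0)
        separated = (not res.mle_retvals.get("converged", True)) or abs(res.params[1]) > 15
    except Exception:
        separated = True
        res = None
    if separated:
        with np.errstate(all="ignore"):
            res = model.fit(method="bfgs", maxiter=200, disp=0)
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(se):
        se = np.inf
    return EffectEstimate(
        term=term,
        beta=beta,
        se=se,
        scale="log_odds",
        n=len(y),
        converged=not separated,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def cox_partial_loglik(beta, time, event, X, ties: str = "efron"):
    """Partial log-likelihood with gradient and observed information.

    Efron's correction handles tied event times by default ("breslow"
    selectable).  Returns ``(loglik, gradient, hessian)`` where the hessian
    is of the log-likelihood (negative definite away from degeneracy).
    """
    beta = np.asarray(beta, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    n, p = X.shape

    order = np.argsort(-time, kind="mergesort")  # descending: risk sets are prefixes
    t = time[order]
    d = event[order]
    Xs = X[order]

    eta = Xs @ beta
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]
    cw = np.cumsum(w)
    cwx = np.cumsum(wx, axis=0)
    cwxx = np.cumsum(wxx, axis=0)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))

    # walk groups of equal time
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    ends = np.r_[starts[1:], n] - 1
    for s, e in zip(starts, ends):
        tied = np.flatnonzero(d[s:e + 1]) + s
        dj = tied.size
        if dj == 0:
            continue
        S_R, Z_R, Q_R = cw[e], cwx[e], cwxx[e]
        ll += eta[tied].sum()
        grad += Xs[tied].sum(axis=0)
        if ties == "efron" and dj > 1:
            S_D = w[tied].sum()
            Z_D = wx[tied].sum(axis=0)
            Q_D = wxx[tied].sum(axis=0)
            for ell in range(dj):
                f = ell / dj
                phi = S_R - f * S_D
                num = Z_R - f * Z_D
                Q = Q_R - f * Q_D
                ll -= np.log(phi)
                grad -= num / phi
                hess -= Q / phi - np.outer(num, num) / phi ** 2
        else:  # breslow, or a single event (identical)
            ll -= dj * np.log(S_R)
            grad -= dj * Z_R / S_R
            hess -= dj * (Q_R / S_R - np.outer(Z_R, Z_R) / S_R ** 2)
    return ll, grad, hess


def cox_fit(
    time,
    event,
    x,
    covariates=None,
    ties: str = "efron",
    term: str = "x",
    max_iter: int = 60,
    grad_tol: float = 1e-8,
    loglik_tol: float = 1e-10,
) -> EffectEstimate:
    """Cox proportional-hazards fit; log-hazard ratio per unit of ``x``.

    Newton–Raphson from beta = 0 with step-halving; convergence when the
    maximal score component falls below ``grad_tol`` or the log-likelihood
    improves by less than ``loglik_tol``.  The SE is model-based, from the
    observed information at the optimum.  A monotone partial likelihood
    (all events at one exposure extreme) yields ``converged=False``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if event.sum() < 1:
        raise ValueError("no events: Cox model undefined")
    X, names = _as_design(x, covariates)
    _check_rank(X, names, with_intercept=False)
    center = X.mean(axis=0)
    Xc = X - center  # centering leaves beta and its SE unchanged

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = cox_partial_loglik(beta, time, event, Xc, ties)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        alpha = 1.0
        for _half in range(40):
            cand = beta + alpha * step
            ll_new, g_new, h_new = cox_partial_loglik(cand, time, event, Xc, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-13:
                break
            alpha *= 0.5
        else:
            break
        delta_ll = ll_new - ll
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
        if abs(delta_ll) < loglik_tol:
            converged = np.max(np.abs(grad)) < 1e-4
            break
    if np.max(np.abs(beta)) > 15:
        converged = False  # monotone likelihood: estimate diverging

    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(-hess)
            se = float(np.sqrt(cov[0, 0]))
        except np.linalg.LinAlgError:
            se = np.inf
    return EffectEstimate(
        term=term,
        beta=float(beta[0]),
        se=se,
        scale="log_hazard",
        n=len(time),
        events=int(event.sum()),
        converged=bool(converged),
    )
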