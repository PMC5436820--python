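"""Zero-altered (hurdle) count models of CPUE by direct maximum likelihood.

Two independent parts: a logistic model for whether any lobsters were
landed, and a zero-truncated Poisson (ZAP) or NB2 (ZANB) model for the
positive counts.  The joint log-likelihood separates, so each part is
maximised on its own; the pieces are recombined into a single fit with
AIC, standard errors from the observed information, likelihood-ratio
testing, family selection and marginality-respecting stepwise
simplification down to the minimum adequate model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln
from scipy.stats import chi2 as chi2_dist

from .types import ValidationError

__all__ = [
    "HurdleDesign",
    "HurdleFit",
    "LrtResult",
    "SeparationError",
    "hurdle_loglik",
    "fit_hurdle",
    "lrt",
    "lrt_pvalue",
    "select_family",
    "stepwise_simplify",
    "predict_cpue",
    "residuals_vs_fitted",
]

TERMS = ("intercept", "ntz_open", "pots", "ntz_open:pots")
FULL_TERMS = TERMS
_THETA_CAP = 1e8  # dispersion above this is numerically Poisson


class SeparationError(ValueError):
    """The zero part is perfectly separated; its MLE does not exist."""


@dataclass(frozen=True)
class HurdleDesign:
    """Model structure: covariate data, term sets for each part, family.

    ``data`` must provide columns ``ntz_open`` (0/1) and ``pots`` (numeric);
    terms are drawn from intercept, ntz_open, pots and their interaction.
    The intercept is always present and the interaction requires both main
    effects (marginality).
    """

    data: pd.DataFrame
    zero_terms: tuple[str, ...] = FULL_TERMS
    count_terms: tuple[str, ...] = FULL_TERMS
    family: str = "negbin"

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "negbin"):
            raise ValidationError(f"family must be poisson or negbin, got {self.family!r}")
        for part, terms in (("zero", self.zero_terms), ("count", self.count_terms)):
            if "intercept" not in terms:
                raise ValidationError(f"{part} part must contain the intercept")
            for t in terms:
                if t not in TERMS:
                    raise ValidationError(f"unknown term {t!r} in {part} part")
            if "ntz_open:pots" in terms and not (
                "ntz_open" in terms and "pots" in terms
            ):
                raise ValidationError(
                    f"{part} part: interaction requires both main effects"
                )

    def _matrix(self, terms: tuple[str, ...]) -> np.ndarray:
        n = len(self.data)
        ntz = self.data["ntz_open"].to_numpy(dtype=float)
        pots = self.data["pots"].to_numpy(dtype=float)
        cols = {
            "intercept": np.ones(n),
            "ntz_open": ntz,
            "pots": pots,
            "ntz_open:pots": ntz * pots,
        }
        return np.column_stack([cols[t] for t in terms])

    def zero_matrix(self) -> np.ndarray:
        return self._matrix(self.zero_terms)

    def count_matrix(self) -> np.ndarray:
        return self._matrix(self.count_terms)

    @property
    def n_params(self) -> int:
        k = len(self.zero_terms) + len(self.count_terms)
        return k + 1 if self.family == "negbin" else k


@dataclass
class HurdleFit:
    """A fitted hurdle model."""

    design: HurdleDesign
    counts: np.ndarray
    zero_coefs: np.ndarray
    count_coefs: np.ndarray
    zero_se: np.ndarray
    count_se: np.ndarray
    dispersion: float  # theta; inf for Poisson family
    loglik: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return self.design.n_params

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    @property
    def fitted_zero_probs(self) -> np.ndarray:
        """P(count > 0) per observation."""
        return expit(self.design.zero_matrix() @ self.zero_coefs)

    @property
    def fitted_conditional_means(self) -> np.ndarray:
        """Untruncated count-part mean mu per observation."""
        return np.exp(self.design.count_matrix() @ self.count_coefs)

    @property
    def fitted_means(self) -> np.ndarray:
        """Unconditional hurdle mean pi*mu/(1 - f(0; mu, theta))."""
        pi = self.fitted_zero_probs
        mu = self.fitted_conditional_means
        return pi * mu / (1.0 - _log_f0_exp(mu, self.dispersion))


@dataclass(frozen=True)
class LrtResult:
    chi2: float
    df: int
    p_value: float


def _log_f0(mu: np.ndarray, theta: float) -> np.ndarray:
    """log P(Y=0) for the untruncated Poisson (theta=inf) or NB2."""
    mu = np.asarray(mu, dtype=float)
    if math.isinf(theta) or theta > _THETA_CAP:
        return -mu
    return theta * (math.log(theta) - np.log(theta + mu))


def _log_f0_exp(mu: np.ndarray, theta: float) -> np.ndarray:
    return np.exp(_log_f0(mu, theta))


def _log1m_f0(mu: np.ndarray, theta: float) -> np.ndarray:
    """log(1 - P(Y=0)), stable for small mu (where f0 -> 1)."""
    log_f0 = np.minimum(_log_f0(mu, theta), -1e-12)
    return np.log(-np.expm1(log_f0))


def _count_logpmf(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    """Untruncated Poisson/NB2 log pmf (vectorised, log-space)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if math.isinf(theta) or theta > _THETA_CAP:
        return y * np.log(mu) - mu - gammaln(y + 1.0)
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1.0)
        + theta * (math.log(theta) - np.log(theta + mu))
        + y * (np.log(mu) - np.log(theta + mu))
    )


def _check_counts(counts) -> np.ndarray:
    y = np.asarray(counts)
    if y.size == 0:
        raise ValidationError("counts must be non-empty")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValidationError("counts must be non-negative integers")
    return y.astype(float)


def hurdle_loglik(params, counts, design: HurdleDesign) -> float:
    """Hurdle log-likelihood at a concatenated parameter vector.

    ``params`` is (zero-part coefs, count-part coefs[, log theta]).  Zeros
    contribute log(1-pi); positives contribute log pi plus the
    zero-truncated count log-density.
    """
    y = _check_counts(counts)
    params = np.asarray(params, dtype=float)
    kz = len(design.zero_terms)
    kc = len(design.count_terms)
    expected = kz + kc + (1 if design.family == "negbin" else 0)
    if params.size != expected:
        raise ValidationError(
            f"expected {expected} parameters for this design, got {params.size}"
        )
    beta_zero = params[:kz]
    beta_count = params[kz:kz + kc]
    theta = math.exp(params[-1]) if design.family == "negbin" else math.inf

    eta_zero = design.zero_matrix() @ beta_zero
    # log pi and log(1-pi) via stable softplus
    log_pi = -np.logaddexp(0.0, -eta_zero)
    log_1mpi = -np.logaddexp(0.0, eta_zero)
    mu = np.exp(np.clip(design.count_matrix() @ beta_count, -500, 500))

    pos = y > 0
    ll = float(np.sum(log_1mpi[~pos]))
    if pos.any():
        ll += float(
            np.sum(
                log_pi[pos]
                + _count_logpmf(y[pos], mu[pos], theta)
                - _log1m_f0(mu[pos], theta)
            )
        )
    return ll


def _fit_logistic(X: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, float]:
    """Newton-Raphson logistic MLE; raises on perfect separation."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(200):
        eta = X @ beta
        prob = expit(eta)
        w = np.maximum(prob * (1 - prob), 1e-12)
        grad = X.T @ (z - prob)
        hess = X.T @ (X * w[:, None]) + 1e-10 * np.eye(p)
        step = np.linalg.solve(hess, grad)
        # dampen huge steps for stability
        norm = np.max(np.abs(step))
        if norm > 10:
            step *= 10 / norm
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    prob = expit(eta)
    pos, neg = prob[z == 1], prob[z == 0]
    if (
        (pos.size == 0 or neg.size == 0)
        or (pos.min() > 1 - 1e-8 and neg.max() < 1e-8)
    ):
        raise SeparationError(
            "zero part is perfectly separated; hurdle probabilities of 0/1 "
            "are not estimable"
        )
    ll = float(np.sum(z * np.log(prob + 1e-300) + (1 - z) * np.log(1 - prob + 1e-300)))
    return beta, ll


def _trunc_count_nll(params, Xpos, ypos, family):
    beta = params[:Xpos.shape[1]]
    theta = math.exp(min(params[-1], 40.0)) if family == "negbin" else math.inf
    mu = np.exp(np.clip(Xpos @ beta, -500, 500))
    ll = _count_logpmf(ypos, mu, theta) - _log1m_f0(mu, theta)
    return -float(np.sum(ll))


def _trunc_count_nll_grad(params, Xpos, ypos, family):
    """Negative truncated-count log-likelihood and its analytic gradient.

    Gradients are with respect to the linear predictor coefficients and, for
    the negbin family, log theta.
    """
    from scipy.special import digamma

    k = Xpos.shape[1]
    beta = params[:k]
    mu = np.exp(np.clip(Xpos @ beta, -500, 500))
    if family == "poisson":
        f0 = np.exp(-mu)
        denom = np.maximum(-np.expm1(-mu), 1e-300)
        nll = -float(np.sum(_count_logpmf(ypos, mu, math.inf) - np.log(denom)))
        deta = ypos - mu / denom
        grad = -(Xpos.T @ deta)
        return nll, grad
    s = min(params[-1], 40.0)
    theta = math.exp(s)
    log_f0 = np.minimum(theta * (math.log(theta) - np.log(theta + mu)), -1e-12)
    f0 = np.exp(log_f0)
    one_m_f0 = -np.expm1(log_f0)
    nll = -float(
        np.sum(_count_logpmf(ypos, mu, theta) - np.log(one_m_f0))
    )
    deta = (
        ypos
        - mu * (ypos + theta) / (theta + mu)
        - mu * theta * f0 / ((theta + mu) * one_m_f0)
    )
    g = math.log(theta) + 1.0 - np.log(theta + mu) - theta / (theta + mu)
    dtheta = (
        g / one_m_f0
        - ypos / (theta + mu)
        + digamma(ypos + theta)
        - digamma(theta)
    )
    grad = np.empty(k + 1)
    grad[:k] = -(Xpos.T @ deta)
    grad[-1] = -float(np.sum(dtheta)) * theta
    return nll, grad


def _num_hessian(f, x, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian; fine for the handful of parameters here."""
    x = np.asarray(x, dtype=float)
    p = x.size
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = eps
            ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return H


def _safe_se(H: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return np.full(H.shape[0], np.nan)


def fit_hurdle(counts, design: HurdleDesign) -> HurdleFit:
    """Maximum-likelihood hurdle fit; the two parts are fitted separately.

    The count part is warm-started from the zero-truncated Poisson solution
    (theta initialised at 1 for the negbin family).  The convergence flag is
    honest: optimiser failure is reported, never hidden.
    """
    y = _check_counts(counts)
    if len(y) != len(design.data):
        raise ValidationError("counts and design data differ in length")
    pos = y > 0
    if not pos.any():
        raise ValidationError("all counts are zero: count part is not estimable")
    if pos.all():
        raise ValidationError("no zero counts: zero part is not estimable")

    Xz = design.zero_matrix()
    beta_zero, ll_zero = _fit_logistic(Xz, pos.astype(float))

    Xc = design.count_matrix()[pos]
    ypos = y[pos]
    kc = Xc.shape[1]
    # optimise on RMS-scaled columns for conditioning; back-transform after
    scale = np.sqrt(np.mean(Xc * Xc, axis=0))
    scale[scale < 1e-12] = 1.0
    Xs = Xc / scale

    # truncated-Poisson warm start from zeros
    res_p = optimize.minimize(
        _trunc_count_nll_grad,
        np.zeros(kc),
        args=(Xs, ypos, "poisson"),
        method="BFGS",
        jac=True,
        options={"gtol": 1e-8, "maxiter": 500},
    )
    if design.family == "poisson":
        res_c = res_p
        beta_count = res_c.x / scale
        theta = math.inf
        count_params = beta_count
    else:
        start = np.append(res_p.x, 0.0)  # log theta = 0 -> theta = 1
        res_c = optimize.minimize(
            _trunc_count_nll_grad,
            start,
            args=(Xs, ypos, "negbin"),
            method="BFGS",
            jac=True,
            options={"gtol": 1e-8, "maxiter": 500},
        )
        beta_count = res_c.x[:kc] / scale
        theta = math.exp(min(res_c.x[-1], 40.0))
        count_params = np.append(beta_count, res_c.x[-1])

    ll_count = -float(res_c.fun)
    loglik = ll_zero + ll_count

    # observed-information standard errors per part
    zero_nll = lambda b: -float(
        np.sum(
            pos * -np.logaddexp(0.0, -(Xz @ b))
            + (1 - pos) * -np.logaddexp(0.0, Xz @ b)
        )
    )
    se_zero = _safe_se(_num_hessian(zero_nll, beta_zero))
    se_count_all = _safe_se(
        _num_hessian(
            lambda pvec: _trunc_count_nll(pvec, Xc, ypos, design.family), count_params
        )
    )
    se_count = se_count_all[:kc]

    # BFGS may report precision loss with the optimum already attained; accept
    # a small gradient as convergence but never hide a genuinely bad exit.
    grad_ok = bool(np.max(np.abs(np.atleast_1d(res_c.jac))) < 1e-3 * max(1.0, len(ypos) / 100))
    converged = (bool(res_c.success) or grad_ok) and np.isfinite(loglik)
    diagnostics = {
        "count_optimizer_message": str(res_c.message),
        "count_optimizer_nit": int(res_c.nit),
        "n_zero": int((~pos).sum()),
        "n_positive": int(pos.sum()),
    }
    if design.family == "negbin":
        diagnostics["log_theta_se"] = float(se_count_all[-1])
    return HurdleFit(
        design=design,
        counts=y.astype(int),
        zero_coefs=beta_zero,
        count_coefs=beta_count,
        zero_se=se_zero,
        count_se=se_count,
        dispersion=theta,
        loglik=loglik,
        converged=converged,
        diagnostics=diagnostics,
    )


def lrt_pvalue(chi2: float, df: int) -> float:
    """Upper-tail chi-square p-value for a likelihood-ratio statistic."""
    if chi2 < 0 or df < 0:
        raise ValidationError("chi2 and df must be non-negative")
    if df == 0:
        return 1.0
    return float(chi2_dist.sf(chi2, df))


def _is_nested(full: HurdleFit, reduced: HurdleFit) -> bool:
    same_terms = set(reduced.design.zero_terms) <= set(full.design.zero_terms) and set(
        reduced.design.count_terms
    ) <= set(full.design.count_terms)
    if not same_terms:
        return False
    if full.design.family == reduced.design.family:
        return full.n_params > reduced.n_params or (
            full.design.zero_terms == reduced.design.zero_terms
            and full.design.count_terms == reduced.design.count_terms
        )
    # ZAP is nested in ZANB (theta -> inf) with identical term sets
    return (
        full.design.family == "negbin"
        and reduced.design.family == "poisson"
        and full.design.zero_terms == reduced.design.zero_terms
        and full.design.count_terms == reduced.design.count_terms
    )


def lrt(fit_full: HurdleFit, fit_reduced: HurdleFit, boundary: bool = False) -> LrtResult:
    """Likelihood-ratio test of a reduced model against a full model.

    ``boundary=True`` applies the 50:50 chi2(0):chi2(1) mixture appropriate
    to the ZAP-vs-ZANB test (theta on the boundary); the default plain
    chi-square matches common practice.
    """
    if not _is_nested(fit_full, fit_reduced):
        raise ValidationError("models are not nested; LRT is undefined")
    chi2 = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    chi2 = max(chi2, 0.0)  # clip optimiser noise at converged optima
    df = fit_full.n_params - fit_reduced.n_params
    if df == 0:
        p = 1.0
    elif boundary and df == 1:
        p = 0.5 * lrt_pvalue(chi2, 1) if chi2 > 0 else 1.0
    else:
        p = lrt_pvalue(chi2, df)
    return LrtResult(chi2=chi2, df=df, p_value=p)


def select_family(
    counts, design: HurdleDesign, alpha: float = 0.05, boundary: bool = False
) -> tuple[str, dict[str, HurdleFit], LrtResult]:
    """Fit ZAP and ZANB with the same terms and pick by AIC plus LRT.

    The NB family is retained only when its AIC is lower and the dispersion
    LRT is significant; ties go to the more parsimonious Poisson.
    """
    design_p = replace(design, family="poisson")
    design_nb = replace(design, family="negbin")
    fit_p = fit_hurdle(counts, design_p)
    fit_nb = fit_hurdle(counts, design_nb)
    test = lrt(fit_nb, fit_p, boundary=boundary)
    chosen = (
        "negbin"
        if fit_nb.aic < fit_p.aic and test.p_value < alpha
        else "poisson"
    )
    return chosen, {"poisson": fit_p, "negbin": fit_nb}, test


def _droppable(terms: tuple[str, ...]) -> list[str]:
    out = []
    for t in terms:
        if t == "intercept":
            continue
        if t == "ntz_open:pots":
            out.append(t)
        elif "ntz_open:pots" not in terms:  # main effects droppable once no interaction
            out.append(t)
    return out


def stepwise_simplify(fit: HurdleFit, alpha: float = 0.05) -> HurdleFit:
    """Backward LRT simplification to the minimum adequate model.

    Interactions are considered before main effects (marginality); the zero
    and count parts are simplified independently.  At each step the single
    least-significant droppable term with p > alpha is removed; if the full
    model's terms all test significant it is returned unchanged.
    """
    current = fit
    while True:
        candidates = []  # (p_value, part, term, candidate_fit)
        for part in ("zero", "count"):
            terms = (
                current.design.zero_terms if part == "zero" else current.design.count_terms
            )
            for term in _droppable(terms):
                new_terms = tuple(t for t in terms if t != term)
                if part == "zero":
                    d = replace(current.design, zero_terms=new_terms)
                else:
                    d = replace(current.design, count_terms=new_terms)
                cand = fit_hurdle(current.counts, d)
                res = lrt(current, cand)
                candidates.append((res.p_value, part, term, cand))
        if not candidates:
            return current
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        best_p, _, _, best_fit = candidates[0]
        if best_p > alpha:
            current = best_fit
        else:
            return current


def predict_cpue(fit: HurdleFit, ntz_open, pots) -> np.ndarray:
    """Unconditional expected count per boatday: pi*mu/(1 - f(0; mu, theta))."""
    if not fit.converged:
        raise ValidationError("cannot predict from an unconverged fit")
    newdata = pd.DataFrame(
        {
            "ntz_open": np.atleast_1d(np.asarray(ntz_open, dtype=float)),
            "pots": np.atleast_1d(np.asarray(pots, dtype=float)),
        }
    )
    d = replace(fit.design, data=newdata)
    pi = expit(d.zero_matrix() @ fit.zero_coefs)
    mu = np.exp(d.count_matrix() @ fit.count_coefs)
    denom = -np.expm1(_log_f0(mu, fit.dispersion))
    return pi * mu / denom


def residuals_vs_fitted(fit: HurdleFit) -> pd.DataFrame:
    """Pearson residuals against unconditional fitted means, as a table."""
    pi = fit.fitted_zero_probs
    mu = fit.fitted_conditional_means
    theta = fit.dispersion
    f0 = _log_f0_exp(mu, theta)
    m = pi * mu / (1.0 - f0)
    if math.isinf(theta) or theta > _THETA_CAP:
        ey2 = mu + mu**2
    else:
        ey2 = mu + mu**2 * (1.0 + 1.0 / theta)
    var = pi * ey2 / (1.0 - f0) - m**2
    var = np.maximum(var, 1e-300)
    resid = (fit.counts - m) / np.sqrt(var)
    return pd.DataFrame({"fitted": m, "residual": resid})
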