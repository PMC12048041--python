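"""Psychometric-function fitting and perceptual metrics.

The probability of a "left slower" choice is modelled as a logistic
function of the belt-speed difference dv (m/s):

    p(left) = 1 / (1 + exp(-(beta0 + beta1 * dv)))

Per-subject fits are ordinary maximum-likelihood logistic regressions.
The group-level fit is a logistic mixed model with a Gaussian random
intercept and random slope per subject (independent components), whose
marginal likelihood is maximized under a Laplace approximation — the same
estimation strategy as lme4's ``glmer`` / MATLAB's ``fitglme``.

Perceptual metrics derive from the coefficients:

* PSE (point of subjective equality) = -beta0 / beta1, the stimulus at
  which both choices are equally likely; its 95% CI propagates the Wald
  CI of beta0 holding beta1 at its estimate.
* JND (just-noticeable difference) = ln(3) / beta1, half the distance
  between the 25% and 75% choice-rate stimuli; its CI maps the edges of
  beta1's Wald CI through the same transform (hence skewed).
* Weber fraction = 100 * JND / mean belt speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .preprocess import filter_trials

__all__ = [
    "PsychometricFit",
    "PerceptionMetrics",
    "GroupFit",
    "fit_logistic_subject",
    "fit_logistic",
    "pse",
    "jnd",
    "weber_fraction",
    "perception_metrics",
    "fit_mixed_logistic",
    "fit_full_model",
]

LN3 = float(np.log(3.0))
_Z95 = 1.959963984540054  # two-sided 95% normal quantile

#: Ridge penalty applied to beta1 only when the MLE diverges (separation).
SEPARATION_RIDGE = 1e-4


@dataclass(frozen=True)
class PsychometricFit:
    """Per-subject logistic fit: p(left) = logistic(beta0 + beta1 dv)."""

    beta0: float
    beta1: float  # per m/s
    cov: np.ndarray  # 2x2 coefficient covariance
    loglik: float
    n_trials: int
    converged: bool = True
    separation: bool = False

    @property
    def se(self) -> tuple[float, float]:
        return float(np.sqrt(self.cov[0, 0])), float(np.sqrt(self.cov[1, 1]))

    def predict(self, dv):
        """Left-choice probability at stimulus dv (m/s)."""
        return _expit(self.beta0 + self.beta1 * np.asarray(dv, dtype=float))


@dataclass(frozen=True)
class PerceptionMetrics:
    """PSE / JND / Weber fraction with 95% confidence intervals."""

    pse: float  # m/s
    pse_ci: tuple[float, float]
    jnd: float  # m/s
    jnd_ci: tuple[float, float]
    weber_fraction: float  # %
    significant_bias: bool


@dataclass
class GroupFit:
    """Mixed-logistic fit: fixed effects plus random-effect SDs."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    re_sd: tuple[float, float]  # (intercept, slope) random-effect SDs
    loglik: float
    converged: bool
    message: str = ""
    ranef: pd.DataFrame | None = field(default=None, repr=False)

    def coef(self, name: str) -> tuple[float, float, float]:
        """(estimate, se, p) for a named fixed effect."""
        i = self.names.index(name)
        return float(self.beta[i]), float(self.se[i]), float(self.pvalues[i])


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def _bernoulli_loglik(y, eta):
    # -log(1 + exp(-eta)) for y=1, -log(1 + exp(eta)) for y=0, stably
    s = np.where(y > 0.5, eta, -eta)
    return float(-np.logaddexp(0.0, -s).sum())


def _choice_data(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(dv in m/s, choice code) over included, responded trials."""
    t = table
    if "excluded" not in t.columns:
        t, _ = filter_trials(t)
    t = t[~t["excluded"] & (t["choice"] != "none")]
    dv = t["delta_v_mms"].to_numpy(dtype=float) / 1000.0
    y = t["choice_code"].to_numpy(dtype=float)
    return dv, y


def _is_separated(dv: np.ndarray, y: np.ndarray) -> bool:
    """Complete separation by a threshold on the single predictor."""
    if y.min() == y.max():
        return True
    lo, hi = dv[y == 1], dv[y == 0]
    return bool(lo.min() > hi.max() or lo.max() < hi.min())


def _newton_logistic(dv, y, ridge_beta1=0.0, max_iter=100, tol=1e-10):
    """Newton-Raphson logistic MLE with optional ridge on the slope.

    Returns (beta, cov, loglik, converged).  The gradient-norm stopping
    rule (1e-8 by default via ``tol`` on the step) matches IRLS practice.
    """
    X = np.column_stack([np.ones_like(dv), dv])
    pen = np.diag([0.0, ridge_beta1])
    beta = np.zeros(2)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = _expit(eta)
        w = p * (1.0 - p)
        grad = X.T @ (y - p) - pen @ beta
        hess = (X * w[:, None]).T @ X + pen
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(grad)) < 1e-8 and np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    p = _expit(eta)
    w = p * (1.0 - p)
    hess = (X * w[:, None]).T @ X + pen
    cov = np.linalg.pinv(hess)
    ll = _bernoulli_loglik(y, eta) - 0.5 * ridge_beta1 * beta[1] ** 2
    return beta, cov, ll, converged


def fit_logistic(dv: np.ndarray, y: np.ndarray) -> PsychometricFit:
    """Maximum-likelihood logistic fit of choice code on stimulus (m/s).

    Complete separation (a deterministic observer) makes the MLE diverge;
    in that case a weak ridge penalty on the slope keeps the estimates
    finite and the fit is flagged ``separation=True``.
    """
    dv = np.asarray(dv, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(dv).size < 2:
        raise ValueError("need >= 2 distinct stimulus levels with responses")
    separated = _is_separated(dv, y)
    if not separated:
        beta, cov, ll, converged = _newton_logistic(dv, y)
        if converged and np.all(np.isfinite(beta)):
            return PsychometricFit(
                beta0=float(beta[0]),
                beta1=float(beta[1]),
                cov=cov,
                loglik=ll,
                n_trials=y.size,
                converged=True,
            )
    beta, cov, ll, converged = _newton_logistic(
        dv, y, ridge_beta1=SEPARATION_RIDGE, max_iter=500
    )
    return PsychometricFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        cov=cov,
        loglik=ll,
        n_trials=y.size,
        converged=converged,
        separation=True,
    )


def fit_logistic_subject(table: pd.DataFrame, subject_id) -> PsychometricFit:
    """Fit one subject's psychometric function from a trial table."""
    sub = table[table["subject_id"] == subject_id]
    if sub.empty:
        raise KeyError(f"subject {subject_id!r} not in table")
    dv, y = _choice_data(sub)
    return fit_logistic(dv, y)


def pse(fit: PsychometricFit) -> tuple[float, tuple[float, float]]:
    """Point of subjective equality -beta0/beta1 (m/s) with 95% CI.

    The CI propagates the Wald interval of beta0 with beta1 held fixed at
    its estimate; a perceptual bias is significant when it excludes 0.
    """
    if not fit.beta1 > 0:
        raise ValueError(f"PSE undefined for beta1 = {fit.beta1} <= 0")
    se0 = fit.se[0]
    est = -fit.beta0 / fit.beta1
    lo = -(fit.beta0 + _Z95 * se0) / fit.beta1
    hi = -(fit.beta0 - _Z95 * se0) / fit.beta1
    return est, (min(lo, hi), max(lo, hi))


def jnd(fit: PsychometricFit) -> tuple[float, tuple[float, float]]:
    """Just-noticeable difference ln(3)/beta1 (m/s) with skewed 95% CI.

    The CI maps the edges of beta1's Wald interval through the same
    transform; if the lower edge of beta1 is non-positive the upper JND
    bound is unbounded (inf).
    """
    if not fit.beta1 > 0:
        raise ValueError(f"JND undefined for beta1 = {fit.beta1} <= 0")
    se1 = fit.se[1]
    b_lo, b_hi = fit.beta1 - _Z95 * se1, fit.beta1 + _Z95 * se1
    hi = LN3 / b_lo if b_lo > 0 else np.inf
    return LN3 / fit.beta1, (LN3 / b_hi, hi)


def weber_fraction(jnd_ms: float, mean_speed: float = 1.05) -> float:
    """JND as a percentage of the mean belt speed (both in m/s)."""
    if not mean_speed > 0:
        raise ValueError(f"mean speed must be > 0, got {mean_speed}")
    return 100.0 * jnd_ms / mean_speed


def perception_metrics(fit: PsychometricFit, mean_speed: float = 1.05) -> PerceptionMetrics:
    """Bundle PSE, JND and Weber fraction for one fit."""
    p, p_ci = pse(fit)
    j, j_ci = jnd(fit)
    return PerceptionMetrics(
        pse=p,
        pse_ci=p_ci,
        jnd=j,
        jnd_ci=j_ci,
        weber_fraction=weber_fraction(j, mean_speed),
        significant_bias=not (p_ci[0] <= 0.0 <= p_ci[1]),
    )


# ---------------------------------------------------------------------------
# Mixed logistic model (Laplace-approximated maximum likelihood)
# ---------------------------------------------------------------------------


def _laplace_subject(y, X, Z, beta, d_inv, u0):
    """Inner Newton step: maximize the joint log density over u (2-dim).

    Returns (u_hat, joint_at_mode, log|A|) with A the negated Hessian.
    """
    u = u0.copy()
    Xb = X @ beta
    for _ in range(50):
        eta = Xb + Z @ u
        p = _expit(eta)
        w = p * (1.0 - p)
        grad = Z.T @ (y - p) - d_inv * u
        A = (Z * w[:, None]).T @ Z + np.diag(d_inv)
        step = np.linalg.solve(A, grad)
        u = u + step
        if np.max(np.abs(grad)) < 1e-9 and np.max(np.abs(step)) < 1e-10:
            break
    eta = Xb + Z @ u
    p = _expit(eta)
    w = p * (1.0 - p)
    A = (Z * w[:, None]).T @ Z + np.diag(d_inv)
    joint = _bernoulli_loglik(y, eta) - 0.5 * float(d_inv @ u**2)
    sign, logdet = np.linalg.slogdet(A)
    return u, joint, float(logdet)


class _MixedLogistic:
    """Laplace marginal likelihood for a logistic GLMM with independent
    Gaussian random intercept + slope grouped by subject."""

    def __init__(self, y, X, dv, groups):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.dv = np.asarray(dv, dtype=float)
        self.groups = groups
        self.idx = [np.flatnonzero(groups == g) for g in np.unique(groups)]
        self.p = self.X.shape[1]
        self._warm = {}

    def neg_marginal(self, theta):
        beta, log_sd = theta[: self.p], theta[self.p :]
        d_inv = np.exp(-2.0 * log_sd)  # 1/sd^2 per component
        total = 0.0
        for k, rows in enumerate(self.idx):
            y, X = self.y[rows], self.X[rows]
            Z = np.column_stack([np.ones(rows.size), self.dv[rows]])
            u0 = self._warm.get(k, np.zeros(2))
            u, joint, logdetA = _laplace_subject(y, X, Z, beta, d_inv, u0)
            self._warm[k] = u
            # log-marginal_j = joint(u_hat) - 0.5 log|D| - 0.5 log|A|
            total += joint - float(np.sum(log_sd)) * 1.0 - 0.5 * logdetA
        return -total


def _fit_mixed(y, X, dv, groups, names):
    model = _MixedLogistic(y, X, dv, groups)
    # start fixed effects at the pooled logistic fit, SDs at moderate values
    beta_start = np.zeros(model.p)
    try:
        pooled, _, _, ok = _newton_logistic(dv, y)
        if ok:
            beta_start[0], beta_start[1] = pooled
    except Exception:
        pass
    theta0 = np.concatenate([beta_start, np.log([0.3, 5.0])])
    bounds = [(None, None)] * model.p + [(-8.0, 5.0)] * 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            model.neg_marginal,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
        )
    theta = res.x
    from statsmodels.tools.numdiff import approx_hess1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hess = approx_hess1(theta, model.neg_marginal)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(theta.size, np.nan)
    beta = theta[: model.p]
    se = se_all[: model.p]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    ranef = pd.DataFrame(
        [model._warm[k] for k in sorted(model._warm)],
        columns=["u_intercept", "u_slope"],
        index=np.unique(groups),
    )
    return GroupFit(
        names=list(names),
        beta=beta,
        se=se,
        pvalues=pvals,
        re_sd=(float(np.exp(theta[model.p])), float(np.exp(theta[model.p + 1]))),
        loglik=-float(res.fun),
        converged=bool(res.success),
        message=str(res.message),
        ranef=ranef,
    )


def _mixed_data(table: pd.DataFrame) -> pd.DataFrame:
    t = table
    if "excluded" not in t.columns:
        t, _ = filter_trials(t)
    t = t[~t["excluded"] & (t["choice"] != "none")].copy()
    t["dv"] = t["delta_v_mms"].astype(float) / 1000.0
    return t


def fit_mixed_logistic(table: pd.DataFrame) -> GroupFit:
    """Group-level logistic mixed model (random intercept + slope).

    Fixed effects are the population-mean intercept and slope; random
    effects are per-subject Gaussian deviations with independent
    components, integrated out by a Laplace approximation and the
    marginal likelihood maximized numerically.
    """
    t = _mixed_data(table)
    if t["subject_id"].nunique() < 2:
        raise ValueError("mixed model requires >= 2 subjects")
    y = t["choice_code"].to_numpy(dtype=float)
    dv = t["dv"].to_numpy()
    X = np.column_stack([np.ones_like(dv), dv])
    return _fit_mixed(y, X, dv, t["subject_id"].to_numpy(), ["intercept", "dv"])


def fit_full_model(table: pd.DataFrame) -> GroupFit:
    """Mixed model with exogenous regressors: habituation, learning,
    laterality.

    Adds to the base model the previous trial's stimulus (``dv_prev``,
    habituation), interactions of dv with block-2 and block-3 indicators
    (task learning), and |dv| (laterality / leg asymmetry).  dv_prev for a
    block's first trial is 0, but those trials are excluded from analysis
    anyway, so every fitted row has a genuine predecessor.
    """
    needed = {"block", "trial_index"}
    if not needed <= set(table.columns):
        raise ValueError(f"trial table missing columns: {sorted(needed - set(table.columns))}")
    t = table.copy()
    t = t.sort_values(["subject_id", "block", "trial_index"])
    prev = t.groupby(["subject_id", "block"])["delta_v_mms"].shift(1)
    t["dv_prev"] = prev.fillna(0.0) / 1000.0
    t = _mixed_data(t)
    if t["subject_id"].nunique() < 2:
        raise ValueError("mixed model requires >= 2 subjects")
    if float(t["dv"].abs().max()) == 0.0:
        raise ValueError("stimulus column is constant at 0; model is degenerate")
    dv = t["dv"].to_numpy()
    X = np.column_stack(
        [
            np.ones_like(dv),
            dv,
            t["dv_prev"].to_numpy(),
            dv * (t["block"].to_numpy() == 2),
            dv * (t["block"].to_numpy() == 3),
            np.abs(dv),
        ]
    )
    names = ["intercept", "dv", "dv_prev", "dv:block2", "dv:block3", "abs_dv"]
    y = t["choice_code"].to_numpy(dtype=float)
    return _fit_mixed(y, X, dv, t["subject_id"].to_numpy(), names)
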