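"""Fitting the drift-diffusion model to mean reaction times alone.

The chronometric curve predicted by the DDM with linear drift link is

    RT(dv) = t_nd + (2 / (sigma^2 mu)) * tanh(mu / 2),   mu = beta0 + beta1 dv

which is maximal where the drift vanishes (dv = -beta0/beta1) and decays
toward t_nd for large |mu|.  Fitting the four parameters (t_nd, sigma,
beta0, beta1) to the 13 per-stimulus mean RTs by least squares lets choice
behaviour — the full psychometric curve, hence PSE and JND — be predicted
without ever looking at the choices: the same (beta0, beta1) that shape
the RT curve parameterize p(left) = logistic(beta0 + beta1 dv).

The sign of beta1 is not identified by RTs (the curve is even in mu up to
relocating its peak), so the search is bounded to beta1 >= 0: observers
are assumed to answer more, not less, accurately for larger stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ddm import DriftLink, expected_rt
from .preprocess import filter_trials
from .psychometrics import LN3

__all__ = [
    "DDMFit",
    "fit_ddm_subject",
    "fit_ddm_curve",
    "mean_rt_table",
    "predict_psychometric",
    "recovery_experiment",
    "summarize_recovery",
]


@dataclass(frozen=True)
class DDMFit:
    """Least-squares DDM fit to per-stimulus mean RTs."""

    t_nd: float
    sigma: float
    beta0: float
    beta1: float  # per m/s, >= 0 by construction
    rss: float
    dv: np.ndarray = field(repr=False)  # stimuli used (m/s)
    predicted_rt: np.ndarray = field(repr=False)
    flat: bool = False  # beta1 pinned at 0 (RT curve carries no stimulus signal)

    @property
    def link(self) -> DriftLink:
        return DriftLink(self.beta0, self.beta1, self.sigma, self.t_nd)

    @property
    def pse(self) -> float:
        if not self.beta1 > 0:
            raise ValueError("PSE undefined: beta1 = 0 (flat fit)")
        return -self.beta0 / self.beta1

    @property
    def jnd(self) -> float:
        if not self.beta1 > 0:
            raise ValueError("JND undefined: beta1 = 0 (flat fit)")
        return LN3 / self.beta1


def mean_rt_table(table: pd.DataFrame, subject_id) -> pd.DataFrame:
    """Per-signed-stimulus mean RTs for one subject (responded trials only).

    Null trials are included: the zero-drift mean decision time 1/sigma^2
    is what pins down sigma.
    """
    sub = table[table["subject_id"] == subject_id]
    if sub.empty:
        raise KeyError(f"subject {subject_id!r} not in table")
    if "excluded" not in sub.columns:
        sub, _ = filter_trials(sub)
    inc = sub[~sub["excluded"] & (sub["choice"] != "none")]
    g = inc.groupby("delta_v_mms")["rt_s"]
    out = pd.DataFrame(
        {"mean_rt_s": g.mean(), "n": g.size(), "se": g.sem()}
    ).reset_index()
    return out


def _predict(theta, dv):
    t_nd, sigma, beta0, beta1 = theta
    return np.asarray(
        expected_rt(DriftLink(beta0, beta1, sigma, t_nd), dv), dtype=float
    )


def fit_ddm_curve(
    dv: np.ndarray,
    mean_rt: np.ndarray,
    weights: np.ndarray | None = None,
) -> DDMFit:
    """Bounded least-squares fit of (t_nd, sigma, beta0, beta1) to mean RTs.

    Parameters
    ----------
    dv : array
        Signed stimuli in m/s (>= 5 distinct levels required).
    mean_rt : array
        Observed mean RT per stimulus, seconds.
    weights : array, optional
        Per-stimulus weights for a weighted fit (e.g. inverse variances);
        default is the unweighted objective.

    Bounds: t_nd in [0, min RT], sigma > 0, beta0 free, beta1 >= 0; the
    optimizer runs from six deterministic starts spanning t_nd in {0,
    0.5 min RT} x sigma in {0.25, 0.5, 1} and keeps the best RSS.
    """
    dv = np.asarray(dv, dtype=float)
    rt = np.asarray(mean_rt, dtype=float)
    if np.unique(dv).size < 5:
        raise ValueError("need mean RTs at >= 5 distinct stimulus levels")
    w = np.ones_like(rt) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)
    rt_min = float(rt.min())

    def residuals(theta):
        return sw * (_predict(theta, dv) - rt)

    lo = [0.0, 1e-6, -np.inf, 0.0]
    hi = [rt_min, np.inf, np.inf, np.inf]
    span = float(np.ptp(np.abs(dv))) or 1.0
    beta1_0 = LN3 / (0.5 * span)  # JND at half the stimulus span
    best = None
    for tnd0 in (0.0, 0.5 * rt_min):
        for sig0 in (0.25, 0.5, 1.0):
            res = optimize.least_squares(
                residuals,
                x0=[tnd0, sig0, 0.0, beta1_0],
                bounds=(lo, hi),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            if best is None or res.cost < best.cost:
                best = res
    theta = best.x
    pred = _predict(theta, dv)
    # no stimulus signal in the fitted curve: pin beta1 at 0 and flag
    flat = bool(np.ptp(pred) < 1e-9)
    if flat:
        theta = np.array([theta[0], theta[1], theta[2], 0.0])
        pred = _predict(theta, dv)
    rss = float(np.sum(w * (pred - rt) ** 2))
    return DDMFit(
        t_nd=float(theta[0]),
        sigma=float(theta[1]),
        beta0=float(theta[2]),
        beta1=float(theta[3]),
        rss=rss,
        dv=dv,
        predicted_rt=pred,
        flat=flat,
    )


def fit_ddm_subject(
    table: pd.DataFrame, subject_id, weighted: bool = False
) -> DDMFit:
    """Fit the DDM to one subject's per-stimulus mean RTs."""
    means = mean_rt_table(table, subject_id)
    dv = means["delta_v_mms"].to_numpy(dtype=float) / 1000.0
    weights = None
    if weighted:
        se = means["se"].to_numpy(dtype=float)
        weights = np.where(se > 0, 1.0 / se**2, 0.0)
    return fit_ddm_curve(dv, means["mean_rt_s"].to_numpy(dtype=float), weights)


def predict_psychometric(fit: DDMFit, dv_grid) -> dict:
    """Choice probabilities predicted from an RT-only DDM fit.

    Uses the logistic/DDM equivalence p(left) = logistic(beta0 + beta1 dv)
    with the coefficients recovered from RTs; returns the curve plus the
    implied PSE and JND (m/s).
    """
    dv_grid = np.asarray(dv_grid, dtype=float)
    p = 0.5 * (1.0 + np.tanh(0.5 * (fit.beta0 + fit.beta1 * dv_grid)))
    return {"dv": dv_grid, "p_left": p, "pse": fit.pse, "jnd": fit.jnd}


def recovery_experiment(
    pop,
    spec=None,
    n_seeds: int = 10,
    seed: int = 0,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Parameter-recovery study: simulate, fit both ways, compare to truth.

    For each seed a cohort is simulated, preprocessed, and every subject
    fitted twice — logistic regression on choices and DDM least squares on
    mean RTs.  Returns one row per (seed, subject) with the generating and
    recovered PSE/JND from both routes; summary statistics (bias, RMSE,
    DDM-vs-choice correlation) are computed by
    :func:`summarize_recovery`.
    """
    from .cohort import generate_cohort
    from .protocol import ProtocolSpec
    from .psychometrics import fit_logistic_subject

    spec = spec or ProtocolSpec()
    rows = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        table, subjects = generate_cohort(pop, spec, rng=rng, dt=dt)
        clean, _ = filter_trials(table)
        for sid, subj in enumerate(subjects, start=1):
            row = {
                "seed": seed + k,
                "subject_id": sid,
                "pse_true": -subj.beta0 / subj.beta1,
                "jnd_true": LN3 / subj.beta1,
            }
            try:
                pf = fit_logistic_subject(clean, sid)
                if pf.beta1 > 0:
                    row["pse_choice"] = -pf.beta0 / pf.beta1
                    row["jnd_choice"] = LN3 / pf.beta1
            except (ValueError, KeyError):
                pass
            try:
                df = fit_ddm_subject(clean, sid)
                if df.beta1 > 0:
                    row["pse_ddm"] = df.pse
                    row["jnd_ddm"] = df.jnd
            except (ValueError, KeyError):
                pass
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_recovery(recovery: pd.DataFrame) -> pd.DataFrame:
    """Bias/RMSE of both JND estimators plus their per-seed correlation."""
    out = []
    for seed, g in recovery.groupby("seed"):
        row = {"seed": seed, "n_subjects": len(g)}
        for est in ("choice", "ddm"):
            err = g[f"jnd_{est}"] - g["jnd_true"]
            row[f"jnd_{est}_bias"] = float(err.mean())
            row[f"jnd_{est}_rmse"] = float(np.sqrt((err**2).mean()))
        both = g.dropna(subset=["jnd_choice", "jnd_ddm"])
        if len(both) >= 3:
            row["jnd_corr"] = float(
                stats.pearsonr(both["jnd_choice"], both["jnd_ddm"])[0]
            )
        out.append(row)
    return pd.DataFrame(out)
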