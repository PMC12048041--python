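"""Cohort-level summaries, correlations, and figure-style outputs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ddm_fit import fit_ddm_subject
from .preprocess import filter_trials, summarize_subject
from .psychometrics import fit_logistic_subject, perception_metrics

__all__ = ["correlate", "build_summary", "CohortSummary"]


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("inputs must have equal length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CohortSummary:
    """Per-subject metrics table plus group means and correlations."""

    per_subject: pd.DataFrame
    group_means: dict[str, float]
    group_sds: dict[str, float]
    correlations: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_subject": self.per_subject.to_dict(orient="records"),
            "group_means": self.group_means,
            "group_sds": self.group_sds,
            "correlations": {
                k: {"rho": v[0], "p": v[1]} for k, v in self.correlations.items()
            },
        }


_NUMERIC = [
    "pse_mms",
    "jnd_mms",
    "weber_fraction_pct",
    "accuracy",
    "mean_rt_s",
    "ddm_sigma",
    "ddm_t_nd_s",
    "ddm_pse_mms",
    "ddm_jnd_mms",
]


def build_summary(
    table: pd.DataFrame, mean_speed: float = 1.05, fit_ddm: bool = True
) -> CohortSummary:
    """Assemble the cohort summary from a trial table.

    Per subject: psychometric PSE/JND/WF (choices), overall accuracy and
    mean RT, and optionally the RT-only DDM fit with its implied PSE/JND.
    Correlations (Pearson) are computed across subjects for JND vs
    accuracy, accuracy vs mean RT, and JND vs mean RT whenever at least
    three subjects are available.  Metric units: mm/s for PSE/JND, % for
    the Weber fraction, seconds for RTs.
    """
    clean = table
    if "excluded" not in clean.columns:
        clean, _ = filter_trials(clean)
    rows = []
    for sid in clean["subject_id"].unique():
        summ = summarize_subject(clean, sid)
        row: dict = {
            "subject_id": sid,
            "accuracy": summ["overall_accuracy"],
            "mean_rt_s": summ["overall_mean_rt_s"],
        }
        try:
            pf = fit_logistic_subject(clean, sid)
            m = perception_metrics(pf, mean_speed)
            row.update(
                pse_mms=1000.0 * m.pse,
                jnd_mms=1000.0 * m.jnd,
                weber_fraction_pct=m.weber_fraction,
                significant_bias=m.significant_bias,
            )
        except (ValueError, KeyError):
            pass
        if fit_ddm:
            try:
                df = fit_ddm_subject(clean, sid)
                row.update(ddm_sigma=df.sigma, ddm_t_nd_s=df.t_nd)
                if df.beta1 > 0:
                    row.update(
                        ddm_pse_mms=1000.0 * df.pse, ddm_jnd_mms=1000.0 * df.jnd
                    )
            except (ValueError, KeyError):
                pass
        rows.append(row)
    per_subject = pd.DataFrame(rows)
    means = {
        c: float(per_subject[c].mean()) for c in _NUMERIC if c in per_subject.columns
    }
    sds = {
        c: float(per_subject[c].std(ddof=1))
        for c in _NUMERIC
        if c in per_subject.columns
    }
    corrs: dict[str, tuple[float, float]] = {}
    if len(per_subject) >= 3:
        pairs = {
            "jnd_vs_accuracy": ("jnd_mms", "accuracy"),
            "accuracy_vs_rt": ("accuracy", "mean_rt_s"),
            "jnd_vs_rt": ("jnd_mms", "mean_rt_s"),
        }
        for name, (a, b) in pairs.items():
            if a in per_subject.columns and b in per_subject.columns:
                sub = per_subject[[a, b]].dropna()
                if len(sub) >= 3:
                    try:
                        corrs[name] = correlate(sub[a], sub[b])
                    except ValueError:
                        pass
    return CohortSummary(
        per_subject=per_subject,
        group_means=means,
        group_sds=sds,
        correlations=corrs,
    )
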