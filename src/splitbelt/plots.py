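"""Figure-style plots: psychometric, chronometric, and JND-bar views."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_psychometric", "plot_chronometric", "plot_jnd_bars"]


def plot_psychometric(fits, dv_grid_mms=None, ax=None, mean_speed=1.05):
    """Individual logistic curves (grey) with their mean (black).

    ``fits`` maps subject id -> PsychometricFit; stimuli on the x-axis in
    mm/s.
    """
    if dv_grid_mms is None:
        dv_grid_mms = np.linspace(-300, 300, 241)
    dv = np.asarray(dv_grid_mms, dtype=float) / 1000.0
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    curves = []
    for fit in fits.values():
        p = fit.predict(dv)
        curves.append(p)
        ax.plot(dv_grid_mms, p, color="0.7", lw=0.6)
    if curves:
        ax.plot(dv_grid_mms, np.mean(curves, axis=0), color="k", lw=2)
    ax.axhline(0.5, color="0.8", ls="--", lw=0.8)
    ax.set_xlabel(r"$\Delta V$ (mm/s)")
    ax.set_ylabel("p(left slower)")
    ax.set_ylim(0, 1)
    return ax


def plot_chronometric(mean_rts, ddm_fit=None, ax=None):
    """Observed mean RTs per stimulus, optionally with the DDM curve."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        mean_rts["delta_v_mms"],
        mean_rts["mean_rt_s"],
        yerr=1.96 * mean_rts["se"],
        fmt="o",
        color="k",
        ms=4,
    )
    if ddm_fit is not None:
        grid = np.linspace(
            mean_rts["delta_v_mms"].min(), mean_rts["delta_v_mms"].max(), 201
        )
        from .ddm import expected_rt

        ax.plot(grid, expected_rt(ddm_fit.link, grid / 1000.0), color="tab:blue")
    ax.set_xlabel(r"$\Delta V$ (mm/s)")
    ax.set_ylabel("mean RT (s)")
    return ax


def plot_jnd_bars(summary, ax=None):
    """Per-subject JND bars ordered by magnitude (skewed CIs omitted when
    absent from the summary table)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    df = summary.per_subject.dropna(subset=["jnd_mms"]).sort_values("jnd_mms")
    ax.bar(range(len(df)), df["jnd_mms"], color="tab:gray")
    mean = df["jnd_mms"].mean()
    ax.axhline(mean, color="k", ls="--", lw=1, label=f"mean {mean:.1f} mm/s")
    ax.set_xlabel("participant (sorted)")
    ax.set_ylabel("JND (mm/s)")
    ax.legend(frameon=False)
    return ax
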