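"""Synthetic cohorts: choices and reaction times from the generative DDM.

Subjects are drawn from a Gaussian population over the drift-link
parameters (beta0, beta1, sigma, t_nd), with beta1 and sigma truncated to
positive values and t_nd truncated at zero, mirroring the Gaussian
random-effect assumption of the group-level analysis.  Every scheduled
trial is then simulated as a Wiener first-passage walk; trials whose
reaction time exceeds the response window are recorded as non-responses
(choice ``none``, missing RT) rather than dropped — removal is the
preprocessing stage's job.

Population defaults are calibrated to the reported group estimates:
sigma 0.5 +/- 0.1, t_nd 0.9 +/- 0.7 s, and a mean slope beta1 =
ln(3) / JND with JND 49.7 mm/s, i.e. about 22.1 per m/s, with its spread
chosen to reproduce the reported 22.6 mm/s JND standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddm import DriftLink, simulate_trials_linked
from .protocol import ProtocolSpec, build_protocol

__all__ = [
    "PopulationSpec",
    "draw_subjects",
    "generate_trials",
    "generate_cohort",
    "plant_nonresponses",
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
]

TRIAL_COLUMNS = [
    "subject_id",
    "block",
    "trial_index",
    "delta_v_mms",
    "choice",
    "rt_s",
    "first_after_break",
]

#: Non-response counts per absolute stimulus magnitude (mm/s) observed in
#: the 39-subject cohort: 16 of 6552 trials, concentrated at small stimuli.
OBSERVED_NONRESPONSE_COUNTS = {0: 5, 25: 5, 50: 3, 150: 2, 300: 1}


@dataclass(frozen=True)
class PopulationSpec:
    """Gaussian population over subject-level drift-link parameters."""

    beta0_mean: float = 0.0
    beta0_sd: float = 0.4
    beta1_mean: float = 22.1  # per m/s; ln(3) / (49.7 mm/s)
    beta1_sd: float = 8.0
    sigma_mean: float = 0.5
    sigma_sd: float = 0.1
    t_nd_mean: float = 0.9  # s
    t_nd_sd: float = 0.7
    n_subjects: int = 39

    def __post_init__(self) -> None:
        for name in ("beta0_sd", "beta1_sd", "sigma_sd", "t_nd_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def _truncated_normal(mean, sd, lo, size, rng):
    """Gaussian draws redrawn until above ``lo`` (lo excluded)."""
    if sd == 0:
        if mean <= lo:
            raise ValueError(f"degenerate draw at mean {mean} <= bound {lo}")
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    bad = out <= lo
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= lo
    return out


def draw_subjects(pop: PopulationSpec, rng: np.random.Generator) -> list[DriftLink]:
    """Draw ``pop.n_subjects`` drift-link parameter sets.

    beta1 and sigma are truncated strictly positive, t_nd at zero
    (inclusive); draws are reproducible given the generator state.
    """
    n = pop.n_subjects
    beta0 = rng.normal(pop.beta0_mean, pop.beta0_sd, n) if pop.beta0_sd else np.full(n, pop.beta0_mean)
    beta1 = _truncated_normal(pop.beta1_mean, pop.beta1_sd, 0.0, n, rng)
    sigma = _truncated_normal(pop.sigma_mean, pop.sigma_sd, 0.0, n, rng)
    if pop.t_nd_sd:
        t_nd = np.clip(rng.normal(pop.t_nd_mean, pop.t_nd_sd, n), 0.0, None)
    else:
        t_nd = np.full(n, pop.t_nd_mean)
    return [
        DriftLink(beta0=float(b0), beta1=float(b1), sigma=float(s), t_nd=float(t))
        for b0, b1, s, t in zip(beta0, beta1, sigma, t_nd)
    ]


def generate_trials(
    subject: DriftLink,
    schedule: pd.DataFrame,
    rng: np.random.Generator,
    window: float = 8.0,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Simulate one subject's choices and RTs over a trial schedule.

    ``schedule`` must carry ``delta_v_mms``; stimuli are converted to m/s
    before entering the drift link.  RTs exceeding ``window`` seconds are
    censored: choice ``none`` and missing RT.
    """
    if not window > subject.t_nd:
        raise ValueError(
            f"response window {window} s must exceed non-decision time "
            f"{subject.t_nd} s"
        )
    dv = schedule["delta_v_mms"].to_numpy(dtype=float) / 1000.0
    max_time = None if np.isinf(window) else window - subject.t_nd
    left, t_d = simulate_trials_linked(subject, dv, rng, dt=dt, max_time=max_time)
    rt = t_d + subject.t_nd
    censored = np.isnan(t_d) | (rt > window)
    out = schedule.copy()
    out["choice"] = np.where(censored, "none", np.where(left, "left", "right"))
    out["rt_s"] = np.where(censored, np.nan, rt)
    return out


def generate_cohort(
    pop: PopulationSpec,
    spec: ProtocolSpec | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    dt: float = 1e-3,
) -> tuple[pd.DataFrame, list[DriftLink]]:
    """Simulate a full cohort on a shared protocol schedule.

    Returns the trial table (one row per scheduled trial, including
    censored non-responses) and the generating per-subject parameters.
    Deterministic given the seed or generator.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    spec = spec or ProtocolSpec()
    schedule = build_protocol(spec, pop.n_subjects, rng)
    subjects = draw_subjects(pop, rng)
    tables = []
    for sid, subject in enumerate(subjects, start=1):
        sub_sched = schedule[schedule["subject_id"] == sid]
        tables.append(
            generate_trials(subject, sub_sched, rng, window=spec.response_window, dt=dt)
        )
    return pd.concat(tables, ignore_index=True)[TRIAL_COLUMNS], subjects


def plant_nonresponses(
    table: pd.DataFrame,
    counts_by_magnitude: dict[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Overwrite chosen trials with non-responses (fixture builder).

    ``counts_by_magnitude`` maps absolute stimulus magnitude (mm/s) to the
    number of trials to censor; defaults to the observed 16-trial pattern.
    Flagged first-after-break trials are left untouched so each excluded
    row keeps a single exclusion reason.
    """
    if counts_by_magnitude is None:
        counts_by_magnitude = OBSERVED_NONRESPONSE_COUNTS
    rng = rng or np.random.default_rng(0)
    out = table.copy()
    eligible = out["first_after_break"] == 0
    for mag, count in counts_by_magnitude.items():
        pool = out.index[(out["delta_v_mms"].abs() == mag) & eligible]
        if count > pool.size:
            raise ValueError(
                f"requested {count} non-responses at |{mag}| mm/s but only "
                f"{pool.size} eligible trials"
            )
        if count == pool.size:
            chosen = pool.to_numpy()
        else:
            chosen = rng.choice(pool.to_numpy(), size=count, replace=False)
        out.loc[chosen, "choice"] = "none"
        out.loc[chosen, "rt_s"] = np.nan
    return out


def write_trials(table: pd.DataFrame, path) -> None:
    """Write the trial-table CSV dialect (UTF-8, '.' decimal, empty RT for
    non-responses)."""
    table[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial-table CSV written by :func:`write_trials`."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df[TRIAL_COLUMNS]
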