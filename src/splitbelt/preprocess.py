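"""Trial coding, exclusion rules, and per-subject summaries.

Choices are coded 1 for "left slower", 0 for "right slower".  Accuracy is
1 when the choice names the belt that actually moved slower: the stimulus
is dv = V_right - V_left, so dv > 0 means the left belt is slower and the
correct choice is "left".  Null trials (dv = 0) have no correct answer and
carry no accuracy score.

Two exclusion rules apply before any analysis: non-response trials (no
keypress within the response window) and the first trial of each block,
which follows a treadmill break and is routinely missed.  Excluded rows
are flagged, never dropped, so row conservation is checkable; the removal
report quotes the non-response percentage against the full trial count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "score_accuracy",
    "filter_trials",
    "summarize_subject",
    "RemovalReport",
]


def score_accuracy(delta_v, choice):
    """Accuracy score: 1 correct, 0 incorrect, NaN undefined.

    Undefined for null stimuli (no correct choice exists) and for
    non-responses.  Vectorized over arrays; scalars return a float.
    """
    dv = np.asarray(delta_v, dtype=float)
    ch = np.asarray(choice, dtype=object)
    correct = np.where(dv > 0, "left", "right")
    acc = np.where(
        (dv == 0) | (ch == "none"),
        np.nan,
        (ch == correct).astype(float),
    )
    return acc if acc.ndim else float(acc)


@dataclass
class RemovalReport:
    """Accounting of excluded trials."""

    n_total: int
    n_nonresponse: int
    n_first_after_break: int
    nonresponse_by_magnitude: dict[int, int]

    @property
    def pct_nonresponse(self) -> float:
        """Non-responses as a percentage of all collected trials."""
        return 100.0 * self.n_nonresponse / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_nonresponse": self.n_nonresponse,
            "n_first_after_break": self.n_first_after_break,
            "pct_nonresponse": self.pct_nonresponse,
            "nonresponse_by_magnitude": {
                str(k): v for k, v in self.nonresponse_by_magnitude.items()
            },
        }


def filter_trials(table: pd.DataFrame) -> tuple[pd.DataFrame, RemovalReport]:
    """Code choices/accuracy and flag excluded trials.

    Adds columns ``choice_code`` (1 left / 0 right, NaN for none),
    ``accuracy``, ``excluded`` (bool) and ``exclude_reason``
    (``first_after_break`` takes precedence over ``non_response``, so each
    excluded row carries exactly one reason).
    """
    out = table.copy()
    dv = out["delta_v_mms"].to_numpy(dtype=float)
    ch = out["choice"].to_numpy(dtype=object)
    out["choice_code"] = np.where(ch == "none", np.nan, (ch == "left").astype(float))
    out["accuracy"] = score_accuracy(dv, ch)

    first = out["first_after_break"].to_numpy(dtype=bool)
    nonresp = ch == "none"
    reason = np.where(first, "first_after_break", np.where(nonresp, "non_response", ""))
    out["excluded"] = reason != ""
    out["exclude_reason"] = reason

    nonresp_only = nonresp & ~first
    by_mag = (
        pd.Series(np.abs(dv[nonresp_only]).astype(int)).value_counts().sort_index()
    )
    report = RemovalReport(
        n_total=len(out),
        n_nonresponse=int(nonresp_only.sum()),
        n_first_after_break=int(first.sum()),
        nonresponse_by_magnitude={int(k): int(v) for k, v in by_mag.items()},
    )
    return out, report


def _stim_summary(df: pd.DataFrame, key: str) -> pd.DataFrame:
    g = df.groupby(key)
    out = pd.DataFrame(
        {
            "n": g.size(),
            "mean_rt_s": g["rt_s"].mean(),
            "se_rt_s": g["rt_s"].sem(),
            "accuracy": g["accuracy"].mean(),
            "se_accuracy": g["accuracy"].sem(),
            "p_left": g["choice_code"].mean(),
            "se_p_left": g["choice_code"].sem(),
        }
    )
    out.index.name = key
    return out.reset_index()


def summarize_subject(table: pd.DataFrame, subject_id) -> dict:
    """Per-stimulus and overall summaries for one subject.

    Means are taken over included (responded, non-first) trials only.
    Returns per-signed-stimulus (13 levels) and pooled-absolute-magnitude
    (7 levels) tables plus overall mean RT and accuracy.  Null trials
    contribute RT and choice fraction but no accuracy.
    """
    sub = table[table["subject_id"] == subject_id]
    if sub.empty:
        raise KeyError(f"subject {subject_id!r} not in table")
    if "excluded" not in sub.columns:
        sub, _ = filter_trials(sub)
    inc = sub[~sub["excluded"]].copy()
    inc["abs_delta_v_mms"] = inc["delta_v_mms"].abs()
    return {
        "subject_id": subject_id,
        "by_stimulus": _stim_summary(inc, "delta_v_mms"),
        "by_magnitude": _stim_summary(inc, "abs_delta_v_mms"),
        "overall_mean_rt_s": float(inc["rt_s"].mean()),
        "overall_accuracy": float(inc["accuracy"].mean()),
        "n_included": int(len(inc)),
    }
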