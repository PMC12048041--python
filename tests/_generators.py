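"""Test-world generators that bypass the walk simulator.

Choices are drawn directly from the hierarchical logistic model the
psychometric fits assume, which makes fitting tests fast and puts the
generating distribution exactly inside the fitted model class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STIMULI_MMS = np.array(
    [-300, -200, -150, -100, -50, -25, 0, 25, 50, 100, 150, 200, 300]
)
BLOCK_REPS = [4] * 6 + [8] + [4] * 6


def make_choice_table(
    seed: int,
    n_subjects: int,
    beta0_mean: float = 0.0,
    beta0_sd: float = 0.4,
    beta1_mean: float = 22.1,
    beta1_sd: float = 8.0,
    beta4: float = 0.0,
    rt: float = 2.0,
) -> pd.DataFrame:
    """Trial table with Bernoulli choices from the hierarchical logistic
    model; ``beta4`` plants a laterality term on |dv|.  Stimulus order is
    shared across subjects, as in the protocol."""
    rng = np.random.default_rng(seed)
    base = np.repeat(STIMULI_MMS, BLOCK_REPS)
    order = {b: rng.permutation(base) for b in (1, 2, 3)}
    rows = []
    for s in range(1, n_subjects + 1):
        b0 = beta0_mean + beta0_sd * rng.standard_normal()
        b1 = max(beta1_mean + beta1_sd * rng.standard_normal(), 1.0)
        for b in (1, 2, 3):
            dv = order[b] / 1000.0
            mu = b0 + b1 * dv + beta4 * np.abs(dv)
            y = rng.random(dv.size) < 1.0 / (1.0 + np.exp(-mu))
            for i, (d, yy) in enumerate(zip(order[b], y), start=1):
                rows.append(
                    (s, b, i, int(d), "left" if yy else "right", rt, int(i == 1))
                )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "block",
            "trial_index",
            "delta_v_mms",
            "choice",
            "rt_s",
            "first_after_break",
        ],
    )
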