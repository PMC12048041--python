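"""Stimulus schedule for the 2AFC belt-speed discrimination protocol.

Each testing block presents every signed non-zero belt-speed difference
(+/-25, 50, 100, 150, 200, 300 mm/s) four times and the null stimulus
eight times, for 56 trials per block.  A block is built from a
pseudo-random base sequence of 14 trials (each signed magnitude once plus
two nulls) emitted in four variants: the base itself, its mirror image
(all signs negated), the base with presentation order flipped, and the
mirrored-and-flipped sequence.  Every subject sees the same stimulus
order.  The first trial of each block follows a treadmill break and is
flagged, since subjects routinely miss it; its stimulus can optionally be
re-presented at the end of the block so per-magnitude repetition counts
survive dropping the flagged trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolSpec",
    "build_block",
    "build_protocol",
    "validate_schedule",
    "SCHEDULE_COLUMNS",
]

SCHEDULE_COLUMNS = [
    "subject_id",
    "block",
    "trial_index",
    "delta_v_mms",
    "first_after_break",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Design constants of the testing protocol.

    ``delta_v`` values are carried in mm/s (the unit of the experiment's
    stimulus set); conversion to m/s happens at the model boundary.
    """

    mean_speed: float = 1.05  # m/s
    nonzero_magnitudes: tuple[int, ...] = (25, 50, 100, 150, 200, 300)
    reps_per_nonzero: int = 4
    null_reps: int = 8
    blocks: int = 3
    window_strides: int = 8
    stride_duration: float = 1.0  # s

    def __post_init__(self) -> None:
        if self.reps_per_nonzero % 4 or self.null_reps % 4:
            raise ValueError(
                "reps_per_nonzero and null_reps must be multiples of 4: the "
                "block is four variants (base/mirror/flip/both) of one base "
                "sequence"
            )
        if any(m <= 0 for m in self.nonzero_magnitudes):
            raise ValueError("nonzero magnitudes must be positive")

    @property
    def response_window(self) -> float:
        """Response window in seconds (stride count times stride duration)."""
        return self.window_strides * self.stride_duration

    @property
    def trials_per_block(self) -> int:
        return 2 * len(self.nonzero_magnitudes) * self.reps_per_nonzero + self.null_reps

    @property
    def signed_magnitudes(self) -> tuple[int, ...]:
        """All 13 stimulus levels in mm/s, negative to positive."""
        mags = sorted(self.nonzero_magnitudes)
        return tuple([-m for m in reversed(mags)] + [0] + mags)


def _base_sequence(spec: ProtocolSpec, rng: np.random.Generator) -> np.ndarray:
    """One shuffled pass: each signed magnitude once + nulls (balanced by
    construction since +m and -m both appear exactly once)."""
    seq = [m for mag in spec.nonzero_magnitudes for m in (mag, -mag)]
    seq += [0] * (spec.null_reps // 4)
    seq = np.array(seq, dtype=int)
    rng.shuffle(seq)
    return seq


def build_block(spec: ProtocolSpec, rng: np.random.Generator) -> np.ndarray:
    """Stimulus sequence (mm/s) of one block: base, mirror, flip, both.

    The four variants of the base sequence give exactly
    ``reps_per_nonzero`` presentations of every signed magnitude and
    ``null_reps`` nulls, with positive and negative stimuli balanced.
    """
    reps = spec.reps_per_nonzero // 4
    parts = []
    for _ in range(reps):
        base = _base_sequence(spec, rng)
        parts += [base, -base, base[::-1], -base[::-1]]
    return np.concatenate(parts)


def build_protocol(
    spec: ProtocolSpec,
    n_subjects: int,
    rng: np.random.Generator,
    append_first_trial_repeat: bool = False,
) -> pd.DataFrame:
    """Full cohort schedule: identical stimulus order for every subject.

    Parameters
    ----------
    append_first_trial_repeat : bool
        If True, the stimulus of each block's flagged first trial is
        re-presented as an extra trial at the block's end, so that after
        dropping first-after-break trials every magnitude retains its full
        repetition count (at the cost of one extra trial per block).

    Returns
    -------
    DataFrame with columns ``subject_id`` (1-based), ``block`` (1-based),
    ``trial_index`` (1-based within block), ``delta_v_mms`` and
    ``first_after_break`` (0/1).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    blocks = []
    for b in range(1, spec.blocks + 1):
        dv = build_block(spec, rng)
        if append_first_trial_repeat:
            dv = np.append(dv, dv[0])
        flag = np.zeros(dv.size, dtype=int)
        flag[0] = 1
        blocks.append(
            pd.DataFrame(
                {
                    "block": b,
                    "trial_index": np.arange(1, dv.size + 1),
                    "delta_v_mms": dv,
                    "first_after_break": flag,
                }
            )
        )
    one = pd.concat(blocks, ignore_index=True)
    out = pd.concat(
        [one.assign(subject_id=s) for s in range(1, n_subjects + 1)],
        ignore_index=True,
    )
    return out[SCHEDULE_COLUMNS]


@dataclass
class ScheduleReport:
    """Per-(block, magnitude) counts plus any deviations from the spec."""

    counts: pd.DataFrame  # index (block, delta_v_mms), column "count"
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_schedule(
    schedule: pd.DataFrame, spec: ProtocolSpec | None = None
) -> ScheduleReport:
    """Count stimuli per block and list deviations from the design.

    Counts are per subject (the schedule is identical across subjects; the
    first subject's is used).  An empty violation list means the schedule
    satisfies the spec exactly.
    """
    spec = spec or ProtocolSpec()
    expected = {m: spec.reps_per_nonzero for m in spec.signed_magnitudes if m != 0}
    expected[0] = spec.null_reps

    if len(schedule):
        sub = schedule[schedule["subject_id"] == schedule["subject_id"].iloc[0]]
    else:
        sub = schedule
    violations: list[str] = []
    rows = []
    block_ids = sorted(sub["block"].unique()) if len(sub) else range(1, spec.blocks + 1)
    for b in block_ids:
        got = (
            sub[sub["block"] == b]["delta_v_mms"].value_counts().to_dict()
            if len(sub)
            else {}
        )
        for m, want in expected.items():
            have = int(got.pop(m, 0))
            rows.append({"block": b, "delta_v_mms": m, "count": have})
            if have != want:
                violations.append(
                    f"block {b}: {m:+d} mm/s presented {have} times, expected {want}"
                )
        for m, have in got.items():
            rows.append({"block": b, "delta_v_mms": m, "count": int(have)})
            violations.append(f"block {b}: unexpected stimulus {m:+d} mm/s")
    counts = pd.DataFrame(rows).set_index(["block", "delta_v_mms"])
    return ScheduleReport(counts=counts, violations=violations)
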