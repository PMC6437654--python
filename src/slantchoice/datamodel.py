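"""Session and trial data model for slant-discrimination recordings.

A *session* is one neuron's worth of trials from either the fixation
(25-condition slant-tilt tuning) task or the two-alternative slant
discrimination task, together with metadata (area, monkey, stimulus
duration) and timing constants.

Sign convention for the discrimination task: planes with tilt 90 deg
(top of the plane nearer the observer) carry *negative* signed slant,
planes with tilt 270 deg carry *positive* signed slant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TASK_FIXATION = "fixation"
TASK_DISCRIMINATION = "discrimination"
TASKS = (TASK_FIXATION, TASK_DISCRIMINATION)

CHOICE_TOP_NEAR = "top_near"
CHOICE_TOP_FAR = "top_far"
CHOICE_NONE = "none"
CHOICES = (CHOICE_TOP_NEAR, CHOICE_TOP_FAR, CHOICE_NONE)

AREAS = ("CIP", "V3A")

#: depths (cm from the display) used in the discrimination task
DEPTHS_CM = (-2.25, 0.0, 2.25)

#: fixation-task grids: slant 0..60 deg in 20 deg steps, tilt 0..315 in 45 deg steps
FIXATION_SLANTS_DEG = (0.0, 20.0, 40.0, 60.0)
FIXATION_TILTS_DEG = tuple(float(t) for t in range(0, 360, 45))

#: per-monkey slant ladders (signed degrees) used in the discrimination task
LADDER_NZ = (-20.0, -10.0, -5.0, -2.5, -1.25, 0.0, 1.25, 2.5, 5.0, 10.0, 20.0)
LADDER_P = (-20.0, -9.0, -4.05, -1.83, -0.82, 0.0, 0.82, 1.83, 4.05, 9.0, 20.0)


class ValidationError(ValueError):
    """A trial table or session violates the data-model contract."""


class SchemaError(ValidationError):
    """A trial table is missing required columns or uses unknown codes."""


def fixation_conditions() -> list[tuple[float, float]]:
    """The 25 unique (slant, tilt) conditions of the tuning protocol.

    Slant 0 collapses all tilts into a single frontoparallel condition
    (tilt is undefined there, recorded as 0), so 25 = 3 x 8 + 1.
    """
    conds = [(0.0, 0.0)]
    for s in FIXATION_SLANTS_DEG[1:]:
        for t in FIXATION_TILTS_DEG:
            conds.append((s, t))
    return conds


@dataclass
class TrialRecord:
    """One stimulus presentation."""

    trial_id: int
    task: str
    slant_deg: float
    tilt_deg: float = np.nan
    depth_cm: float = 0.0
    choice: str = CHOICE_NONE
    spike_count: int = 0
    spike_times_ms: tuple[float, ...] | None = None
    eye_vpos_deg: float | None = None
    eye_vvel_deg_s: float | None = None
    vergence_deg: float | None = None

    def validate(self, stim_dur_ms: float = 1000.0) -> None:
        if self.trial_id <= 0:
            raise ValidationError(f"trial_id must be positive, got {self.trial_id}")
        if self.task not in TASKS:
            raise SchemaError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.choice not in CHOICES:
            raise SchemaError(
                f"unknown choice {self.choice!r}; expected one of {CHOICES}"
            )
        if (self.choice == CHOICE_NONE) != (self.task == TASK_FIXATION):
            raise ValidationError(
                f"trial {self.trial_id}: choice must be 'none' iff task is fixation "
                f"(task={self.task}, choice={self.choice})"
            )
        if self.spike_count < 0:
            raise ValidationError(f"trial {self.trial_id}: negative spike_count")
        if self.spike_times_ms is not None:
            times = np.asarray(self.spike_times_ms, dtype=float)
            if times.size and np.any(np.diff(times) < 0):
                raise ValidationError(f"trial {self.trial_id}: spike times not sorted")
            # stimulus window is half-open [0, stim_dur_ms)
            n_in = int(np.sum((times >= 0) & (times < stim_dur_ms)))
            if n_in != self.spike_count:
                raise ValidationError(
                    f"trial {self.trial_id}: spike_count={self.spike_count} but "
                    f"{n_in} spike times fall in [0, {stim_dur_ms}) ms"
                )


@dataclass
class Session:
    """One neuron's trials plus metadata.

    ``trials`` is a DataFrame with one row per :class:`TrialRecord` field
    (``spike_times_ms`` held as tuples / None in an object column).
    """

    neuron_id: str
    area: str
    monkey_id: str
    trials: pd.DataFrame
    stim_dur_ms: float = 1000.0
    preferred_sign_fixation: str = "unknown"
    extra: dict = field(default_factory=dict)

    COLUMNS = [
        "trial_id", "task", "slant_deg", "tilt_deg", "depth_cm", "choice",
        "spike_count", "spike_times_ms", "eye_vpos_deg", "eye_vvel_deg_s",
        "vergence_deg",
    ]

    def __post_init__(self) -> None:
        if isinstance(self.trials, (list, tuple)):
            self.trials = records_to_frame(self.trials)

    @property
    def task(self) -> str:
        tasks = self.trials["task"].unique()
        if len(tasks) != 1:
            raise ValidationError(f"session {self.neuron_id}: mixed tasks {tasks}")
        return tasks[0]

    def to_records(self) -> list[TrialRecord]:
        recs = []
        for row in self.trials.itertuples(index=False):
            d = row._asdict()
            recs.append(TrialRecord(**{k: d[k] for k in d if k in _FIELD_NAMES}))
        return recs

    def validate(self) -> None:
        if self.stim_dur_ms <= 0:
            raise ValidationError("stim_dur_ms must be positive")
        if self.area not in AREAS:
            raise SchemaError(f"unknown area {self.area!r}; expected one of {AREAS}")
        if self.preferred_sign_fixation not in ("positive", "negative", "unknown"):
            raise SchemaError(
                f"unknown preferred_sign_fixation {self.preferred_sign_fixation!r}"
            )
        ids = self.trials["trial_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate trial_id {dup}")
        for i, rec in enumerate(self.to_records()):
            try:
                rec.validate(self.stim_dur_ms)
            except ValidationError as exc:
                raise type(exc)(f"row {i + 1}: {exc}") from None

    # -- convenience selectors -------------------------------------------

    def screen_depth_trials(self) -> pd.DataFrame:
        """Discrimination trials at screen distance (0 cm), the only depth
        with enough repetitions for the neural analyses."""
        t = self.trials
        return t[(t["task"] == TASK_DISCRIMINATION) & (t["depth_cm"] == 0.0)]

    def counts_by_slant(self, depth_cm: float | None = 0.0) -> dict[float, np.ndarray]:
        t = self.trials[self.trials["task"] == TASK_DISCRIMINATION]
        if depth_cm is not None:
            t = t[t["depth_cm"] == depth_cm]
        return {
            s: g["spike_count"].to_numpy(dtype=float)
            for s, g in t.groupby("slant_deg", sort=True)
        }


_FIELD_NAMES = {f.name for f in dataclasses.fields(TrialRecord)}


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=Session.COLUMNS)
    frame["spike_times_ms"] = [
        tuple(r.spike_times_ms) if r.spike_times_ms is not None else None
        for r in records
    ]
    return frame


def sessions_equal(a: Session, b: Session, rtol: float = 0.0) -> bool:
    """Structural equality of two sessions (used by round-trip tests)."""
    if (a.neuron_id, a.area, a.monkey_id, a.stim_dur_ms, a.preferred_sign_fixation) != (
        b.neuron_id, b.area, b.monkey_id, b.stim_dur_ms, b.preferred_sign_fixation
    ):
        return False
    if len(a.trials) != len(b.trials):
        return False
    for col in Session.COLUMNS:
        xa, xb = a.trials[col], b.trials[col]
        if col == "spike_times_ms":
            for ta, tb in zip(xa, xb):
                if (ta is None) != (tb is None):
                    return False
                if ta is not None and not np.allclose(ta, tb, rtol=rtol, atol=0):
                    return False
        elif xa.dtype.kind in "fc":
            if not np.allclose(
                xa.to_numpy(float), xb.to_numpy(float),
                rtol=rtol, atol=0, equal_nan=True,
            ):
                return False
        else:
            if not (xa.to_numpy() == xb.to_numpy()).all():
                return False
    return True


def choice_sign(choices: Sequence[str] | pd.Series) -> np.ndarray:
    """Code choices numerically: top_near = -1, top_far = +1."""
    arr = np.asarray(choices)
    out = np.where(arr == CHOICE_TOP_FAR, 1.0, np.where(arr == CHOICE_TOP_NEAR, -1.0, np.nan))
    return out
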