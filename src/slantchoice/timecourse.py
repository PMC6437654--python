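"""Sliding-window dynamics of choice and stimulus signals.

All time-resolved statistics use 200-ms windows whose centers run from
100 ms to 1150 ms after stimulus onset in 50-ms steps (22 windows).
The first window is [0, 200) ms; the last, [1050, 1250), extends 150 ms
past the 1000-ms stimulus offset, reaching approximately the median
choice time (1271 ms after onset = stimulus duration + 271 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .choiceprob import InclusionError, grand_cp
from .datamodel import Session
from .neurometric import build_neurometric_curve
from .partialcorr import partial_correlations

#: median time of the choice saccade, ms after stimulus onset
#: (1000 ms stimulus + 271 ms post-offset)
MEDIAN_CHOICE_TIME_MS = 1000.0 + 271.0

METRICS = ("cp", "threshold", "spc2", "cpc2", "sdf")


@dataclass
class WindowSpec:
    width_ms: float = 200.0
    step_ms: float = 50.0
    first_center_ms: float = 100.0
    last_center_ms: float = 1150.0

    def centers(self) -> np.ndarray:
        if self.step_ms <= 0:
            raise ValueError("step_ms must be > 0")
        n = int(round((self.last_center_ms - self.first_center_ms) / self.step_ms)) + 1
        return self.first_center_ms + self.step_ms * np.arange(n)


def make_windows(spec: WindowSpec, stim_dur_ms: float = 1000.0) -> list[tuple[float, float]]:
    """Half-open [start, end) windows; they may extend past stimulus offset."""
    half = spec.width_ms / 2.0
    return [(c - half, c + half) for c in spec.centers()]


def median_choice_time_ms(stim_dur_ms: float = 1000.0,
                          post_offset_ms: float = 271.0) -> float:
    """Median choice time relative to stimulus onset."""
    return stim_dur_ms + post_offset_ms


def counts_in_window(session: Session, start_ms: float, end_ms: float) -> np.ndarray:
    """Per-trial spike counts restricted to [start, end) ms."""
    out = np.empty(len(session.trials), dtype=float)
    for i, ts in enumerate(session.trials["spike_times_ms"]):
        if ts is None:
            raise ValueError("spike_times_ms required for windowed analysis")
        t = np.asarray(ts, dtype=float)
        out[i] = np.sum((t >= start_ms) & (t < end_ms))
    return out


def _windowed_session(session: Session, start: float, end: float) -> Session:
    trials = session.trials.copy()
    trials["spike_count"] = counts_in_window(session, start, end)
    trials["spike_times_ms"] = [None] * len(trials)
    return Session(
        neuron_id=session.neuron_id, area=session.area,
        monkey_id=session.monkey_id, trials=trials,
        stim_dur_ms=session.stim_dur_ms,
        preferred_sign_fixation=session.preferred_sign_fixation,
        extra=session.extra,
    )


@dataclass
class TimecourseResult:
    metric: str
    bin_centers_ms: list
    mean: list
    sem: list
    n: list
    anova_p: float
    first_significant_bin_ms: float | None
    per_neuron: np.ndarray = field(repr=False, default=None)


def _neuron_stat(session: Session, metric: str) -> float:
    try:
        if metric == "cp":
            return grand_cp(session).grand_cp
        if metric == "threshold":
            res = build_neurometric_curve(session)
            return res.comparison_threshold_deg
        pc = partial_correlations(session)
        return pc.spc2 if metric == "spc2" else pc.cpc2
    except (InclusionError, ValueError):
        return np.nan


def metric_timecourse(
    sessions: list[Session],
    metric: str,
    spec: WindowSpec | None = None,
) -> TimecourseResult:
    """Population time course of a per-neuron statistic.

    Recomputes the chosen statistic (grand CP, doubled neurometric
    threshold, squared slant/choice partial correlation) on counts
    restricted to each window; returns the per-bin population mean and
    SEM, a one-way ANOVA across bins, and (via Tukey multiple
    comparisons against the first bin) the earliest bin whose values
    differ from the initial bin.
    """
    if metric not in ("cp", "threshold", "spc2", "cpc2"):
        raise ValueError(f"unknown metric {metric!r}")
    for s in sessions:
        if s.task != "discrimination":
            raise ValueError("time-course metrics require discrimination sessions")
    spec = spec or WindowSpec()
    windows = make_windows(spec)
    centers = spec.centers()
    values = np.full((len(sessions), len(windows)), np.nan)
    for i, session in enumerate(sessions):
        for j, (start, end) in enumerate(windows):
            values[i, j] = _neuron_stat(_windowed_session(session, start, end), metric)
    finite = np.isfinite(values)
    return _summarize(metric, centers, values, finite)


def _summarize(metric, centers, values, finite) -> TimecourseResult:
    mean = np.array([values[finite[:, j], j].mean() if finite[:, j].any() else np.nan
                     for j in range(values.shape[1])])
    sem = np.array([
        stats.sem(values[finite[:, j], j]) if finite[:, j].sum() > 1 else np.nan
        for j in range(values.shape[1])
    ])
    n = finite.sum(axis=0)
    groups = [values[finite[:, j], j] for j in range(values.shape[1])
              if finite[:, j].sum() > 1]
    anova_p = float(stats.f_oneway(*groups).pvalue) if len(groups) > 1 else np.nan

    first_sig = None
    flat_vals, flat_bins = [], []
    for j in range(values.shape[1]):
        v = values[finite[:, j], j]
        flat_vals.append(v)
        flat_bins.append(np.full(len(v), j))
    flat_vals = np.concatenate(flat_vals)
    flat_bins = np.concatenate(flat_bins)
    if len(np.unique(flat_bins)) > 1 and np.ptp(flat_vals) > 0:
        tukey = pairwise_tukeyhsd(flat_vals, flat_bins)
        res = np.asarray(tukey._results_table.data[1:], dtype=object)
        for row in res:
            g1, g2, reject = int(row[0]), int(row[1]), bool(row[-1])
            if g1 == 0 and reject:
                first_sig = float(centers[g2])
                break
    return TimecourseResult(
        metric=metric,
        bin_centers_ms=[float(c) for c in centers],
        mean=[float(m) for m in mean],
        sem=[float(s) for s in sem],
        n=[int(x) for x in n],
        anova_p=anova_p,
        first_significant_bin_ms=first_sig,
        per_neuron=values,
    )


def compute_sdf(sessions: list[Session], spec: WindowSpec | None = None) -> TimecourseResult:
    """Spike density function: per-bin mean firing rate (Hz), averaged
    over trials within neuron and then over neurons — the population
    response on the same binning as the other time-course metrics."""
    spec = spec or WindowSpec()
    windows = make_windows(spec)
    centers = spec.centers()
    values = np.full((len(sessions), len(windows)), np.nan)
    for i, session in enumerate(sessions):
        for j, (start, end) in enumerate(windows):
            counts = counts_in_window(session, start, end)
            values[i, j] = counts.mean() / (spec.width_ms / 1000.0)
    finite = np.isfinite(values)
    return _summarize("sdf", centers, values, finite)
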