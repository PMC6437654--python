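"""Synthetic fixation and discrimination sessions.

The recordings behind this analysis were never deposited, so the
pipeline is exercised on simulated sessions that carry the statistical
structure the analyses assume: Bingham-shaped slant-tilt tuning, spike
counts with a selectable noise family (Poisson or rounded Gaussian with
a Fano factor), choices from a noisy observer with a cumulative-Gaussian
psychometric function, and a controllable neuron-choice coupling.

Coupling mechanism: the observer's decision variable for a trial of
signed slant s is

    d = (s - bias) / sigma_b + rho * eta + sqrt(1 - rho^2) * nu,

with eta, nu standard normal; the choice is top_far when d > 0 (lapses
flip it).  The same eta enters the neuron's standardized count
fluctuation with weight rho (signed by the neuron's slant-preference
sign), implemented as a Gaussian copula so the count marginal stays
exactly the configured noise model.  At rho = 0 counts are exactly
conditionally independent of choice given the stimulus; grand CP then
averages 0.5.

Defaults follow the study's stated world: 1000-ms stimulus window,
70/15/15 screen/near/far depth mixture, per-monkey slant ladders, a
behavioral threshold near 3.6 deg.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .datamodel import (
    CHOICE_NONE,
    CHOICE_TOP_FAR,
    CHOICE_TOP_NEAR,
    DEPTHS_CM,
    LADDER_NZ,
    Session,
    TrialRecord,
    fixation_conditions,
)
from .tuning import BinghamParams, surface_normal


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class ObserverConfig:
    """Noisy-observer model of the 2AFC slant judgement."""

    sensory_sigma_deg: float = 3.6
    bias_deg: float = 0.0
    lapse_rate: float = 0.01
    coupling_rho: float = 0.0
    slant_ladder_deg: tuple = LADDER_NZ
    depth_mixture: tuple = (0.15, 0.70, 0.15)  # near / screen / far
    coupling_onset_ms: float = 0.0
    coupling_gain: float = 0.3  # spike-time mode: rate modulation per SD of eta

    def validate(self) -> None:
        if self.sensory_sigma_deg <= 0:
            raise ConfigError("sensory_sigma_deg must be > 0")
        if not 0 <= self.lapse_rate < 0.5:
            raise ConfigError("lapse_rate must lie in [0, 0.5)")
        if not -1 <= self.coupling_rho <= 1:
            raise ConfigError("coupling_rho must lie in [-1, 1]")
        if abs(sum(self.depth_mixture) - 1.0) > 1e-9:
            raise ConfigError("depth_mixture must sum to 1")
        ladder = np.asarray(self.slant_ladder_deg, dtype=float)
        if not np.allclose(np.sort(ladder), np.sort(-ladder)):
            raise ConfigError("slant ladder must be symmetric about 0")


@dataclass
class GroundTruth:
    """Complete generative description of one synthetic neuron."""

    tuning: BinghamParams
    baseline_hz: float
    gain_hz: float
    noise_model: str = "poisson"
    fano_factor: float = 1.0
    observer: ObserverConfig = field(default_factory=ObserverConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_hz < 0 or self.gain_hz < 0:
            raise ConfigError("rates must be non-negative")
        if self.noise_model not in ("poisson", "gaussian"):
            raise ConfigError(f"unknown noise_model {self.noise_model!r}")
        if self.fano_factor <= 0:
            raise ConfigError("fano_factor must be > 0")
        self.observer.validate()

    # -- derived quantities ---------------------------------------------

    def rate_hz(self, slant_deg, tilt_deg) -> np.ndarray:
        return self.tuning.rate(slant_deg, tilt_deg)

    def rate_signed(self, signed_slant_deg) -> np.ndarray:
        """Firing rate along the discrimination axis: tilt 90 for
        negative slants, 270 for positive."""
        s = np.asarray(signed_slant_deg, dtype=float)
        tilt = np.where(s < 0, 90.0, 270.0)
        return self.rate_hz(np.abs(s), tilt)

    @property
    def preferred_sign(self) -> str:
        hi = float(self.rate_signed(20.0))
        lo = float(self.rate_signed(-20.0))
        return "positive" if hi >= lo else "negative"

    @property
    def preferred_slant_tilt(self) -> tuple[float, float]:
        return self.tuning.preferred_slant_tilt


@dataclass
class GroundTruthSpec:
    """Uniform sampling ranges for :func:`make_ground_truth`."""

    baseline_hz_range: tuple = (5.0, 15.0)
    gain_hz_range: tuple = (20.0, 50.0)
    lambda_range: tuple = (-8.0, -0.5)
    pref_slant_range: tuple = (0.0, 60.0)
    pref_tilt_range: tuple = (0.0, 360.0)
    noise_model: str = "poisson"
    fano_factor: float = 1.0
    observer: ObserverConfig = field(default_factory=ObserverConfig)

    def validate(self) -> None:
        for name in ("baseline_hz_range", "gain_hz_range", "lambda_range",
                     "pref_slant_range", "pref_tilt_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ConfigError(f"{name} is empty: ({lo}, {hi})")


def _basis_for_peak(peak: np.ndarray, phi: float) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (v1, v2) spanning the plane orthogonal to ``peak``,
    rotated in-plane by ``phi``."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(peak @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    a = np.cross(peak, helper)
    a /= np.linalg.norm(a)
    b = np.cross(peak, a)
    v1 = np.cos(phi) * a + np.sin(phi) * b
    v2 = -np.sin(phi) * a + np.cos(phi) * b
    return v1, v2


def make_ground_truth(spec: GroundTruthSpec, seed: int) -> GroundTruth:
    """Sample a reproducible :class:`GroundTruth` from a parameter spec."""
    spec.validate()
    rng = np.random.default_rng(seed)
    pref_s = rng.uniform(*spec.pref_slant_range)
    pref_t = rng.uniform(*spec.pref_tilt_range)
    peak = surface_normal(pref_s, pref_t)
    v1, v2 = _basis_for_peak(peak, rng.uniform(0, 2 * np.pi))
    lams = np.sort(rng.uniform(*spec.lambda_range, size=2))  # l1 <= l2 <= 0
    baseline = rng.uniform(*spec.baseline_hz_range)
    gain = rng.uniform(*spec.gain_hz_range)
    gt = GroundTruth(
        tuning=BinghamParams(
            amplitude=float(gain), baseline=float(baseline),
            lambda1=float(lams[0]), lambda2=float(lams[1]),
            v1=tuple(v1), v2=tuple(v2),
        ),
        baseline_hz=float(baseline),
        gain_hz=float(gain),
        noise_model=spec.noise_model,
        fano_factor=spec.fano_factor,
        observer=replace(spec.observer),
        seed=int(seed),
    )
    gt.validate()
    return gt


# ---------------------------------------------------------------------------
# count noise
# ---------------------------------------------------------------------------

def _draw_counts(gt: GroundTruth, mu: np.ndarray, z: np.ndarray | None,
                 rng: np.random.Generator) -> np.ndarray:
    """Counts with mean ``mu`` and the configured noise family.

    ``z`` (standard-normal per trial) is the standardized fluctuation;
    None draws it fresh.  Poisson counts use the Gaussian-copula
    inverse-CDF so the marginal stays exactly Poisson.
    """
    mu = np.asarray(mu, dtype=float)
    if z is None:
        z = rng.standard_normal(mu.shape)
    if gt.noise_model == "poisson":
        u = stats.norm.cdf(z)
        return stats.poisson.ppf(np.clip(u, 1e-15, 1 - 1e-15), mu).astype(int)
    sd = np.sqrt(gt.fano_factor * np.maximum(mu, 1e-12))
    return np.maximum(0, np.rint(mu + sd * z)).astype(int)


# ---------------------------------------------------------------------------
# fixation task
# ---------------------------------------------------------------------------

def simulate_fixation_session(
    gt: GroundTruth, n_reps: int = 3, seed: int | None = None,
    stim_dur_ms: float = 1000.0, neuron_id: str = "sim",
    area: str = "CIP", monkey_id: str = "S",
) -> Session:
    """One 25-condition tuning session: ``n_reps`` presentations of each
    slant-tilt combination in pseudo-random order."""
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    gt.validate()
    rng = np.random.default_rng(gt.seed if seed is None else seed)
    conds = fixation_conditions() * n_reps
    order = rng.permutation(len(conds))
    records = []
    for tid, idx in enumerate(order, start=1):
        s, t = conds[idx]
        mu = float(gt.rate_hz(s, t)) * stim_dur_ms / 1000.0
        count = int(_draw_counts(gt, np.array([mu]), None, rng)[0])
        records.append(TrialRecord(
            trial_id=tid, task="fixation", slant_deg=s, tilt_deg=t,
            depth_cm=0.0, choice=CHOICE_NONE, spike_count=count,
        ))
    session = Session(
        neuron_id=neuron_id, area=area, monkey_id=monkey_id,
        trials=records, stim_dur_ms=stim_dur_ms,
        preferred_sign_fixation=gt.preferred_sign,
        extra={"ground_truth": _gt_dict(gt)},
    )
    return session


# ---------------------------------------------------------------------------
# discrimination task
# ---------------------------------------------------------------------------

def simulate_discrimination_session(
    gt: GroundTruth, n_reps_per_slant: int = 40, seed: int | None = None,
    stim_dur_ms: float = 1000.0, include_spike_times: bool = False,
    neuron_id: str = "sim", area: str = "CIP", monkey_id: str = "S",
) -> Session:
    """One discrimination session of the noisy observer + coupled neuron.

    Each ladder slant is presented ``n_reps_per_slant`` times (shuffled);
    depth is drawn per trial from the configured mixture.  Correct-sign
    choices are rewarded; 0-deg trials are rewarded with probability 0.5.

    With ``include_spike_times`` the 1000-ms window is tiled with 50-ms
    subwindows of Poisson spiking whose rate after
    ``observer.coupling_onset_ms`` is modulated by the shared decision
    noise (gain ``1 + coupling_gain * rho * sign_pref * eta``); the
    recorded ``spike_count`` is then the number of spikes in the window.
    Without it, counts come from the copula draw described above.
    """
    if n_reps_per_slant < 1:
        raise ConfigError("n_reps_per_slant must be >= 1")
    gt.validate()
    obs = gt.observer
    rng = np.random.default_rng(gt.seed if seed is None else seed)

    ladder = np.asarray(obs.slant_ladder_deg, dtype=float)
    slants = np.repeat(ladder, n_reps_per_slant)
    rng.shuffle(slants)
    n = len(slants)
    depths = rng.choice([DEPTHS_CM[0], DEPTHS_CM[1], DEPTHS_CM[2]],
                        size=n, p=[obs.depth_mixture[0], obs.depth_mixture[1],
                                   obs.depth_mixture[2]])

    rho = obs.coupling_rho
    eta = rng.standard_normal(n)                # shared decision noise
    nu = rng.standard_normal(n)                 # observer-private noise
    d = (slants - obs.bias_deg) / obs.sensory_sigma_deg \
        + rho * eta + np.sqrt(1 - rho ** 2) * nu
    top_far = d > 0
    lapse = rng.random(n) < obs.lapse_rate
    top_far = np.where(lapse, ~top_far, top_far)
    choices = np.where(top_far, CHOICE_TOP_FAR, CHOICE_TOP_NEAR)

    rewarded = np.where(
        slants == 0.0, rng.random(n) < 0.5,
        (slants > 0) == top_far,
    )

    sign_pref = 1.0 if gt.preferred_sign == "positive" else -1.0
    mu = gt.rate_signed(slants) * stim_dur_ms / 1000.0

    spike_times: list[tuple[float, ...] | None]
    if include_spike_times:
        counts, spike_times = _simulate_trains(
            gt, mu, eta, sign_pref, stim_dur_ms, rng
        )
    else:
        eps = rng.standard_normal(n)            # neuron-private noise
        z = sign_pref * (rho * eta + np.sqrt(1 - rho ** 2) * eps)
        counts = _draw_counts(gt, mu, z, rng)
        spike_times = [None] * n

    records = [
        TrialRecord(
            trial_id=i + 1, task="discrimination",
            slant_deg=float(slants[i]), tilt_deg=np.nan,
            depth_cm=float(depths[i]), choice=str(choices[i]),
            spike_count=int(counts[i]), spike_times_ms=spike_times[i],
        )
        for i in range(n)
    ]
    return Session(
        neuron_id=neuron_id, area=area, monkey_id=monkey_id,
        trials=records, stim_dur_ms=stim_dur_ms,
        preferred_sign_fixation=gt.preferred_sign,
        extra={"ground_truth": _gt_dict(gt),
               "rewarded": [bool(r) for r in rewarded]},
    )


def _simulate_trains(gt, mu, eta, sign_pref, stim_dur_ms, rng,
                     bin_ms: float = 50.0):
    """Poisson spike trains with trial-shared rate modulation after the
    coupling onset; returns (counts, spike-time tuples)."""
    obs = gt.observer
    n = len(mu)
    edges = np.arange(0.0, stim_dur_ms + bin_ms / 2, bin_ms)
    n_bins = len(edges) - 1
    gain = np.maximum(0.0, 1.0 + obs.coupling_gain * obs.coupling_rho
                      * sign_pref * eta)
    counts = np.zeros(n, dtype=int)
    times: list[tuple[float, ...]] = []
    for i in range(n):
        mu_bin = mu[i] / n_bins
        per_bin = np.empty(n_bins, dtype=int)
        for b in range(n_bins):
            coupled = edges[b] + bin_ms / 2 >= obs.coupling_onset_ms
            lam = mu_bin * (gain[i] if coupled else 1.0)
            per_bin[b] = rng.poisson(lam)
        t = np.concatenate([
            np.sort(edges[b] + rng.random(per_bin[b]) * bin_ms)
            for b in range(n_bins)
        ]) if per_bin.sum() else np.empty(0)
        counts[i] = per_bin.sum()
        times.append(tuple(float(x) for x in t))
    return counts, times


# ---------------------------------------------------------------------------
# eye covariates
# ---------------------------------------------------------------------------

@dataclass
class EyeEffectSizes:
    """Injected structure of trial-mean eye covariates.

    ``choice_shift``: additive shift of the covariate with choice sign
    (confound route); ``count_beta``: spikes added per covariate unit
    (direct route).  Zeroes give covariates independent of everything.
    """

    choice_shift: float = 0.0
    count_beta: float = 0.0
    noise_sd: float = 1.0


def simulate_eye_covariates(
    session: Session,
    effect_sizes: dict[str, EyeEffectSizes] | None = None,
    seed: int = 0,
) -> Session:
    """Return a copy of ``session`` with trial-mean eye covariates added.

    ``effect_sizes`` maps covariate column (eye_vpos_deg,
    eye_vvel_deg_s, vergence_deg) to its injected structure; missing
    covariates get independent unit-normal values.  When a covariate is
    injected into the spike counts, spike times (if any) are dropped to
    keep the count/times invariant.  The injected ground truth is
    recorded in ``session.extra['eye_effects']``.
    """
    if len(session.trials) == 0:
        raise ValueError("session has no trials")
    rng = np.random.default_rng(seed)
    effect_sizes = effect_sizes or {}
    trials = session.trials.copy()
    n = len(trials)
    csign = np.where(trials["choice"] == CHOICE_TOP_FAR, 1.0,
                     np.where(trials["choice"] == CHOICE_TOP_NEAR, -1.0, 0.0))
    recorded = {}
    counts = trials["spike_count"].to_numpy(dtype=float)
    any_beta = False
    for col in ("eye_vpos_deg", "eye_vvel_deg_s", "vergence_deg"):
        eff = effect_sizes.get(col, EyeEffectSizes())
        x = rng.standard_normal(n) * eff.noise_sd + eff.choice_shift * csign
        trials[col] = x
        if eff.count_beta != 0.0:
            counts = counts + eff.count_beta * x
            any_beta = True
        recorded[col] = dataclasses.asdict(eff)
    if any_beta:
        trials["spike_count"] = np.maximum(0, np.rint(counts)).astype(int)
        trials["spike_times_ms"] = [None] * n
    extra = dict(session.extra)
    extra["eye_effects"] = {"seed": int(seed), "effects": recorded}
    return Session(
        neuron_id=session.neuron_id, area=session.area,
        monkey_id=session.monkey_id, trials=trials,
        stim_dur_ms=session.stim_dur_ms,
        preferred_sign_fixation=session.preferred_sign_fixation,
        extra=extra,
    )


def _gt_dict(gt: GroundTruth) -> dict:
    d = dataclasses.asdict(gt)
    return d


def simulate_population(
    n_neurons: int,
    spec: GroundTruthSpec | None = None,
    n_reps_per_slant: int = 40,
    seed: int = 0,
    include_spike_times: bool = False,
    area: str = "CIP",
) -> list[Session]:
    """Simulate ``n_neurons`` discrimination sessions with ground truths
    drawn from ``spec``; neuron i uses child seed ``seed * 10**6 + i``
    kept below 2**31."""
    spec = spec or GroundTruthSpec()
    sessions = []
    for i in range(n_neurons):
        child = (seed * 1_000_003 + i) % (2 ** 31 - 1)
        gt = make_ground_truth(spec, seed=child)
        sessions.append(simulate_discrimination_session(
            gt, n_reps_per_slant=n_reps_per_slant, seed=child + 7,
            include_spike_times=include_spike_times,
            neuron_id=f"{area.lower()}_{i:03d}", area=area,
        ))
    return sessions
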