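import numpy as np
import pytest

from slantchoice.datamodel import (
    CHOICE_NONE,
    CHOICE_TOP_FAR,
    CHOICE_TOP_NEAR,
    Session,
    TrialRecord,
    fixation_conditions,
)
from slantchoice.synth import (
    GroundTruthSpec,
    ObserverConfig,
    make_ground_truth,
    simulate_discrimination_session,
    simulate_fixation_session,
)


def make_fixation_session(rate_fn, n_reps=3, noise_sd=0.0, seed=0, **meta):
    """Deterministic (or jittered) 25-condition fixation session with
    counts given by ``rate_fn(slant, tilt)``."""
    rng = np.random.default_rng(seed)
    records, tid = [], 0
    for _ in range(n_reps):
        for s, t in fixation_conditions():
            tid += 1
            mu = rate_fn(s, t)
            count = max(0, int(round(mu + noise_sd * rng.standard_normal())))
            records.append(TrialRecord(
                trial_id=tid, task="fixation", slant_deg=s, tilt_deg=t,
                choice=CHOICE_NONE, spike_count=count,
            ))
    meta.setdefault("neuron_id", "fix")
    meta.setdefault("area", "CIP")
    meta.setdefault("monkey_id", "N")
    return Session(trials=records, **meta)


def make_discrimination_session(groups, preferred_sign="positive", **meta):
    """Discrimination session from {slant: (pref_counts, nonpref_counts)}
    where 'pref' means choices toward ``preferred_sign``."""
    pref_choice = CHOICE_TOP_FAR if preferred_sign == "positive" else CHOICE_TOP_NEAR
    nonpref_choice = CHOICE_TOP_NEAR if preferred_sign == "positive" else CHOICE_TOP_FAR
    records, tid = [], 0
    for s, (pref, nonpref) in groups.items():
        for c in pref:
            tid += 1
            records.append(TrialRecord(
                trial_id=tid, task="discrimination", slant_deg=float(s),
                choice=pref_choice, spike_count=int(c),
            ))
        for c in nonpref:
            tid += 1
            records.append(TrialRecord(
                trial_id=tid, task="discrimination", slant_deg=float(s),
                choice=nonpref_choice, spike_count=int(c),
            ))
    meta.setdefault("neuron_id", "disc")
    meta.setdefault("area", "CIP")
    meta.setdefault("monkey_id", "N")
    return Session(trials=records, preferred_sign_fixation=preferred_sign, **meta)


@pytest.fixture(scope="session")
def default_gt():
    return make_ground_truth(GroundTruthSpec(), seed=11)


@pytest.fixture(scope="session")
def sim_fixation(default_gt):
    return simulate_fixation_session(default_gt, n_reps=5, seed=21)


@pytest.fixture(scope="session")
def sim_discrimination(default_gt):
    return simulate_discrimination_session(default_gt, n_reps_per_slant=40, seed=31)


@pytest.fixture(scope="session")
def coupled_session():
    gt = make_ground_truth(
        GroundTruthSpec(observer=ObserverConfig(coupling_rho=0.6)), seed=41
    )
    return simulate_discrimination_session(gt, n_reps_per_slant=40, seed=42)
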