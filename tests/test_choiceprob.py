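"""Choice probability: zero-slant CP, balanced z-scoring, grand CP,
permutation test, and the population CP-vs-threshold analysis."""

import numpy as np
import pandas as pd
import pytest

from slantchoice.choiceprob import (
    InclusionError,
    balanced_zscore,
    cp_vs_threshold,
    cp_zero_slant,
    grand_cp,
    permutation_test_cp,
)
from slantchoice.neurometric import roc_auc

from conftest import make_discrimination_session


def brute_force_auc(a, b):
    """Exhaustive pair-count oracle: P(b > a) + 0.5 P(b == a)."""
    wins = ties = 0
    for x in a:
        for y in b:
            wins += y > x
            ties += y == x
    return (wins + 0.5 * ties) / (len(a) * len(b))


# ---------------------------------------------------------------------------
# CP at the ambiguous slant
# ---------------------------------------------------------------------------

def test_cp_zero_identical_distributions():
    session = make_discrimination_session({0: ([3, 5, 4], [3, 5, 4])})
    assert cp_zero_slant(session) == 0.5


def test_cp_zero_perfect_separation():
    session = make_discrimination_session({0: ([10] * 5, [0] * 5)})
    assert cp_zero_slant(session) == 1.0


def test_cp_zero_hand_table_matches_brute_force():
    pref, nonpref = [3, 5, 4, 6], [2, 4, 3, 5]
    session = make_discrimination_session({0: (pref, nonpref)})
    assert cp_zero_slant(session) == pytest.approx(
        brute_force_auc(nonpref, pref), abs=1e-12
    )


def test_cp_zero_missing_choice_group_is_none():
    session = make_discrimination_session({0: ([3, 5, 4], [])})
    assert cp_zero_slant(session) is None


# ---------------------------------------------------------------------------
# balanced z-score
# ---------------------------------------------------------------------------

def test_balanced_equals_plain_zscore_when_choices_balanced():
    pref = np.array([2.0, 4.0, 6.0])
    nonpref = np.array([1.0, 3.0, 8.0])
    zp, zn = balanced_zscore(pref, nonpref)
    pooled = np.concatenate([pref, nonpref])
    expected = (pooled - pooled.mean()) / pooled.std(ddof=0)
    assert np.allclose(np.concatenate([zp, zn]), expected, atol=1e-12)


def test_balanced_zscore_hand_arithmetic():
    # 4 preferred: 2,4,6,8 ; 2 nonpreferred: 1,3
    # center = (5 + 2)/2 = 3.5
    # msd_pref  = (2.25 + 0.25 + 6.25 + 20.25)/4 = 7.25
    # msd_nonpref = (6.25 + 0.25)/2 = 3.25
    # scale = sqrt(0.5*(7.25 + 3.25)) = sqrt(5.25)
    zp, zn = balanced_zscore([2, 4, 6, 8], [1, 3])
    scale = np.sqrt(5.25)
    assert np.allclose(zp, (np.array([2, 4, 6, 8]) - 3.5) / scale, atol=1e-12)
    assert np.allclose(zn, (np.array([1, 3]) - 3.5) / scale, atol=1e-12)


def test_balanced_zscore_affine_invariance():
    pref, nonpref = np.array([2.0, 4.0, 6.0, 8.0]), np.array([1.0, 3.0, 7.0])
    z1 = balanced_zscore(pref, nonpref)
    z2 = balanced_zscore(3.0 * pref + 11.0, 3.0 * nonpref + 11.0)
    assert np.allclose(z1[0], z2[0], atol=1e-12)
    assert np.allclose(z1[1], z2[1], atol=1e-12)


def test_balanced_zscore_zero_sd_rejected():
    with pytest.raises(ZeroDivisionError):
        balanced_zscore([5.0, 5.0], [5.0, 5.0])


# ---------------------------------------------------------------------------
# grand CP
# ---------------------------------------------------------------------------

def test_grand_cp_hand_session_matches_brute_force():
    groups = {
        0: ([3, 5, 4], [2, 4, 3]),
        5: ([8, 9, 11], [7, 8, 10]),
    }
    session = make_discrimination_session(groups)
    res = grand_cp(session)
    z_pref, z_nonpref = [], []
    for s, (p, n) in groups.items():
        zp, zn = balanced_zscore(np.array(p, float), np.array(n, float))
        z_pref.extend(zp)
        z_nonpref.extend(zn)
    assert res.grand_cp == pytest.approx(
        brute_force_auc(z_nonpref, z_pref), abs=1e-12
    )
    assert set(res.included_slants) == {0.0, 5.0}


def test_grand_cp_single_balanced_slant_equals_raw_cp():
    pref, nonpref = [3, 6, 9, 12], [2, 5, 8, 11]
    session = make_discrimination_session({0: (pref, nonpref)})
    res = grand_cp(session)
    assert res.grand_cp == pytest.approx(roc_auc(nonpref, pref), abs=1e-12)


def test_grand_cp_inclusion_rule():
    session = make_discrimination_session({
        0: ([3, 5, 4, 6], [2, 4, 3]),     # included: 4 and 3 choices
        10: ([8, 9, 10, 11], [7, 9]),     # excluded: only 2 nonpreferred
    })
    res = grand_cp(session)
    assert set(res.included_slants) == {0.0}
    assert res.excluded_slants == [10.0]
    with pytest.raises(InclusionError):
        grand_cp(make_discrimination_session({0: ([1, 2], [3, 2])}))


def test_grand_cp_invariant_to_per_slant_affine_transform(sim_discrimination):
    res1 = grand_cp(sim_discrimination)
    scaled = sim_discrimination.trials.copy()
    for i, s in enumerate(np.unique(scaled["slant_deg"])):
        mask = scaled["slant_deg"] == s
        scaled.loc[mask, "spike_count"] = (2.0 + i) * scaled.loc[mask, "spike_count"] + 7 * i
    from slantchoice.datamodel import Session
    session2 = Session(
        sim_discrimination.neuron_id, sim_discrimination.area,
        sim_discrimination.monkey_id, scaled,
        preferred_sign_fixation=sim_discrimination.preferred_sign_fixation,
    )
    assert grand_cp(session2).grand_cp == pytest.approx(res1.grand_cp, abs=1e-12)


def test_cp_flips_under_preference_sign_inversion(coupled_session):
    res = grand_cp(coupled_session)
    flipped = coupled_session
    sign = flipped.preferred_sign_fixation
    flipped.preferred_sign_fixation = "negative" if sign == "positive" else "positive"
    res_flip = grand_cp(flipped)
    flipped.preferred_sign_fixation = sign
    assert res_flip.grand_cp == pytest.approx(1.0 - res.grand_cp, abs=1e-12)
    assert res_flip.cp_zero == pytest.approx(1.0 - res.cp_zero, abs=1e-12)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def test_permutation_mean_near_half_and_deterministic(sim_discrimination):
    r1 = permutation_test_cp(sim_discrimination, n_perm=500, seed=3)
    r2 = permutation_test_cp(sim_discrimination, n_perm=500, seed=3)
    assert r1.p_perm == r2.p_perm
    assert 0 < r1.p_perm <= 1


def test_choice_locked_neuron_hits_smoothed_floor():
    rng = np.random.default_rng(4)
    groups = {
        s: (list(100 + rng.integers(0, 5, 10)), list(rng.integers(0, 5, 10)))
        for s in (-5, 0, 5, 10)
    }
    session = make_discrimination_session(groups)
    res = permutation_test_cp(session, n_perm=1000, seed=5)
    assert res.grand_cp == 1.0
    assert res.p_perm <= 0.002  # floor 1/1001 with add-one smoothing


def test_permutation_requires_positive_n(sim_discrimination):
    with pytest.raises(ValueError):
        permutation_test_cp(sim_discrimination, n_perm=0)


def test_permuted_grand_cp_centered_on_half():
    # under within-slant label shuffling the permuted CP distribution is
    # centered on chance
    rng = np.random.default_rng(6)
    groups = {s: (list(rng.poisson(20, 12)), list(rng.poisson(20, 12)))
              for s in (-5, 0, 5)}
    session = make_discrimination_session(groups)
    from slantchoice.choiceprob import _auc_rows, _balanced_z_matrix, _choice_groups
    gs = _choice_groups(session)
    cps = []
    for s, (pref, nonpref) in gs.items():
        x = np.concatenate([pref, nonpref])
        base = np.zeros(len(x), bool)
        base[:len(pref)] = True
        keys = rng.random((2000, len(x)))
        labels = base[np.argsort(keys, axis=1)]
        z = _balanced_z_matrix(x, labels)
        cps.append((z, labels))
    z = np.concatenate([c[0] for c in cps], axis=1)
    labels = np.concatenate([c[1] for c in cps], axis=1)
    perm_cp = _auc_rows(z, labels)
    assert abs(np.nanmean(perm_cp) - 0.5) < 0.01


# ---------------------------------------------------------------------------
# population CP vs threshold
# ---------------------------------------------------------------------------

def _population(rng, n, area, slope):
    thr = rng.uniform(5, 60, n)
    cp = 0.5 + slope * (30 - thr) / 100 + rng.normal(0, 0.02, n)
    return pd.DataFrame({
        "area": area, "grand_cp": cp, "comparison_threshold_deg": thr,
    })


def test_cp_vs_threshold_recovers_constructed_effect():
    rng = np.random.default_rng(7)
    pop = pd.concat([
        _population(rng, 40, "CIP", slope=0.5),   # sensitive neurons carry CP
        _population(rng, 40, "V3A", slope=0.0),
    ], ignore_index=True)
    res = cp_vs_threshold(pop)
    assert res.per_area["CIP"]["r"] < -0.5
    assert abs(res.per_area["V3A"]["r"]) < 0.35
    assert res.interaction_p < 0.01


def test_cp_vs_threshold_duplicated_population_no_interaction():
    rng = np.random.default_rng(8)
    base = _population(rng, 40, "CIP", slope=0.5)
    dup = base.copy()
    dup["area"] = "V3A"
    res = cp_vs_threshold(pd.concat([base, dup], ignore_index=True))
    assert res.interaction_p > 0.95  # identical slopes


def test_cp_vs_threshold_degenerate_thresholds_rejected():
    pop = pd.DataFrame({
        "area": ["CIP"] * 6, "grand_cp": np.linspace(0.4, 0.6, 6),
        "comparison_threshold_deg": [20.0] * 6,
    })
    with pytest.raises(ValueError, match="constant"):
        cp_vs_threshold(pop)
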