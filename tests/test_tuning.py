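"""SODI, condition ANOVA, Bingham fit, classification, equal-area
projection, and preference-uniformity testing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from slantchoice.tuning import (
    BinghamParams,
    BinghamTuning,
    analyze_tuning,
    classify_tuning,
    compute_sodi,
    condition_anova,
    fit_bingham_tuning,
    preference_uniformity_test,
    project_equal_area,
    surface_normal,
    unproject_equal_area,
)

from conftest import make_fixation_session


# ---------------------------------------------------------------------------
# SODI
# ---------------------------------------------------------------------------

def brute_force_sodi(groups):
    """Independent direct evaluation of the modulation-index formula."""
    means = [np.mean(g) for g in groups.values()]
    r_max, r_min = max(means), min(means)
    sse = sum(sum((x - np.mean(g)) ** 2 for x in g) for g in groups.values())
    n = sum(len(g) for g in groups.values())
    m = len(groups)
    return (r_max - r_min) / (r_max - r_min + 2 * np.sqrt(sse / (n - m)))


def test_sodi_hand_example_matches_brute_force():
    groups = {
        "a": np.array([10.0, 12.0, 11.0, 13.0]),
        "b": np.array([20.0, 22.0, 21.0, 21.0]),
        "c": np.array([5.0, 6.0, 5.0, 4.0]),
    }
    assert compute_sodi(groups) == pytest.approx(brute_force_sodi(groups), abs=1e-12)


def test_sodi_is_one_for_zero_within_condition_variance():
    groups = {i: np.full(3, 10.0 + i) for i in range(25)}
    assert compute_sodi(groups) == 1.0


def test_sodi_is_zero_for_flat_means():
    groups = {i: np.array([5.0, 7.0]) for i in range(5)}  # identical means
    assert compute_sodi(groups) == 0.0


def test_sodi_invariant_to_common_mean_shift():
    rng = np.random.default_rng(0)
    groups = {i: rng.poisson(10 + 3 * i, size=5).astype(float) for i in range(6)}
    shifted = {i: g + 42.0 for i, g in groups.items()}
    assert compute_sodi(shifted) == pytest.approx(compute_sodi(groups), abs=1e-12)


def test_sodi_undefined_variance_term_rejected():
    # 4 trials spread over a 25-condition protocol with within-condition
    # variance: the pooled-variance denominator N - M is non-positive
    with pytest.raises(ValueError, match="N.*M"):
        compute_sodi({0: np.array([1.0, 2.0]), 1: np.array([3.0, 5.0])},
                     m_conditions=25)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def test_condition_anova_separation():
    rng = np.random.default_rng(1)
    groups = {i: 50.0 * i + 0.01 * rng.standard_normal(4) for i in range(5)}
    assert condition_anova(groups) < 1e-6


def test_condition_anova_requires_two_trials_each():
    with pytest.raises(ValueError):
        condition_anova({0: np.array([1.0]), 1: np.array([2.0, 3.0])})


def test_condition_anova_type_I_rate():
    # identical distributions: p < 0.05 in about 5% of simulated neurons
    rng = np.random.default_rng(2)
    hits = 0
    n_sim = 400
    for _ in range(n_sim):
        groups = {i: rng.poisson(15, 3).astype(float) for i in range(25)}
        if condition_anova(groups) < 0.05:
            hits += 1
    rate = hits / n_sim
    assert 0.02 < rate < 0.09  # ~3 binomial SDs around 0.05


# ---------------------------------------------------------------------------
# Bingham fit
# ---------------------------------------------------------------------------

def _grid():
    from slantchoice.datamodel import fixation_conditions
    return np.array(fixation_conditions())


def test_bingham_noiseless_recovery():
    true = BinghamParams(
        amplitude=30.0, baseline=8.0, lambda1=-5.0, lambda2=-2.0,
        v1=(1.0, 0.0, 0.0), v2=(0.0, 1.0, 0.0),  # peak at the pole
    )
    X = _grid()
    y = true.rate(X[:, 0], X[:, 1])
    est = BinghamTuning().fit(X, y)
    assert est.r_ == pytest.approx(1.0, abs=1e-6)
    # recovered peak within 1 degree of the true peak direction
    n_true = true.peak_normal
    n_fit = est.params_.peak_normal
    angle = np.degrees(np.arccos(np.clip(abs(n_true @ n_fit), -1, 1)))
    assert angle < 1.0


def test_bingham_noiseless_recovery_off_pole():
    peak = surface_normal(40.0, 135.0)
    # orthonormal complement of the peak
    a = np.cross(peak, [0.0, 0.0, 1.0]); a /= np.linalg.norm(a)
    b = np.cross(peak, a)
    true = BinghamParams(25.0, 5.0, -6.0, -3.0, tuple(a), tuple(b))
    X = _grid()
    est = BinghamTuning().fit(X, true.rate(X[:, 0], X[:, 1]))
    assert est.r_ > 0.999
    angle = np.degrees(np.arccos(np.clip(abs(true.peak_normal @ est.params_.peak_normal), -1, 1)))
    assert angle < 1.0


def test_bingham_flat_means_untuned():
    X = _grid()
    params, r = fit_bingham_tuning({tuple(x): 12.0 for x in X})
    assert r == -np.inf
    assert classify_tuning(0.01, r) != "tuned"


def test_bingham_two_peaked_profile_underfits():
    # two bumps at different slants on opposite tilts: breaks the
    # antipodal symmetry of the quadratic-form family, so the fit r
    # stays < 0.8 (verified numerically; symmetric bump pairs CAN be
    # captured by girdle-shaped fits and are not a valid probe)
    X = _grid()
    n = surface_normal(X[:, 0], X[:, 1])
    p1 = surface_normal(20.0, 0.0)
    p2 = surface_normal(60.0, 180.0)
    y = 30 * np.exp(-12 * (1 - (n @ p1) ** 2)) \
        + 30 * np.exp(-12 * (1 - (n @ p2) ** 2)) + 5
    est = BinghamTuning().fit(X, y)
    assert est.r_ < 0.8


@pytest.mark.parametrize("p, r, expected", [
    (0.01, 0.95, "tuned"),
    (0.01, 0.6, "untuned_multipeak"),
    (0.5, 0.99, "untuned"),
    (0.5, 0.5, "untuned"),
    (0.049, 0.8, "tuned"),     # gate boundaries: p < 0.05, r >= 0.8
    (0.05, 0.99, "untuned"),
    (0.01, 0.799, "untuned_multipeak"),
])
def test_classify_tuning_threshold_grid(p, r, expected):
    assert classify_tuning(p, r) == expected


def test_analyze_tuning_on_synthetic(sim_fixation, default_gt):
    res = analyze_tuning(sim_fixation)
    assert res.m_conditions == 25
    assert 0 <= res.sodi <= 1
    assert res.tuned
    true_s, true_t = default_gt.preferred_slant_tilt
    n_true = surface_normal(true_s, true_t)
    n_fit = surface_normal(res.preferred_slant_deg, res.preferred_tilt_deg)
    angle = np.degrees(np.arccos(np.clip(abs(n_true @ n_fit), -1, 1)))
    assert angle < 15.0  # Poisson noise at 5 reps


# ---------------------------------------------------------------------------
# equal-area projection
# ---------------------------------------------------------------------------

def test_projection_pole_and_closed_form():
    assert project_equal_area(0.0, 123.0) == (0.0, 0.0)
    x, y = project_equal_area(60.0, 90.0)
    assert x == pytest.approx(0.0, abs=1e-12)
    assert y == pytest.approx(1.0, abs=1e-12)  # 2 sin(30 deg) = 1


def test_projection_rejects_out_of_range():
    with pytest.raises(ValueError):
        project_equal_area(91.0, 0.0)
    with pytest.raises(ValueError):
        project_equal_area(-1.0, 0.0)


@settings(max_examples=50, deadline=None)
@given(
    s=st.floats(0.5, 89.5),
    t=st.floats(0.0, 359.9),
)
def test_projection_inverts(s, t):
    x, y = project_equal_area(s, t)
    s2, t2 = unproject_equal_area(x, y)
    assert abs(s2 - s) < 1e-9
    assert min(abs(t2 - t), 360 - abs(t2 - t)) < 1e-9


def test_projection_area_preserving():
    # Monte-Carlo: uniform directions on the cap project to uniform
    # density in the disc; planar cap areas match spherical cap areas.
    rng = np.random.default_rng(3)
    z = rng.uniform(0, 1, 200_000)          # uniform on hemisphere: z ~ U
    slant = np.degrees(np.arccos(z))
    tilt = rng.uniform(0, 360, z.size)
    x, y = project_equal_area(slant, tilt)
    rho2 = x ** 2 + y ** 2
    # fraction inside projected radius of a 45-deg cap == cap-area fraction
    for cap in (30.0, 45.0, 60.0):
        r_cap = 2 * np.sin(np.deg2rad(cap) / 2)
        frac = np.mean(rho2 <= r_cap ** 2)
        expected = 1 - np.cos(np.deg2rad(cap))  # hemisphere area fraction
        assert abs(frac - expected) / expected < 0.005 + 3 / np.sqrt(z.size)


# ---------------------------------------------------------------------------
# preference uniformity
# ---------------------------------------------------------------------------

def test_uniformity_identical_preferences_rejected():
    chi2, p = preference_uniformity_test([30.0] * 200, [90.0] * 200)
    assert p < 1e-10


def test_uniformity_calibrated_on_uniform_sample():
    rng = np.random.default_rng(4)
    pvals = []
    for _ in range(150):
        z = rng.uniform(0, 1, 500)
        slant = np.degrees(np.arccos(z))
        tilt = rng.uniform(0, 360, 500)
        pvals.append(preference_uniformity_test(slant, tilt)[1])
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_uniformity_power_against_low_slant_bias():
    rng = np.random.default_rng(5)
    rejections = 0
    for _ in range(20):
        slant = rng.uniform(0, 25, 200)   # biased toward small slants
        tilt = rng.uniform(0, 360, 200)
        if preference_uniformity_test(slant, tilt)[1] < 0.05:
            rejections += 1
    assert rejections >= 18


def test_uniformity_needs_enough_points():
    with pytest.raises(ValueError):
        preference_uniformity_test([10.0] * 10, [0.0] * 10)
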