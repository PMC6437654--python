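"""3D slant-tilt tuning quantification from fixation sessions.

Tuning strength is summarised by the surface orientation discrimination
index (SODI),

    SODI = (R_max - R_min) / (R_max - R_min + 2*sqrt(SSE / (N - M))),

where R_max and R_min are the largest and smallest of the M = 25
condition mean responses, SSE is the summed squared error of individual
trials around their condition means, and N is the total trial count.
SODI is near 1 for strong modulation relative to trial-to-trial
variability and near 0 for weak modulation.

A neuron is classified *tuned* by a two-step gate: a one-way ANOVA
across the 25 conditions (p < 0.05) followed by a Bingham-function fit
whose Pearson correlation with the observed means must be >= 0.8; the
second step rejects multi-peaked profiles that pass an ANOVA but are
not selective for a unique surface orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .datamodel import Session, TASK_FIXATION

BINGHAM_R_GATE = 0.8
ANOVA_ALPHA = 0.05

#: sentinel for a Bingham fit that failed every restart
R_FAILED = -np.inf


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def surface_normal(slant_deg, tilt_deg):
    """Unit surface normal n = (sin s cos t, sin s sin t, cos s)."""
    s = np.deg2rad(np.asarray(slant_deg, dtype=float))
    t = np.deg2rad(np.asarray(tilt_deg, dtype=float))
    return np.stack([np.sin(s) * np.cos(t), np.sin(s) * np.sin(t), np.cos(s)], axis=-1)


def normal_to_slant_tilt(n):
    """Inverse of :func:`surface_normal` onto the z >= 0 hemisphere."""
    n = np.asarray(n, dtype=float)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    slant = np.degrees(np.arccos(np.clip(n[..., 2], -1.0, 1.0)))
    tilt = np.degrees(np.arctan2(n[..., 1], n[..., 0])) % 360.0
    return slant, tilt


def project_equal_area(slant_deg, tilt_deg):
    """Lambert azimuthal equal-area projection about the frontoparallel pole.

    Radius rho = 2 sin(s/2), azimuth = tilt; returns (x, y).  Area on the
    unit hemisphere is preserved per steradian; the pole (slant 0) maps
    to the origin.
    """
    s = np.asarray(slant_deg, dtype=float)
    if np.any((s < 0) | (s > 90)):
        raise ValueError("slant must lie in [0, 90] degrees")
    t = np.deg2rad(np.asarray(tilt_deg, dtype=float))
    rho = 2.0 * np.sin(np.deg2rad(s) / 2.0)
    return rho * np.cos(t), rho * np.sin(t)


def unproject_equal_area(x, y):
    """Numerical inverse of :func:`project_equal_area`."""
    rho = np.hypot(x, y)
    slant = 2.0 * np.degrees(np.arcsin(np.clip(rho / 2.0, 0.0, 1.0)))
    tilt = np.degrees(np.arctan2(y, x)) % 360.0
    return slant, tilt


# ---------------------------------------------------------------------------
# condition grouping
# ---------------------------------------------------------------------------

def condition_groups(session: Session) -> dict[tuple[float, float], np.ndarray]:
    """Group fixation-trial spike counts by (slant, tilt) condition.

    All slant-0 trials collapse into the single frontoparallel condition
    (0, 0) since tilt is undefined there.
    """
    t = session.trials[session.trials["task"] == TASK_FIXATION]
    groups: dict[tuple[float, float], list[float]] = {}
    for row in t.itertuples(index=False):
        s = float(row.slant_deg)
        key = (0.0, 0.0) if s == 0.0 else (s, float(row.tilt_deg))
        groups.setdefault(key, []).append(float(row.spike_count))
    return {k: np.asarray(v) for k, v in groups.items()}


def compute_sodi(
    groups: dict[tuple[float, float], np.ndarray] | Session,
    m_conditions: int | None = None,
) -> float:
    """Surface orientation discrimination index from grouped responses.

    ``m_conditions`` is the number of *tested* stimulus combinations
    (M = 25 for the full protocol); it defaults to the number of
    conditions observed with at least one trial.
    """
    if isinstance(groups, Session):
        groups = condition_groups(groups)
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v)}
    if len(groups) < 2:
        raise ValueError("SODI needs >= 2 non-empty conditions")
    means = np.array([g.mean() for g in groups.values()])
    r_max, r_min = means.max(), means.min()
    sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups.values())
    n = sum(len(g) for g in groups.values())
    m = len(groups) if m_conditions is None else m_conditions
    if sse > 0 and n <= m:
        raise ValueError(f"variance term undefined: N={n} <= M={m} with SSE > 0")
    noise = 2.0 * np.sqrt(sse / (n - m)) if sse > 0 else 0.0
    denom = (r_max - r_min) + noise
    return float((r_max - r_min) / denom) if denom > 0 else 0.0


def condition_anova(groups: dict | Session) -> float:
    """One-way fixed-effects ANOVA p across the slant-tilt conditions."""
    if isinstance(groups, Session):
        groups = condition_groups(groups)
    samples = [np.asarray(g, dtype=float) for g in groups.values()]
    if len(samples) < 2:
        raise ValueError("ANOVA needs >= 2 conditions")
    if any(len(g) < 2 for g in samples):
        raise ValueError("ANOVA needs >= 2 trials per condition")
    return float(stats.f_oneway(*samples).pvalue)


def slant_axis_anova(session: Session) -> float:
    """ANOVA p for slant tuning along the 90/270-deg tilt axis
    (the axis along which the discrimination task is performed)."""
    groups = condition_groups(session)
    axis = {
        k: v for k, v in groups.items()
        if k[0] == 0.0 or k[1] in (90.0, 270.0)
    }
    return condition_anova(axis)


def preferred_sign_from_fixation(session: Session) -> str:
    """Slant-preference sign along the 90/270 axis (tilt 270 => positive)."""
    groups = condition_groups(session)
    pos = [v.mean() for k, v in groups.items() if k[0] > 0 and k[1] == 270.0]
    neg = [v.mean() for k, v in groups.items() if k[0] > 0 and k[1] == 90.0]
    if not pos or not neg:
        return "unknown"
    return "positive" if np.max(pos) >= np.max(neg) else "negative"


# ---------------------------------------------------------------------------
# Bingham fit
# ---------------------------------------------------------------------------

@dataclass
class BinghamParams:
    """Parameters of R(n) = A exp(l1 (v1.n)^2 + l2 (v2.n)^2) + B.

    With concentrations l1 <= l2 <= 0 the peak of R is attained where n
    is orthogonal to both axes, i.e. at the third orthonormal axis
    v3 = v1 x v2 (taken on the z >= 0 hemisphere).
    """

    amplitude: float
    baseline: float
    lambda1: float
    lambda2: float
    v1: tuple[float, float, float]
    v2: tuple[float, float, float]

    @property
    def peak_normal(self) -> np.ndarray:
        v3 = np.cross(self.v1, self.v2)
        v3 /= np.linalg.norm(v3)
        return v3 if v3[2] >= 0 else -v3

    @property
    def preferred_slant_tilt(self) -> tuple[float, float]:
        return normal_to_slant_tilt(self.peak_normal)

    def rate(self, slant_deg, tilt_deg) -> np.ndarray:
        n = surface_normal(slant_deg, tilt_deg)
        q = (n @ np.asarray(self.v1)) ** 2 * self.lambda1 \
            + (n @ np.asarray(self.v2)) ** 2 * self.lambda2
        return self.amplitude * np.exp(q) + self.baseline


def _rotation_basis(rotvec: np.ndarray) -> np.ndarray:
    """3x3 rotation matrix from a Rodrigues rotation vector."""
    theta = np.linalg.norm(rotvec)
    if theta < 1e-12:
        return np.eye(3)
    k = rotvec / theta
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)


class BinghamTuning(RegressorMixin, BaseEstimator):
    """Least-squares Bingham-function fit of a slant-tilt tuning profile.

    scikit-learn style estimator: ``fit(X, y)`` with ``X`` an (n, 2)
    array of (slant_deg, tilt_deg) and ``y`` the condition mean rates.
    Multi-start Levenberg-Marquardt-type optimisation, initialised at
    the ``n_starts`` grid conditions with the largest observed means.

    Fitted attributes: ``params_`` (:class:`BinghamParams`), ``r_``
    (Pearson r between fitted and observed means; ``-inf`` sentinel if
    every restart fails or the fit is degenerate), ``preferred_slant_``
    and ``preferred_tilt_`` (degrees).
    """

    def __init__(self, n_starts: int = 8, max_nfev: int = 2000):
        self.n_starts = n_starts
        self.max_nfev = max_nfev

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2) of (slant_deg, tilt_deg)")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if not np.any(X[:, 0] > 0):
            raise ValueError("need at least one non-frontoparallel condition")
        normals = surface_normal(X[:, 0], X[:, 1])

        y_span = y.max() - y.min()
        best = None
        order = np.argsort(y)[::-1]
        starts = order[: self.n_starts]
        for idx in starts:
            peak = normals[idx]
            # basis whose third column is the candidate peak normal
            helper = np.array([1.0, 0.0, 0.0])
            if abs(peak @ helper) > 0.9:
                helper = np.array([0.0, 1.0, 0.0])
            v1 = np.cross(peak, helper)
            v1 /= np.linalg.norm(v1)
            v2 = np.cross(peak, v1)
            basis = np.column_stack([v1, v2, peak])
            # rotation vector reproducing that basis
            from scipy.spatial.transform import Rotation
            rotvec = Rotation.from_matrix(basis).as_rotvec()
            p0 = np.array([max(y_span, 1e-3), max(y.min(), 0.0), -3.0, -1.5,
                           *rotvec])
            try:
                sol = optimize.least_squares(
                    self._residuals, p0, args=(normals, y),
                    bounds=([0.0, 0.0, -50.0, -50.0, -2 * np.pi, -2 * np.pi, -2 * np.pi],
                            [np.inf, np.inf, 0.0, 0.0, 2 * np.pi, 2 * np.pi, 2 * np.pi]),
                    max_nfev=self.max_nfev,
                )
            except Exception:  # pragma: no cover - optimiser edge cases
                continue
            if best is None or sol.cost < best.cost:
                best = sol

        if best is None:
            self.params_ = None
            self.r_ = R_FAILED
            self.preferred_slant_ = self.preferred_tilt_ = np.nan
            return self

        self.params_ = self._unpack(best.x)
        fitted = self.params_.rate(X[:, 0], X[:, 1])
        if np.std(fitted) < 1e-12 or np.std(y) < 1e-12:
            # flat fit or flat data: correlation undefined
            self.r_ = R_FAILED
        else:
            self.r_ = float(np.corrcoef(fitted, y)[0, 1])
        self.preferred_slant_, self.preferred_tilt_ = self.params_.preferred_slant_tilt
        return self

    @staticmethod
    def _unpack(p: np.ndarray) -> BinghamParams:
        a, b, l1, l2 = p[:4]
        basis = _rotation_basis(p[4:7])
        v1, v2 = basis[:, 0], basis[:, 1]
        if l1 > l2:  # enforce l1 <= l2 by swapping axes
            l1, l2 = l2, l1
            v1, v2 = v2, v1
        return BinghamParams(float(a), float(b), float(l1), float(l2),
                             tuple(v1), tuple(v2))

    @staticmethod
    def _residuals(p: np.ndarray, normals: np.ndarray, y: np.ndarray) -> np.ndarray:
        a, b, l1, l2 = p[:4]
        basis = _rotation_basis(p[4:7])
        q = l1 * (normals @ basis[:, 0]) ** 2 + l2 * (normals @ basis[:, 1]) ** 2
        return a * np.exp(q) + b - y

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.params_.rate(X[:, 0], X[:, 1])


def fit_bingham_tuning(
    condition_means: dict[tuple[float, float], float],
) -> tuple[BinghamParams | None, float]:
    """Fit a Bingham function to per-condition mean rates.

    Returns ``(params, r)`` with ``r = -inf`` sentinel when the fit
    failed or is degenerate (neuron then classifies untuned).
    """
    keys = sorted(condition_means)
    X = np.array(keys, dtype=float)
    y = np.array([condition_means[k] for k in keys], dtype=float)
    est = BinghamTuning().fit(X, y)
    return est.params_, est.r_


def classify_tuning(anova_p: float, bingham_r: float) -> str:
    """Two-step tuned/untuned classification.

    tuned iff anova_p < 0.05 and bingham_r >= 0.8;
    'untuned_multipeak' marks neurons passing the ANOVA whose unimodal
    fit is poor (r < 0.8).
    """
    if anova_p < ANOVA_ALPHA and bingham_r >= BINGHAM_R_GATE:
        return "tuned"
    if anova_p < ANOVA_ALPHA:
        return "untuned_multipeak"
    return "untuned"


# ---------------------------------------------------------------------------
# full per-neuron tuning result
# ---------------------------------------------------------------------------

@dataclass
class TuningResult:
    neuron_id: str
    condition_means: dict
    r_max: float
    r_min: float
    sse: float
    n_trials: int
    m_conditions: int
    sodi: float
    anova_p: float
    bingham: BinghamParams | None
    bingham_r: float
    tuned: bool
    multi_peak_rejected: bool
    preferred_slant_deg: float
    preferred_tilt_deg: float
    slant_axis_anova_p: float = field(default=np.nan)


def analyze_tuning(session: Session) -> TuningResult:
    """Run the full tuning analysis on one fixation session."""
    groups = condition_groups(session)
    means = {k: float(v.mean()) for k, v in groups.items()}
    sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups.values())
    sodi = compute_sodi(groups)
    anova_p = condition_anova(groups)
    params, r = fit_bingham_tuning(means)
    label = classify_tuning(anova_p, r)
    if params is not None and label == "tuned":
        pref_s, pref_t = params.preferred_slant_tilt
    else:
        pref_s = pref_t = np.nan
    return TuningResult(
        neuron_id=session.neuron_id,
        condition_means={f"{k[0]:g}/{k[1]:g}": v for k, v in means.items()},
        r_max=max(means.values()),
        r_min=min(means.values()),
        sse=sse,
        n_trials=sum(len(g) for g in groups.values()),
        m_conditions=len(groups),
        sodi=sodi,
        anova_p=anova_p,
        bingham=params,
        bingham_r=r,
        tuned=label == "tuned",
        multi_peak_rejected=label == "untuned_multipeak",
        preferred_slant_deg=pref_s,
        preferred_tilt_deg=pref_t,
        slant_axis_anova_p=slant_axis_anova(session),
    )


# ---------------------------------------------------------------------------
# population preference uniformity
# ---------------------------------------------------------------------------

def preference_uniformity_test(
    slants_deg,
    tilts_deg,
    n_sectors: int = 8,
    min_expected: float = 5.0,
) -> tuple[float, float]:
    """Chi-square goodness-of-fit of preferred directions vs uniformity.

    The hemisphere is partitioned into equal-area bins: slant rings with
    equal-area radii crossed with ``n_sectors`` tilt sectors, the number
    of rings chosen so every bin expects at least ``min_expected``
    counts under uniformity.  Returns (chi2, p).
    """
    s = np.asarray(slants_deg, dtype=float)
    t = np.asarray(tilts_deg, dtype=float) % 360.0
    n = len(s)
    if n < 20:
        raise ValueError("need >= 20 preferred directions")
    n_rings = max(1, int(n // (min_expected * n_sectors)))
    n_bins = n_rings * n_sectors
    if n < n_bins:
        raise ValueError(
            f"{n} preferences cannot fill {n_bins} bins; use coarser binning"
        )
    # equal-area ring edges on the slant<=90 cap: area ~ 1 - cos(s)
    ring_fracs = np.arange(1, n_rings) / n_rings
    ring_edges = np.degrees(np.arccos(1.0 - ring_fracs))  # cap total area 1-cos90 = 1
    ring_idx = np.searchsorted(ring_edges, s, side="right")
    sector_idx = np.floor(t / (360.0 / n_sectors)).astype(int) % n_sectors
    flat = ring_idx * n_sectors + sector_idx
    observed = np.bincount(flat, minlength=n_bins).astype(float)
    expected = np.full(n_bins, n / n_bins)
    chi2, p = stats.chisquare(observed, expected)
    return float(chi2), float(p)
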