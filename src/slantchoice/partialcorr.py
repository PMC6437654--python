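"""Partial-correlation decomposition of stimulus and choice signals.

Pearson correlations are computed among spike count F, signed slant S,
and choice C (top_near = -1, top_far = +1) over all screen-depth
trials; the slant and choice partial correlations are

    r_FS.C = (r_FS - r_FC * r_SC) / sqrt((1 - r_FC^2)(1 - r_SC^2))
    r_FC.S = (r_FC - r_FS * r_SC) / sqrt((1 - r_FS^2)(1 - r_SC^2)).

A positive r_FS.C means greater counts for positive slants; a positive
r_FC.S means greater counts for top-far choices.  Significance uses the
t transform with n - 3 degrees of freedom.  Squaring the partials gives
the spike-count variance fraction attributable to stimulus or choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CHOICE_TOP_FAR, CHOICE_TOP_NEAR, Session, choice_sign


@dataclass
class PartialCorrResult:
    r_fs: float
    r_fc: float
    r_sc: float
    r_fs_c: float
    r_fc_s: float
    p_fs_c: float
    p_fc_s: float
    spc2: float
    cpc2: float
    quadrant: str
    n_trials: int


def _partial(r_xy: float, r_xz: float, r_yz: float) -> float:
    num = r_xy - r_xz * r_yz
    denom = np.sqrt((1.0 - r_xz ** 2) * (1.0 - r_yz ** 2))
    if denom == 0:
        if abs(num) < 1e-12:
            # 0/0 limit, e.g. F == S exactly: no residual variance, no
            # residual association
            return 0.0
        raise ValueError(
            "partial correlation undefined: perfect collinearity among variables"
        )
    return num / denom


def _partial_p(r: float, n: int) -> float:
    """Two-sided p via t = r sqrt((n-3)/(1-r^2)) on n-3 df."""
    df = n - 3
    if df <= 0:
        return np.nan
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r ** 2))
    return float(2.0 * stats.t.sf(abs(t), df))


def quadrant_of(r_fs_c: float, r_fc_s: float) -> str:
    """Quadrant by sign pattern: I (+,+), II (-,+), III (-,-), IV (+,-).

    Quadrants I/III hold neurons whose stimulus and choice effects are
    congruent (correct choices for the preferred slant sign raise firing).
    """
    if r_fs_c >= 0:
        return "I" if r_fc_s >= 0 else "IV"
    return "II" if r_fc_s >= 0 else "III"


def partial_correlations_arrays(counts, slants, choices) -> PartialCorrResult:
    """Partial correlations from raw arrays (choices coded +/-1)."""
    f = np.asarray(counts, dtype=float)
    s = np.asarray(slants, dtype=float)
    c = np.asarray(choices, dtype=float)
    n = len(f)
    if np.ptp(f) == 0:
        raise ValueError("constant spike counts: correlations undefined")
    if len(np.unique(s)) < 2 or len(np.unique(c)) < 2:
        raise ValueError("need >= 2 distinct slants and both choices")
    r_fs = float(np.corrcoef(f, s)[0, 1])
    r_fc = float(np.corrcoef(f, c)[0, 1])
    r_sc = float(np.corrcoef(s, c)[0, 1])
    if abs(r_sc) >= 1.0 - 1e-15:
        raise ValueError(
            "choice perfectly determined by slant (|r_SC| = 1): collinear"
        )
    r_fs_c = _partial(r_fs, r_fc, r_sc)
    r_fc_s = _partial(r_fc, r_fs, r_sc)
    return PartialCorrResult(
        r_fs=r_fs, r_fc=r_fc, r_sc=r_sc,
        r_fs_c=float(r_fs_c), r_fc_s=float(r_fc_s),
        p_fs_c=_partial_p(r_fs_c, n), p_fc_s=_partial_p(r_fc_s, n),
        spc2=float(r_fs_c ** 2), cpc2=float(r_fc_s ** 2),
        quadrant=quadrant_of(r_fs_c, r_fc_s),
        n_trials=n,
    )


def partial_correlations(
    session: Session, slant_transform=None
) -> PartialCorrResult:
    """Partial correlations of one discrimination session.

    ``slant_transform`` optionally recodes the slant regressor (e.g.
    cubic or sigmoidal) as a sensitivity sweep; the default is the
    linear slant value.
    """
    t = session.screen_depth_trials()
    s = t["slant_deg"].to_numpy(float)
    if slant_transform is not None:
        s = slant_transform(s)
    return partial_correlations_arrays(
        t["spike_count"].to_numpy(float), s, choice_sign(t["choice"])
    )


# ---------------------------------------------------------------------------
# choice-conditioned tuning curves
# ---------------------------------------------------------------------------

def choice_conditioned_tuning(
    session: Session, min_choices: int = 3
) -> pd.DataFrame:
    """Mean count vs slant overall and per choice.

    The per-choice curves include a slant only when the animal made at
    least ``min_choices`` choices in that direction there.  Returns a
    tidy frame with columns slant_deg, curve ('all'/'top_far'/'top_near'),
    mean, sem, n.
    """
    t = session.screen_depth_trials()
    rows = []
    for s, g in t.groupby("slant_deg", sort=True):
        counts = g["spike_count"].to_numpy(float)
        rows.append(("all", float(s), counts))
        for choice in (CHOICE_TOP_FAR, CHOICE_TOP_NEAR):
            sub = g.loc[g["choice"] == choice, "spike_count"].to_numpy(float)
            if len(sub) >= min_choices:
                rows.append((choice, float(s), sub))
    return pd.DataFrame(
        [
            {
                "curve": curve,
                "slant_deg": s,
                "mean": x.mean(),
                "sem": x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
                "n": len(x),
            }
            for curve, s, x in rows
        ]
    )


# ---------------------------------------------------------------------------
# population confidence ellipses
# ---------------------------------------------------------------------------

@dataclass
class EllipseFit:
    group: str
    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle_deg: float
    angle_ci_deg: tuple[float, float]
    n_points: int


def _ellipse_geometry(points: np.ndarray, coverage: float) -> tuple:
    cov = np.cov(points, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        raise ValueError("degenerate covariance: points are collinear")
    scale = stats.chi2.ppf(coverage, df=2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    major = evecs[:, 0]
    angle = np.degrees(np.arctan2(major[1], major[0])) % 180.0
    return (points.mean(axis=0), np.sqrt(evals * scale), angle)


def confidence_ellipse(
    points,
    group: str = "cp_above_half",
    coverage: float = 0.95,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> EllipseFit:
    """Bivariate-normal coverage ellipse of (r_FS.C, r_FC.S) points.

    Semi-axes scale with the chi-square(2) quantile of ``coverage``;
    the major-axis angle (degrees in [0, 180)) comes from the principal
    eigenvector; its 95% CI is a percentile bootstrap over neurons with
    angles unwrapped to within 90 deg of the point estimate.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 5:
        raise ValueError("need >= 5 points per group")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    center, axes, angle = _ellipse_geometry(pts, coverage)

    boot_angles = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(pts), size=len(pts))
        try:
            _, _, a = _ellipse_geometry(pts[idx], coverage)
        except ValueError:
            continue
        # axial data: unwrap to within +/-90 deg of the point estimate
        d = (a - angle + 90.0) % 180.0 - 90.0
        boot_angles.append(angle + d)
    lo, hi = np.percentile(boot_angles, [2.5, 97.5])
    lo, hi = min(lo, angle), max(hi, angle)  # CI always contains estimate
    return EllipseFit(
        group=group,
        center=(float(center[0]), float(center[1])),
        semi_major=float(axes[0]),
        semi_minor=float(axes[1]),
        angle_deg=float(angle),
        angle_ci_deg=(float(lo), float(hi)),
        n_points=int(len(pts)),
    )


def ellipses_by_cp(
    population: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> dict[str, EllipseFit]:
    """Fit coverage ellipses separately for neurons with grand CP above
    and below 0.5 (columns: r_fs_c, r_fc_s, grand_cp)."""
    out = {}
    rng = np.random.default_rng(seed)
    for group, mask in (
        ("cp_above_half", population["grand_cp"] > 0.5),
        ("cp_below_half", population["grand_cp"] < 0.5),
    ):
        pts = population.loc[mask, ["r_fs_c", "r_fc_s"]].to_numpy(float)
        if len(pts) >= 5:
            out[group] = confidence_ellipse(pts, group=group, n_boot=n_boot, seed=rng)
    return out
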