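"""Psychometric analysis of the slant discrimination task.

Behavioral performance is the proportion of top-far choices as a
function of signed slant, fit with a cumulative Gaussian

    P(top_far | s) = gamma + (1 - gamma - lambda) * Phi((s - mu) / sigma).

The point of subjective equality (P.S.E.) is the mean mu and the
behavioral threshold is the SD sigma of the fit.  Lapse parameters
gamma and lambda are fitted but bounded at 0.1, standard psychophysics
practice to keep sigma stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .datamodel import CHOICE_TOP_FAR, Session

#: sentinel threshold for non-converged / unmodulated fits
SIGMA_SENTINEL = np.inf

LAPSE_BOUND = 0.1
_SIGMA_FLOOR = 1e-3


@dataclass
class PsychometricFit:
    pse_deg: float
    threshold_deg: float
    lapse_lower: float
    lapse_upper: float
    log_likelihood: float
    n_trials: dict
    converged: bool

    def predict(self, slants) -> np.ndarray:
        s = np.asarray(slants, dtype=float)
        g, lam = self.lapse_lower, self.lapse_upper
        return g + (1 - g - lam) * stats.norm.cdf(
            (s - self.pse_deg) / self.threshold_deg
        )


class CumulativeGaussian(BaseEstimator):
    """Maximum-likelihood cumulative-Gaussian fit of choice proportions.

    ``fit(X, y, sample_weight)`` takes signed slants ``X`` (shape (n,)
    or (n, 1)), observed proportions of top-far reports ``y`` in [0, 1]
    and per-point trial counts ``sample_weight``; the binomial
    log-likelihood is maximised by L-BFGS-B from several starts.
    Non-integer effective counts (e.g. ROC values from a neurometric
    function) are accepted: the likelihood is evaluated with k = y * n.

    Fitted attributes: ``pse_`` (mu), ``threshold_`` (sigma; ``inf``
    sentinel when the data carry no modulation), ``lapse_lower_``,
    ``lapse_upper_``, ``loglik_``, ``converged_``.
    """

    def __init__(self, fit_lapses: bool = True, lapse_bound: float = LAPSE_BOUND,
                 n_starts: int = 5):
        self.fit_lapses = fit_lapses
        self.lapse_bound = lapse_bound
        self.n_starts = n_starts

    @staticmethod
    def _nll(params, s, k, n, lapse_bound, fit_lapses):
        mu, log_sigma = params[0], params[1]
        g, lam = (params[2], params[3]) if fit_lapses else (0.0, 0.0)
        sigma = np.exp(log_sigma)
        p = g + (1 - g - lam) * stats.norm.cdf((s - mu) / sigma)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))

    def fit(self, X, y, sample_weight=None):
        s = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        n = (np.ones_like(s) if sample_weight is None
             else np.asarray(sample_weight, dtype=float).reshape(-1))
        keep = n > 0
        if not keep.all():
            import warnings
            warnings.warn("dropping zero-count rows from psychometric fit")
            s, y, n = s[keep], y[keep], n[keep]
        if len(np.unique(s)) < 4 or s.min() >= 0 or s.max() <= 0:
            raise ValueError("need >= 4 distinct slants spanning both signs")
        k = y * n

        self.converged_ = True
        if np.allclose(y, y[0]):
            # no modulation: sigma undefined
            self.pse_, self.threshold_ = np.nan, SIGMA_SENTINEL
            self.lapse_lower_ = self.lapse_upper_ = 0.0
            self.loglik_ = -self._nll([0.0, 10.0, 0.0, 0.0], s, k, n,
                                      self.lapse_bound, True)
            self.converged_ = False
            return self

        span = s.max() - s.min()
        sigma0s = np.array([0.1, 0.3, 1.0]) * span
        mu0s = [0.0, float(np.median(s))]
        best = None
        bounds = [(s.min() - span, s.max() + span),
                  (np.log(_SIGMA_FLOOR), np.log(100 * span))]
        if self.fit_lapses:
            bounds += [(0.0, self.lapse_bound)] * 2
        starts = [
            [mu0, np.log(sg0)] + ([0.01, 0.01] if self.fit_lapses else [])
            for mu0 in mu0s for sg0 in sigma0s
        ][: max(self.n_starts, 1)]
        for p0 in starts:
            res = optimize.minimize(
                self._nll, p0, args=(s, k, n, self.lapse_bound, self.fit_lapses),
                method="L-BFGS-B", bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
        self.converged_ = bool(best.success)
        self.pse_ = float(best.x[0])
        self.threshold_ = float(np.exp(best.x[1]))
        if self.fit_lapses:
            self.lapse_lower_, self.lapse_upper_ = map(float, best.x[2:4])
        else:
            self.lapse_lower_ = self.lapse_upper_ = 0.0
        self.loglik_ = float(-best.fun)
        return self

    def predict(self, X):
        s = np.asarray(X, dtype=float).reshape(-1)
        g, lam = self.lapse_lower_, self.lapse_upper_
        return g + (1 - g - lam) * stats.norm.cdf((s - self.pse_) / self.threshold_)

    def to_fit(self, n_trials: dict | None = None) -> PsychometricFit:
        return PsychometricFit(
            pse_deg=self.pse_,
            threshold_deg=self.threshold_,
            lapse_lower=self.lapse_lower_,
            lapse_upper=self.lapse_upper_,
            log_likelihood=self.loglik_,
            n_trials=n_trials or {},
            converged=self.converged_,
        )


def fit_cumulative_gaussian(slants, k_top_far, n, fit_lapses=True) -> PsychometricFit:
    """MLE cumulative-Gaussian fit from per-slant top-far counts."""
    slants = np.asarray(slants, dtype=float)
    k = np.asarray(k_top_far, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(n > 0, k / np.maximum(n, 1), 0.0)
    est = CumulativeGaussian(fit_lapses=fit_lapses).fit(slants, y, sample_weight=n)
    return est.to_fit(n_trials={float(s): float(m) for s, m in zip(slants, n)})


def psychometric_from_session(session: Session, depth_cm: float | None = 0.0,
                              fit_lapses: bool = True) -> PsychometricFit:
    """Fit the psychometric function of one discrimination session."""
    t = session.trials[session.trials["task"] == "discrimination"]
    if depth_cm is not None:
        t = t[t["depth_cm"] == depth_cm]
    grouped = t.groupby("slant_deg")["choice"]
    slants = np.array(sorted(grouped.groups))
    k = np.array([(grouped.get_group(s) == CHOICE_TOP_FAR).sum() for s in slants])
    n = np.array([len(grouped.get_group(s)) for s in slants])
    return fit_cumulative_gaussian(slants, k, n, fit_lapses=fit_lapses)


def screen_crossing_slant(stim_angle_deg: float, view_dist_cm: float,
                          depth_offset_cm: float) -> float:
    """Smallest slant at which a depth-offset plane crosses the display.

    For a stimulus of angular size ``stim_angle_deg`` viewed at
    ``view_dist_cm``, a plane centered ``depth_offset_cm`` in front of or
    behind the screen first touches the display plane at slant
    arctan(|offset| / (view_dist * tan(angle / 2))).  At the study's
    geometry (31 deg, 32.5 cm, 2.25 cm) this is about 14 deg — the bias
    magnitude a local-disparity strategy would produce.
    """
    if stim_angle_deg <= 0:
        raise ValueError("stimulus angle must be positive")
    if view_dist_cm <= 0:
        raise ValueError("viewing distance must be positive")
    half_extent = view_dist_cm * np.tan(np.deg2rad(stim_angle_deg) / 2.0)
    return float(np.degrees(np.arctan(abs(depth_offset_cm) / half_extent)))


@dataclass
class DepthControlResult:
    p_pse: float
    p_threshold: float
    pse_by_depth: dict
    threshold_by_depth: dict
    disparity_prediction_deg: float


def depth_control_anova(
    fits: dict[float, list[PsychometricFit]],
    stim_angle_deg: float = 31.0,
    view_dist_cm: float = 32.5,
) -> DepthControlResult:
    """One-way ANOVA of P.S.E. and threshold across stimulus depths.

    ``fits`` maps depth (cm) to the per-session psychometric fits at
    that depth.  Also reports the local-disparity prediction: were the
    task solved from local absolute disparity, |P.S.E.| at the offset
    depths would be at least the screen-crossing slant (~14 deg).
    """
    depths = sorted(fits)
    if len(depths) < 2:
        raise ValueError("need >= 2 depth levels")
    pses = {d: [f.pse_deg for f in fits[d]] for d in depths}
    thrs = {d: [f.threshold_deg for f in fits[d]] for d in depths}
    p_pse = float(stats.f_oneway(*[pses[d] for d in depths]).pvalue)
    p_thr = float(stats.f_oneway(*[thrs[d] for d in depths]).pvalue)
    offset = max(abs(d) for d in depths)
    pred = screen_crossing_slant(stim_angle_deg, view_dist_cm, offset) if offset > 0 else 0.0
    return DepthControlResult(
        p_pse=p_pse,
        p_threshold=p_thr,
        pse_by_depth={d: float(np.mean(pses[d])) for d in depths},
        threshold_by_depth={d: float(np.mean(thrs[d])) for d in depths},
        disparity_prediction_deg=pred,
    )
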