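"""Eye-movement confound controls.

For each neuron an ANCOVA relates firing rate to choice with a
trial-mean eye covariate (vertical position, vertical velocity, or
vergence) as a continuous coregressor; significance of the covariate
across neurons is corrected with the Bonferroni-Holm step-down.  The
responses are then detrended — the simple linear dependence on the
covariate subtracted — and the grand CP and neuronal threshold are
recomputed, with paired before/after comparisons.

Detrending uses the marginal (simple-regression) slope so that the
corrected responses have exactly zero linear trend on the covariate and
the operation is idempotent; the ANCOVA (which additionally conditions
on choice) is used only for significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .choiceprob import InclusionError, grand_cp
from .datamodel import Session, choice_sign
from .neurometric import build_neurometric_curve

COVARIATES = ("eye_vpos_deg", "eye_vvel_deg_s", "vergence_deg")


@dataclass
class EyeControlResult:
    covariate: str
    neuron_ids: list
    ancova_p: list
    significant: list          # after Bonferroni-Holm
    significant_fraction: float
    cp_before: list
    cp_after: list
    threshold_before: list
    threshold_after: list
    p_cp_paired: float
    p_threshold_paired: float
    r_cp_before_after: float
    skipped: list


def detrend_on_covariate(counts: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Remove the linear trend of ``counts`` on ``covariate``.

    Subtracts slope * (x - mean(x)); the mean response is preserved and
    the residual slope is exactly zero, making the operation idempotent.
    """
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(counts, dtype=float)
    xc = x - x.mean()
    denom = np.sum(xc ** 2)
    if denom == 0:
        raise ValueError("constant covariate")
    slope = np.sum(xc * (y - y.mean())) / denom
    return y - slope * xc


def _ancova_p(session: Session, covariate: str) -> float:
    t = session.screen_depth_trials().copy()
    t["csign"] = choice_sign(t["choice"])
    t = t.rename(columns={covariate: "x"})
    model = smf.ols("spike_count ~ C(csign) + x", data=t).fit()
    return float(model.pvalues["x"])


def eye_ancova_and_detrend(
    sessions: list[Session],
    covariate: str,
    alpha: float = 0.05,
) -> EyeControlResult:
    """Run the eye-covariate control over a population of sessions.

    Sessions lacking the covariate (or with a constant covariate) are
    skipped with a warning, mirroring that the original controls ran
    only where eye signals existed.
    """
    if covariate not in COVARIATES:
        raise ValueError(f"unknown covariate {covariate!r}; one of {COVARIATES}")
    ids, pvals, skipped = [], [], []
    cp_before, cp_after = [], []
    thr_before, thr_after = [], []
    for session in sessions:
        t = session.screen_depth_trials()
        x = t[covariate].to_numpy(dtype=float) if covariate in t else None
        if x is None or np.any(~np.isfinite(x)):
            warnings.warn(f"{session.neuron_id}: missing {covariate}, skipped")
            skipped.append(session.neuron_id)
            continue
        if np.ptp(x) == 0:
            warnings.warn(f"{session.neuron_id}: constant {covariate}, skipped")
            skipped.append(session.neuron_id)
            continue
        ids.append(session.neuron_id)
        pvals.append(_ancova_p(session, covariate))

        counts = t["spike_count"].to_numpy(dtype=float)
        detrended = detrend_on_covariate(counts, x)
        corrected = _with_counts(session, detrended)
        for sess, cps, thrs in ((session, cp_before, thr_before),
                                (corrected, cp_after, thr_after)):
            try:
                cps.append(grand_cp(sess).grand_cp)
            except (InclusionError, ValueError):
                cps.append(np.nan)
            try:
                thrs.append(build_neurometric_curve(sess).neuronal_threshold_deg)
            except ValueError:
                thrs.append(np.nan)

    if not ids:
        raise ValueError(f"no session carries covariate {covariate}")
    reject, p_corr, *_ = multipletests(pvals, alpha=alpha, method="holm")

    cpb, cpa = np.asarray(cp_before), np.asarray(cp_after)
    ok = np.isfinite(cpb) & np.isfinite(cpa)
    p_cp = float(stats.ttest_rel(cpb[ok], cpa[ok]).pvalue) if ok.sum() > 1 else np.nan
    r_cp = float(np.corrcoef(cpb[ok], cpa[ok])[0, 1]) if ok.sum() > 1 else np.nan
    tb, ta = np.asarray(thr_before), np.asarray(thr_after)
    okt = np.isfinite(tb) & np.isfinite(ta)
    if okt.sum() > 1 and np.ptp(tb[okt] - ta[okt]) > 0:
        p_thr = float(stats.wilcoxon(tb[okt], ta[okt]).pvalue)
    else:
        p_thr = np.nan

    return EyeControlResult(
        covariate=covariate,
        neuron_ids=ids,
        ancova_p=[float(p) for p in pvals],
        significant=[bool(r) for r in reject],
        significant_fraction=float(np.mean(reject)),
        cp_before=[float(v) for v in cpb],
        cp_after=[float(v) for v in cpa],
        threshold_before=[float(v) for v in tb],
        threshold_after=[float(v) for v in ta],
        p_cp_paired=p_cp,
        p_threshold_paired=p_thr,
        r_cp_before_after=r_cp,
        skipped=skipped,
    )


def _with_counts(session: Session, counts: np.ndarray) -> Session:
    """Session copy whose screen-depth discrimination trials carry the
    given (possibly non-integer, detrended) response values."""
    trials = session.trials.copy()
    mask = (trials["task"] == "discrimination") & (trials["depth_cm"] == 0.0)
    col = trials["spike_count"].astype(float)
    col.loc[mask] = counts
    trials["spike_count"] = col
    trials["spike_times_ms"] = [None] * len(trials)
    return Session(
        neuron_id=session.neuron_id, area=session.area,
        monkey_id=session.monkey_id, trials=trials,
        stim_dur_ms=session.stim_dur_ms,
        preferred_sign_fixation=session.preferred_sign_fixation,
        extra=session.extra,
    )
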