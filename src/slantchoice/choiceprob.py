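"""Choice probability: ROC separation of responses by the animal's choice.

CP is the ROC area between spike-count distributions conditioned on
preferred- vs nonpreferred-sign choices (preference sign taken from the
fixation task, never from the discrimination data, to keep it free of
choice-related activity).  CP = 0.5 means no choice relation; CP > 0.5
means stronger firing when the animal chooses the neuron's preferred
slant sign.

The *grand CP* pools across stimulus slants for statistical power:
within each slant the responses are normalized with a balanced z-score
(center = mean of the two choice-conditional means, scale = the
choice-balanced pooled SD) so that choice imbalance at a slant cannot
bias the pooled distributions; only slants with at least three choices
in each direction are included.  Significance against CP = 0.5 comes
from a permutation test that shuffles choice labels within each slant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .datamodel import (
    CHOICE_TOP_FAR,
    CHOICE_TOP_NEAR,
    Session,
)
from .neurometric import roc_auc

MIN_CHOICES_PER_SIDE = 3


class InclusionError(ValueError):
    """No stimulus slant satisfies the >=3-choices-each-direction rule."""


def _preferred_choice(session: Session) -> str:
    sign = session.preferred_sign_fixation
    if sign == "positive":
        return CHOICE_TOP_FAR
    if sign == "negative":
        return CHOICE_TOP_NEAR
    raise ValueError("preferred_sign_fixation must be 'positive' or 'negative'")


def _choice_groups(session: Session) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Per-slant (preferred-choice, nonpreferred-choice) count arrays,
    screen-depth trials only."""
    pref_choice = _preferred_choice(session)
    t = session.screen_depth_trials()
    out = {}
    for s, g in t.groupby("slant_deg", sort=True):
        counts = g["spike_count"].to_numpy(dtype=float)
        is_pref = (g["choice"] == pref_choice).to_numpy()
        out[float(s)] = (counts[is_pref], counts[~is_pref])
    return out


def cp_zero_slant(session: Session) -> float | None:
    """CP at the ambiguous 0-deg slant; None when a choice group is empty
    (undefined — deliberately not reported as 0.5)."""
    groups = _choice_groups(session)
    if 0.0 not in groups:
        return None
    pref, nonpref = groups[0.0]
    if len(pref) == 0 or len(nonpref) == 0:
        return None
    return roc_auc(nonpref, pref)


def balanced_zscore(pref: np.ndarray, nonpref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Balanced z-score normalization of one slant's responses.

    Center: mean of the two choice-conditional means.  Scale: sqrt of
    the equal-weight average of the two within-choice mean squared
    deviations from that center.  With balanced choice counts this is
    exactly the ordinary (ddof=0) per-slant z-score; with imbalanced
    counts each choice contributes equally, so imbalance cannot shift
    the pooled distributions.
    """
    pref = np.asarray(pref, dtype=float)
    nonpref = np.asarray(nonpref, dtype=float)
    center = 0.5 * (pref.mean() + nonpref.mean())
    var = 0.5 * (np.mean((pref - center) ** 2) + np.mean((nonpref - center) ** 2))
    if var <= 0:
        raise ZeroDivisionError("zero pooled SD within slant")
    scale = np.sqrt(var)
    return (pref - center) / scale, (nonpref - center) / scale


@dataclass
class CPResult:
    cp_zero: float | None
    grand_cp: float
    p_perm: float | None
    n_permutations: int
    included_slants: dict
    n_trials_used: int
    preferred_sign_source: str = "fixation_task"
    excluded_slants: list = field(default_factory=list)


def grand_cp(session: Session) -> CPResult:
    """Grand CP of one discrimination session (screen-depth trials).

    Pools balanced-z-scored responses over every slant with >= 3
    choices in each direction into composite preferred/nonpreferred
    distributions and takes the ROC area between them.
    """
    groups = _choice_groups(session)
    included, excluded = {}, []
    z_pref, z_nonpref = [], []
    for s, (pref, nonpref) in groups.items():
        if len(pref) < MIN_CHOICES_PER_SIDE or len(nonpref) < MIN_CHOICES_PER_SIDE:
            excluded.append(s)
            continue
        try:
            zp, zn = balanced_zscore(pref, nonpref)
        except ZeroDivisionError:
            warnings.warn(f"slant {s}: zero pooled SD, excluded from grand CP")
            excluded.append(s)
            continue
        included[s] = {"n_pref_choices": len(pref), "n_nonpref_choices": len(nonpref)}
        z_pref.append(zp)
        z_nonpref.append(zn)
    if not included:
        raise InclusionError(
            "no slant has >= 3 choices in each direction "
            f"(rule: {MIN_CHOICES_PER_SIDE} per side)"
        )
    pooled_pref = np.concatenate(z_pref)
    pooled_nonpref = np.concatenate(z_nonpref)
    return CPResult(
        cp_zero=cp_zero_slant(session),
        grand_cp=roc_auc(pooled_nonpref, pooled_pref),
        p_perm=None,
        n_permutations=0,
        included_slants=included,
        n_trials_used=int(len(pooled_pref) + len(pooled_nonpref)),
        excluded_slants=sorted(excluded),
    )


# ---------------------------------------------------------------------------
# permutation test (vectorised over permutations)
# ---------------------------------------------------------------------------

def _balanced_z_matrix(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Balanced z-scores of one slant's responses under many labelings.

    ``x``: (n,) responses; ``labels``: (n_perm, n) boolean, True =
    preferred choice.  Returns (n_perm, n) z-scored responses.  Rows
    with zero balanced variance come back as NaN.
    """
    n1 = labels.sum(axis=1, keepdims=True).astype(float)
    n0 = labels.shape[1] - n1
    mean_p = (labels @ x)[:, None] / n1
    mean_n = ((~labels) @ x)[:, None] / n0
    center = 0.5 * (mean_p + mean_n)
    dev2 = (x[None, :] - center) ** 2
    msd_p = (dev2 * labels).sum(axis=1, keepdims=True) / n1
    msd_n = (dev2 * (~labels)).sum(axis=1, keepdims=True) / n0
    var = 0.5 * (msd_p + msd_n)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x[None, :] - center) / np.sqrt(var)
    z[np.broadcast_to(var <= 0, z.shape)] = np.nan
    return z


def _auc_rows(z: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise rank-sum AUC of preferred (True) vs nonpreferred values."""
    ranks = stats.rankdata(z, axis=1)
    n1 = labels.sum(axis=1).astype(float)
    n0 = labels.shape[1] - n1
    u = (ranks * labels).sum(axis=1) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def permutation_test_cp(
    session: Session,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> CPResult:
    """Grand CP with a two-sided permutation test against CP = 0.5.

    Choice labels are shuffled within each included slant (preserving
    per-slant choice counts), the balanced normalization and pooled ROC
    are recomputed per permutation, and

        p = (1 + #{|CP_perm - 0.5| >= |CP_obs - 0.5|}) / (1 + n_perm)

    with add-one smoothing so p is never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    result = grand_cp(session)
    groups = _choice_groups(session)

    z_cols, label_cols = [], []
    for s in result.included_slants:
        pref, nonpref = groups[s]
        x = np.concatenate([pref, nonpref])
        base = np.zeros(len(x), dtype=bool)
        base[: len(pref)] = True
        # random permutations of the label vector within this slant
        keys = rng.random((n_perm, len(x)))
        order = np.argsort(keys, axis=1)
        labels = base[order]
        z_cols.append(_balanced_z_matrix(x, labels))
        label_cols.append(labels)
    z = np.concatenate(z_cols, axis=1)
    labels = np.concatenate(label_cols, axis=1)
    ok = ~np.isnan(z).any(axis=1)
    perm_cp = np.full(n_perm, np.nan)
    if ok.any():
        perm_cp[ok] = _auc_rows(z[ok], labels[ok])
    # degenerate permutations (zero balanced variance at some slant) count
    # as non-exceeding; they are vanishingly rare for continuous-ish counts
    obs_dev = abs(result.grand_cp - 0.5)
    exceed = np.nansum(np.abs(perm_cp - 0.5) >= obs_dev - 1e-12)
    result.p_perm = float((1 + exceed) / (1 + n_perm))
    result.n_permutations = n_perm
    return result


# ---------------------------------------------------------------------------
# population: CP vs neuronal threshold
# ---------------------------------------------------------------------------

@dataclass
class CPThresholdSummary:
    per_area: dict
    interaction_p: float
    ancova_table: dict


def cp_vs_threshold(population: pd.DataFrame) -> CPThresholdSummary:
    """Regression of grand CP on (doubled) neuronal threshold per area,
    plus an ANCOVA with a threshold-by-area interaction.

    ``population`` needs columns ``area``, ``grand_cp``,
    ``comparison_threshold_deg``.
    """
    pop = population.dropna(subset=["grand_cp", "comparison_threshold_deg"])
    pop = pop[np.isfinite(pop["comparison_threshold_deg"])]
    per_area = {}
    for area, g in pop.groupby("area"):
        if len(g) < 5:
            raise ValueError(f"area {area}: need >= 5 neurons, got {len(g)}")
        x = g["comparison_threshold_deg"].to_numpy(float)
        y = g["grand_cp"].to_numpy(float)
        if np.ptp(x) == 0:
            raise ValueError(f"area {area}: thresholds are constant")
        r, p = stats.pearsonr(x, y)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        lo, hi = ols.conf_int()[1]
        per_area[area] = {
            "n": int(len(g)), "r": float(r), "p": float(p),
            "slope": float(ols.params[1]), "intercept": float(ols.params[0]),
            "slope_ci": (float(lo), float(hi)),
        }
    model = smf.ols(
        "grand_cp ~ comparison_threshold_deg * C(area)", data=pop
    ).fit()
    inter = [k for k in model.pvalues.index if ":" in k]
    interaction_p = float(model.pvalues[inter].min()) if inter else np.nan
    return CPThresholdSummary(
        per_area=per_area,
        interaction_p=interaction_p,
        ancova_table={k: float(v) for k, v in model.pvalues.items()},
    )
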