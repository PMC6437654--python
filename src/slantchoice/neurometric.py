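"""ROC-based ideal-observer analysis of discrimination responses.

For each non-zero slant, the spike-count distribution is compared with
the 0-deg (frontoparallel) distribution via the ROC area: the
probability that an ideal observer tells the two apart.  Plotting those
values against signed slant and fitting a cumulative Gaussian yields a
*neurometric* function; the neuronal threshold is the SD of that fit.
Before comparison with the simultaneously measured behavioral
threshold, the neuronal threshold is doubled: the behavioral task is a
one-interval judgement whereas the neurometric construction compares
two response distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .behavior import CumulativeGaussian, PsychometricFit, SIGMA_SENTINEL
from .datamodel import Session

MIN_REPS_PER_SLANT = 10


def roc_auc(responses_a, responses_b) -> float:
    """P(random draw from b > random draw from a), ties counted 1/2.

    Rank-sum (Mann-Whitney) formulation; equals the trapezoidal area
    under the threshold-sweep ROC curve.
    """
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both response groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    rank_sum_b = ranks[a.size:].sum()
    u = rank_sum_b - b.size * (b.size + 1) / 2.0
    return float(u / (a.size * b.size))


@dataclass
class NeurometricResult:
    slants: list
    p_ideal_top_far: list
    n_per_slant: list
    pse_deg: float
    neuronal_threshold_deg: float
    comparison_threshold_deg: float
    converged: bool
    excluded_slants: list = field(default_factory=list)
    threshold_ratio: float = np.nan
    ratio_flagged: bool = False


def build_neurometric_curve(
    session: Session,
    min_reps: int = MIN_REPS_PER_SLANT,
    counts_by_slant: dict | None = None,
) -> NeurometricResult:
    """Neurometric function of one discrimination session.

    Only screen-depth (0 cm) trials enter.  For each non-zero slant the
    ROC area against the 0-deg distribution is computed and oriented as
    the probability that the ideal observer reports *positive* slant,
    using the neuron's fixation-task slant-preference sign (flipped for
    negative-preferring neurons).  A cumulative Gaussian is then fit to
    the oriented values over signed slant.
    """
    groups = counts_by_slant if counts_by_slant is not None \
        else session.counts_by_slant(depth_cm=0.0)
    if 0.0 not in groups:
        raise ValueError("session has no 0-deg slant trials at screen depth")
    excluded = [s for s, g in groups.items() if len(g) < min_reps]
    if excluded:
        warnings.warn(f"slants {sorted(excluded)} excluded (< {min_reps} reps)")
    groups = {s: g for s, g in groups.items() if len(g) >= min_reps}
    if 0.0 not in groups:
        raise ValueError(f"0-deg slant has fewer than {min_reps} reps")
    zero = groups[0.0]

    sign = {"positive": 1.0, "negative": -1.0}.get(session.preferred_sign_fixation)
    if sign is None:
        raise ValueError(
            "preferred_sign_fixation must be known to orient the neurometric curve"
        )

    slants, p_pos, ns = [], [], []
    for s in sorted(groups):
        if s == 0.0:
            continue
        auc = roc_auc(zero, groups[s])  # P(draw at slant s exceeds draw at 0)
        p = auc if sign > 0 else 1.0 - auc
        slants.append(float(s))
        p_pos.append(float(p))
        ns.append(len(groups[s]))

    slants_arr = np.asarray(slants)
    p_arr = np.asarray(p_pos)
    n_arr = np.asarray(ns, dtype=float)
    try:
        est = CumulativeGaussian().fit(slants_arr, p_arr, sample_weight=n_arr)
        pse, sigma, conv = est.pse_, est.threshold_, est.converged_
    except ValueError:
        pse, sigma, conv = np.nan, SIGMA_SENTINEL, False
    return NeurometricResult(
        slants=slants,
        p_ideal_top_far=p_pos,
        n_per_slant=ns,
        pse_deg=pse,
        neuronal_threshold_deg=sigma,
        comparison_threshold_deg=2.0 * sigma,
        converged=conv,
        excluded_slants=sorted(excluded),
    )


def neuronal_threshold(
    result: NeurometricResult, behavioral: PsychometricFit
) -> NeurometricResult:
    """Attach the x2 comparison threshold and neuronal/behavioral ratio.

    The ratio uses the doubled neuronal threshold over the simultaneous
    behavioral threshold; ratios < 1 (neuron apparently more sensitive
    than the animal) and sentinel (infinite) thresholds are flagged.
    """
    sigma = result.neuronal_threshold_deg
    result.comparison_threshold_deg = 2.0 * sigma
    if not np.isfinite(sigma) or not np.isfinite(behavioral.threshold_deg):
        result.threshold_ratio = np.inf
        result.ratio_flagged = True
        return result
    result.threshold_ratio = float(result.comparison_threshold_deg
                                   / behavioral.threshold_deg)
    result.ratio_flagged = result.threshold_ratio < 1.0
    return result
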