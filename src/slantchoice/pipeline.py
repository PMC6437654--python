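"""End-to-end per-neuron and population analysis pipeline.

For each neuron (a fixation session and/or a discrimination session):
tuning quantification and the tuned/untuned gates, psychometric and
neurometric fits, grand CP with its permutation test, partial
correlations, optional time courses and eye-covariate controls.  The
population stage aggregates CP-vs-threshold regressions, the quadrant /
confidence-ellipse analysis, and the preference-uniformity test.  Every
gate decision (ANOVA p, Bingham r, repetition counts) is logged in the
report, and the seed and configuration are embedded in every output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, choiceprob, controls, neurometric, partialcorr, timecourse, tuning
from .datamodel import Session
from .io import read_session, write_results

MIN_REPS_DISCRIMINATION = 10


@dataclass
class PipelineConfig:
    fixation_paths: list = field(default_factory=list)
    discrimination_paths: list = field(default_factory=list)
    out_dir: str = "slantchoice_out"
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    seed: int = 0
    run_timecourses: bool = False
    run_eye_controls: bool = False
    window: timecourse.WindowSpec = field(default_factory=timecourse.WindowSpec)

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


def analyze_neuron(
    discrimination: Session,
    fixation: Session | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Full single-neuron analysis; returns a JSON-ready dict."""
    out: dict = {"neuron_id": discrimination.neuron_id,
                 "area": discrimination.area,
                 "gates": {}}
    if fixation is not None:
        tun = tuning.analyze_tuning(fixation)
        out["tuning"] = tun
        out["gates"]["anova_p"] = tun.anova_p
        out["gates"]["bingham_r"] = tun.bingham_r
        out["gates"]["tuned"] = tun.tuned
        out["gates"]["slant_axis_anova_p"] = tun.slant_axis_anova_p
        sign = tuning.preferred_sign_from_fixation(fixation)
        if sign != "unknown":
            if (discrimination.preferred_sign_fixation not in ("unknown", sign)):
                out["gates"]["sign_reversal_logged"] = True
            discrimination.preferred_sign_fixation = sign

    reps = {s: len(g) for s, g in discrimination.counts_by_slant().items()}
    out["gates"]["reps_per_slant"] = {f"{s:g}": n for s, n in reps.items()}
    eligible = all(n >= MIN_REPS_DISCRIMINATION for n in reps.values())
    out["gates"]["eligible"] = bool(eligible)

    psych = behavior.psychometric_from_session(discrimination)
    out["psychometric"] = psych
    neuro = neurometric.build_neurometric_curve(discrimination)
    neuro = neurometric.neuronal_threshold(neuro, psych)
    out["neurometric"] = neuro
    cp = choiceprob.permutation_test_cp(
        discrimination, n_perm=n_permutations, seed=seed
    )
    out["cp"] = cp
    out["partial_correlations"] = partialcorr.partial_correlations(discrimination)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline over the configured session files.

    Returns the report dict (also written to ``out_dir``).  A report
    with zero eligible neurons keeps an empty population section and
    signals failure via ``report['status']``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fixations = {s.neuron_id: s for s in map(read_session, config.fixation_paths)}
    discriminations = [read_session(p) for p in config.discrimination_paths]

    per_neuron, rows = [], []
    rng = np.random.default_rng(config.seed)
    for session in discriminations:
        child = int(rng.integers(0, 2 ** 31 - 1))
        res = analyze_neuron(
            session, fixations.get(session.neuron_id),
            n_permutations=config.n_permutations, seed=child,
        )
        per_neuron.append(res)
        if res["gates"]["eligible"]:
            rows.append({
                "neuron_id": res["neuron_id"],
                "area": res["area"],
                "grand_cp": res["cp"].grand_cp,
                "cp_zero": res["cp"].cp_zero,
                "p_perm": res["cp"].p_perm,
                "comparison_threshold_deg": res["neurometric"].comparison_threshold_deg,
                "behavioral_threshold_deg": res["psychometric"].threshold_deg,
                "threshold_ratio": res["neurometric"].threshold_ratio,
                "r_fs_c": res["partial_correlations"].r_fs_c,
                "r_fc_s": res["partial_correlations"].r_fc_s,
                "quadrant": res["partial_correlations"].quadrant,
            })

    population = pd.DataFrame(rows)
    pop_summary: dict = {}
    if len(population):
        pop_summary["mean_grand_cp"] = float(population["grand_cp"].mean())
        pop_summary["mean_cp_by_area"] = {
            a: float(g["grand_cp"].mean()) for a, g in population.groupby("area")
        }
        finite = population[np.isfinite(population["comparison_threshold_deg"])]
        if (finite.groupby("area").size() >= 5).all() and len(finite["area"].unique()) >= 1:
            try:
                pop_summary["cp_vs_threshold"] = dataclasses.asdict(
                    choiceprob.cp_vs_threshold(finite)
                )
            except ValueError as exc:
                pop_summary["cp_vs_threshold_error"] = str(exc)
        ell = partialcorr.ellipses_by_cp(
            population, n_boot=config.n_bootstrap, seed=config.seed
        )
        pop_summary["ellipses"] = {k: dataclasses.asdict(v) for k, v in ell.items()}

    report = {
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "n_neurons": len(per_neuron),
        "n_eligible": int(len(population)),
        "status": "ok" if len(population) else "no_eligible_neurons",
        "population": pop_summary,
    }
    write_results(report, out_dir / "report.json", seed=config.seed,
                  config=dataclasses.asdict(config))
    for res in per_neuron:
        write_results(res, out_dir / f"neuron_{res['neuron_id']}.json",
                      seed=config.seed)
    if len(population):
        write_results(population, out_dir / "population.tsv", seed=config.seed)
    return report
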