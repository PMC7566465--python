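"""Replication pipeline: counts, transition-specific fits, AIC, curves.

Runs the full analysis on a cohort: transition counting, stacked
long-format construction, Weibull proportional-hazards fits of the three
direct transitions under two covariate families (clinical, adjusted for
treatment exposure; mutational, restricted to the mutation-informative
subcohort), baseline-only fits of the transitions out of the intermediate
states, AIC comparison of the families, and transition-probability /
state-occupation curves by ODE integration and by path simulation.

Because the mutational family is fitted on a subcohort, AICs across
families are not comparable on different data; the pipeline therefore also
refits the clinical family on the mutation-informative subcohort and
reports both comparisons.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .state_space import (
    StateSpace,
    SubjectRecord,
    build_long_format,
    count_transitions,
    default_state_space,
    long_format_to_frame,
    read_state_space_yaml,
    read_subject_csv,
)
from .weibull_ph import FitError, WeibullPHFit, aic, fit_transition, hazard_ratios
from .predict import (
    ModelSet,
    population_average_occupation,
    simulate_transition_probabilities,
    transition_probabilities_ode,
)

__all__ = ["AnalysisReport", "run_analysis", "DEFAULT_MODEL_SPEC"]

#: default covariate families.  ``subset`` names a 0/1 indicator column
#: restricting the fit to subjects with that datum available.
DEFAULT_MODEL_SPEC: dict = {
    "clinical": {
        "covariates": [
            "male",
            "age_gt65",
            "anemia",
            "wbc_gt15",
            "plt_gt1000",
            "fibrosis_g1",
            "spleen_gt5cm",
            "ldh_gt1_5",
            "abnormal_karyotype",
        ],
        "adjusters": ["chemo", "antiplatelet", "anticoagulant"],
        "subset": None,
    },
    "mutational": {
        # driver mutations (triple-negative reference) plus high molecular risk
        "covariates": ["jak2", "mpl", "calr", "hmr"],
        "adjusters": [],
        "subset": "mutation_data",
    },
}


@dataclass
class AnalysisReport:
    """Consolidated result of :func:`run_analysis`."""

    counts: pd.DataFrame
    fits: dict[str, dict[int, WeibullPHFit | None]]
    fit_notes: dict[str, dict[int, str]]
    aic_table: pd.DataFrame
    manifest: list[str]
    metadata: dict

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "counts": self.counts.to_dict("records"),
            "ending_counts": self.counts.attrs.get("ending_counts", {}),
            "n_subjects": self.counts.attrs.get("n_subjects"),
            "fits": {
                family: {
                    str(k): (f.to_dict() if f is not None else None)
                    for k, f in fits_k.items()
                }
                for family, fits_k in self.fits.items()
            },
            "fit_notes": {
                family: {str(k): v for k, v in notes.items()}
                for family, notes in self.fit_notes.items()
            },
            "aic": self.aic_table.to_dict("records"),
            "manifest": self.manifest,
        }

    def content_hash(self) -> str:
        """SHA-256 over the canonical report content (metadata excluded)."""
        doc = self.to_dict()
        doc.pop("metadata")
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()
        ).hexdigest()


def _complete_case(
    subjects: Sequence[SubjectRecord],
    needed: Sequence[str],
    subset: str | None,
) -> tuple[list[SubjectRecord], int]:
    kept, dropped = [], 0
    for s in subjects:
        if subset is not None and not s.covariates.get(subset, 0.0):
            continue
        vals = [s.covariates.get(c, np.nan) for c in needed]
        if np.all(np.isfinite(vals)):
            kept.append(s)
        else:
            dropped += 1
    return kept, dropped


def _fit_family(
    subjects: Sequence[SubjectRecord],
    space: StateSpace,
    transitions: Sequence[int],
    covariates: Sequence[str],
    clock: str,
) -> tuple[dict[int, WeibullPHFit | None], dict[int, str]]:
    rows = build_long_format(subjects, space, clock=clock)
    fits: dict[int, WeibullPHFit | None] = {}
    notes: dict[int, str] = {}
    for k in transitions:
        k_rows = [r for r in rows if r.transition == k]
        # drop covariates that are constant among this transition's rows
        use = []
        for c in covariates:
            vals = {r.covariates[c] for r in k_rows}
            if len(vals) > 1:
                use.append(c)
        dropped = sorted(set(covariates) - set(use))
        if dropped:
            notes[k] = f"dropped constant covariates: {', '.join(dropped)}"
        try:
            fits[k] = fit_transition(k_rows, use, transition=k)
        except FitError as exc:
            fits[k] = None
            notes[k] = f"fit skipped: {exc}"
    return fits, notes


def run_analysis(
    subjects: Sequence[SubjectRecord] | str | Path,
    space: StateSpace | str | Path | None = None,
    model_spec: dict | str | Path | None = None,
    out_dir: str | Path = "analysis_out",
    seed: int = 0,
    clock: str = "forward",
    n_paths: int = 10_000,
    times: np.ndarray | None = None,
    make_plot: bool = True,
) -> AnalysisReport:
    """Run the full replication analysis and write its outputs.

    Writes to ``out_dir``: ``report.json``, ``counts.csv``,
    ``fits_clinical.csv``, ``fits_mutational.csv``, ``aic.csv``,
    ``curves/ode.csv``, ``curves/sim.csv``, ``occupation.csv`` and an
    optional stacked occupation plot.
    """
    import yaml

    if isinstance(subjects, (str, Path)):
        subjects = read_subject_csv(subjects)
    if space is None:
        space = default_state_space()
    elif isinstance(space, (str, Path)):
        space = read_state_space_yaml(space)
    if model_spec is None:
        model_spec = DEFAULT_MODEL_SPEC
    elif isinstance(model_spec, (str, Path)):
        with open(model_spec) as fh:
            model_spec = yaml.safe_load(fh)

    out_dir = Path(out_dir)
    (out_dir / "curves").mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    counts = count_transitions(subjects, space)
    counts.to_csv(out_dir / "counts.csv", index=False)
    manifest.append("counts.csv")

    initial = space.state_ids[0]
    direct = space.transitions_from(initial)
    later = [
        k
        for k in range(1, space.n_transitions + 1)
        if k not in direct
    ]

    all_fits: dict[str, dict[int, WeibullPHFit | None]] = {}
    all_notes: dict[str, dict[int, str]] = {}
    exclusions: dict[str, dict] = {}
    for family, spec_f in model_spec.items():
        needed = list(spec_f["covariates"]) + list(spec_f.get("adjusters") or [])
        kept, dropped = _complete_case(subjects, needed, spec_f.get("subset"))
        exclusions[family] = {
            "n_fitted": len(kept),
            "n_dropped_missing": dropped,
            "subset": spec_f.get("subset"),
        }
        fits, notes = _fit_family(kept, space, direct, needed, clock)
        all_fits[family] = fits
        all_notes[family] = notes

    # clinical family refitted on the mutational subcohort for a
    # like-for-like AIC comparison
    mut_subset = model_spec.get("mutational", {}).get("subset")
    if "clinical" in model_spec and mut_subset:
        spec_c = model_spec["clinical"]
        needed = list(spec_c["covariates"]) + list(spec_c.get("adjusters") or [])
        kept, dropped = _complete_case(subjects, needed, mut_subset)
        exclusions["clinical_subcohort"] = {
            "n_fitted": len(kept),
            "n_dropped_missing": dropped,
            "subset": mut_subset,
        }
        fits, notes = _fit_family(kept, space, direct, needed, clock)
        all_fits["clinical_subcohort"] = fits
        all_notes["clinical_subcohort"] = notes

    # baseline-only fits of the later transitions (covariate models for
    # them are not part of the analysis) on the full cohort
    rows_full = build_long_format(subjects, space, clock=clock)
    baseline_fits: dict[int, WeibullPHFit | None] = {}
    baseline_notes: dict[int, str] = {}
    for k in later:
        try:
            baseline_fits[k] = fit_transition(
                [r for r in rows_full if r.transition == k], [], transition=k
            )
        except FitError as exc:
            baseline_fits[k] = None
            baseline_notes[k] = f"fit skipped: {exc}"
    all_fits["baseline"] = baseline_fits
    all_notes["baseline"] = baseline_notes

    # hazard-ratio tables
    for family in model_spec:
        recs = []
        for k, fit in all_fits[family].items():
            if fit is None or fit.covariance is None:
                continue
            tab = hazard_ratios(fit)
            tab.insert(0, "transition", k)
            recs.append(tab)
        fname = f"fits_{family}.csv"
        if recs:
            pd.concat(recs, ignore_index=True).to_csv(out_dir / fname, index=False)
        else:
            pd.DataFrame(
                columns=["transition", "covariate", "HR", "CI_low", "CI_high", "p"]
            ).to_csv(out_dir / fname, index=False)
        manifest.append(fname)

    # AIC comparison
    aic_recs = []
    for family, fits in all_fits.items():
        if family == "baseline":
            continue
        for k, fit in fits.items():
            if fit is None:
                continue
            aic_recs.append(
                {
                    "transition": k,
                    "family": family,
                    "n_rows": fit.n_rows,
                    "n_events": fit.n_events,
                    "aic": aic(fit),
                }
            )
    aic_table = pd.DataFrame(
        aic_recs, columns=["transition", "family", "n_rows", "n_events", "aic"]
    )
    aic_table.to_csv(out_dir / "aic.csv", index=False)
    manifest.append("aic.csv")

    # prediction curves from the clinical model set (direct transitions
    # with clinical covariates, later transitions baseline-only)
    curve_fits: dict[int, WeibullPHFit] = {}
    complete = True
    for k in direct:
        f = all_fits["clinical"].get(k)
        if f is None:
            complete = False
        else:
            curve_fits[k] = f
    for k in later:
        f = baseline_fits.get(k)
        if f is None:
            complete = False
        else:
            curve_fits[k] = f

    if complete:
        model = ModelSet(space=space, fits=curve_fits)
        if times is None:
            times = np.linspace(0.0, 25.0, 101)
        clin_needed = list(model_spec["clinical"]["covariates"]) + list(
            model_spec["clinical"].get("adjusters") or []
        )
        profiles = pd.DataFrame(
            [{c: s.covariates.get(c, np.nan) for c in clin_needed} for s in subjects]
        ).dropna()
        occ = population_average_occupation(model, profiles, times)
        occ.to_frame().to_csv(out_dir / "curves" / "ode.csv", index=False)
        occ.occupation_frame().to_csv(out_dir / "occupation.csv", index=False)
        manifest += ["curves/ode.csv", "occupation.csv"]

        # simulated cross-check at the cohort-mean covariate profile
        mean_profile = profiles.mean().to_dict()
        sim = simulate_transition_probabilities(
            model, 0.0, times, mean_profile, n_paths=n_paths, seed=seed
        )
        sim.to_frame().to_csv(out_dir / "curves" / "sim.csv", index=False)
        manifest.append("curves/sim.csv")
        ode_ref = transition_probabilities_ode(model, 0.0, times, mean_profile)
        sim_vs_ode = float(np.max(np.abs(sim.P - ode_ref.P)))

        if make_plot:
            _stacked_plot(occ, out_dir / "occupation.png")
            manifest.append("occupation.png")
    else:
        occ = None
        sim_vs_ode = None

    metadata = {
        "seed": seed,
        "clock": clock,
        "n_subjects": len(subjects),
        "exclusions": exclusions,
        "sim_vs_ode_max_abs_diff": sim_vs_ode,
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "model_spec": model_spec,
                    "space": list(map(list, space.transitions)),
                    "seed": seed,
                    "clock": clock,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest(),
    }

    report = AnalysisReport(
        counts=counts,
        fits=all_fits,
        fit_notes=all_notes,
        aic_table=aic_table,
        manifest=manifest,
        metadata=metadata,
    )
    doc = report.to_dict()
    doc["content_hash"] = report.content_hash()
    with open(out_dir / "report.json", "w") as fh:
        json.dump(doc, fh, indent=2)
    return report


def _stacked_plot(curves, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bands = curves.stacked_bands()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    labels = [c for c in bands.columns if c != "time"]
    prev = np.zeros(len(bands))
    for lab in labels:
        ax.fill_between(bands["time"], prev, bands[lab], label=lab, alpha=0.8)
        prev = bands[lab].to_numpy()
    ax.set_xlabel("years since diagnosis")
    ax.set_ylabel("state occupation probability")
    ax.set_ylim(0, 1)
    ax.legend(loc="center left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
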