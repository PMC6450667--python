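"""End-to-end orchestration from simulated (or supplied) trial tables to
the full results bundle: exclusion, aggregate mixture fits, threshold
derivation, trial scoring, dependency statistics, background connectivity,
and memory-modulated gPPI — all seeded and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import circular, scoring, dependency, connectivity, gppi
from .synthgen import (
    StudyDesign, BehavioralParams, NeuralParams,
    generate_design, generate_behavior, generate_timeseries, write_ground_truth,
)

log = logging.getLogger("mnemonet")

DEFAULT_QUALITY_MODULATIONS = (
    # retrieval-quality coupling planted on hippocampus<->cortex pairs
    ("aHIPP", "PHC", "quality", 0.5),
    ("pHIPP", "RSC", "quality", 0.5),
    ("PRC", "aHIPP", "quality", 0.5),
)


@dataclass
class RunConfig:
    """Pipeline configuration; every stochastic step has an explicit seed."""

    out_dir: str = "out"
    profile: str = "small"  # small | full
    seed: int = 0
    thresholds: dict | str = "derive"  # {'color': .., 'scene': ..} or 'derive'
    quality_scaling: str = "threshold"
    connectivity_cut: float = 0.25
    louvain_restarts: int = 100
    louvain_seed: int = 0
    fdr_alpha: float = 0.05
    gppi_tails: str = "one"
    dependency_tails: str = "two"
    plant_modulations: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def design(self) -> StudyDesign:
        if self.profile == "full":
            return StudyDesign.full()
        if self.profile == "small":
            return StudyDesign.small()
        raise ValueError(f"unknown profile {self.profile!r}")


def simulate_cohort(config: RunConfig, with_timeseries: bool = True):
    """Generate the cohort's trial table and (optionally) per-subject time
    series under the configured profile and seed."""
    design = config.design()
    bparams = BehavioralParams()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2 + design.n_subjects)]
    trials = generate_design(design, seed=seeds[0])
    trials = generate_behavior(trials, bparams, seed=seeds[1])
    ts_sets = {}
    if with_timeseries:
        mods = DEFAULT_QUALITY_MODULATIONS if config.plant_modulations else ()
        for i, subject in enumerate(sorted(trials["subject"].unique())):
            nparams = NeuralParams(modulations=mods, seed=seeds[2 + i])
            ts_sets[subject] = generate_timeseries(
                trials[trials["subject"] == subject], nparams, design)
    return design, bparams, trials, ts_sets


def derive_thresholds(trials: pd.DataFrame) -> tuple[dict[str, float], dict]:
    """Aggregate mixture fits over included subjects -> per-feature
    success thresholds (posterior 0.5 crossing)."""
    thresholds, fits = {}, {}
    for feature in ("color", "scene"):
        err = circular.wrap_error(
            trials[f"resp_{feature}_deg"].to_numpy(),
            trials[f"target_{feature}_deg"].to_numpy())
        fit = circular.fit_mixture(err)
        thresholds[feature] = circular.success_threshold(fit)
        fits[feature] = fit
    return thresholds, fits


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> exclude -> aggregate-fit -> thresholds -> score ->
    dependency -> connectivity -> gppi -> report. Idempotent given seeds."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design, bparams, trials, ts_sets = simulate_cohort(config)
    nparams_repr = NeuralParams(
        modulations=DEFAULT_QUALITY_MODULATIONS if config.plant_modulations else ())
    write_ground_truth(out / "ground_truth.json", design, bparams, nparams_repr, config.seed)
    trials.to_csv(out / "trials.csv", index=False)

    # --- exclusion and aggregate behavioral fits -------------------------
    exclusion = scoring.exclude_subjects(trials)
    exclusion.to_csv(out / "exclusion.csv", index=False)
    included = set(exclusion.loc[exclusion["included"], "subject"])
    log.info("excluded %d of %d subjects", len(exclusion) - len(included), len(exclusion))
    trials_inc = trials[trials["subject"].isin(included)]

    if config.thresholds == "derive":
        thresholds, fits = derive_thresholds(trials_inc)
        fit_payload = {
            f: json.loads(fits[f].to_json(feature=f, threshold_deg=thresholds[f]))
            for f in fits
        }
    else:
        thresholds = dict(config.thresholds)
        fit_payload = {}
    log.info("thresholds: %s", thresholds)
    (out / "mixture_fits.json").write_text(json.dumps(
        {"thresholds_deg": thresholds, "fits": fit_payload}, indent=2))

    # --- scoring and dependency ------------------------------------------
    scored = scoring.score_trials(trials_inc, thresholds, config.quality_scaling)
    scoring.write_scores_csv(scored, out / "scores.csv")
    dep_table = dependency.subject_dependency_table(scored)
    dep_table.to_csv(out / "dependency.csv", index=False)
    dep_stats = dependency.group_dependency_stats(dep_table, tails=config.dependency_tails)
    dep_stats.to_csv(out / "dependency_stats.csv", index=False)

    # --- connectivity + gPPI per subject ----------------------------------
    metrics_rows, summaries, activity_tables = [], [], []
    matrices = {c: [] for c in connectivity.CONDITIONS}
    for subject, ts in sorted(ts_sets.items()):
        if subject not in included:
            continue
        sub_scored = scored[scored["subject"] == subject].reset_index(drop=True)
        ts = connectivity.ROITimeSeriesSet(
            data=ts.data, run_ids=ts.run_ids, roi_names=ts.roi_names,
            network_labels=ts.network_labels, tr=ts.tr,
            nuisance=ts.nuisance, trials=sub_scored)
        model = connectivity.build_event_model(sub_scored, design)

        bg = connectivity.denoise(ts, model, include_task=True, on_collinear="drop")
        row = {"subject": subject}
        row.update(connectivity.condition_metrics(
            bg, model, cut=config.connectivity_cut,
            louvain_seed=config.louvain_seed, n_restarts=config.louvain_restarts))
        metrics_rows.append(row)
        for cond in connectivity.CONDITIONS:
            matrices[cond].append(connectivity.threshold_matrix(
                connectivity.weighted_correlation_matrix(bg, model.weights[cond], cond),
                config.connectivity_cut))

        clean = connectivity.denoise(ts, model, include_task=False)
        quality_mod = gppi.build_quality_modulator(sub_scored, design)
        rem_box = gppi.build_remember_boxcar(sub_scored, design)
        result = gppi.gppi_matrix(clean, {"remember": rem_box, "quality": quality_mod})
        summaries.append(gppi.network_summary(result.betas["quality"], ts.network_labels))
        enc_box = model.regressors[:, model.names.index("encoding_box")]
        activity_tables.append(gppi.activity_glm(
            clean, {"encoding": enc_box, "remember": rem_box}, quality_mod))

    results = {"thresholds_deg": thresholds, "n_included": len(included)}
    if metrics_rows:
        metrics = pd.DataFrame(metrics_rows)
        metrics.to_csv(out / "connectivity_metrics.csv", index=False)
        comparison = connectivity.compare_conditions(metrics)
        comparison.to_csv(out / "connectivity_comparison.csv", index=False)
        for cond in connectivity.CONDITIONS:
            connectivity.group_average_matrix(matrices[cond]).to_frame().to_csv(
                out / f"group_matrix_{cond}.csv")
        gppi_stats = gppi.group_inference(
            summaries, tails=config.gppi_tails, alpha=config.fdr_alpha)
        gppi_stats.to_csv(out / "gppi_network_stats.csv", index=False)
        activity_stats = gppi.activity_group_stats(activity_tables, alpha=config.fdr_alpha)
        activity_stats.to_csv(out / "activity_stats.csv", index=False)
        results["comparison"] = comparison.to_dict("records")
        results["gppi_mean_beta"] = float(
            pd.concat(summaries)["mean_beta"].mean())

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "file_hashes": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json"))
            if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
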