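"""Generalized psychophysiological interaction (gPPI) models.

For a seed ROI s and target ROI t, the target time series is regressed on
run intercepts, the seed series, the psychological regressors (HRF-convolved
task/memory covariates) and the interaction of the seed with each
psychological regressor (elementwise product in BOLD space). The interaction
coefficient measures how seed->target coupling changes with the
psychological variable — here, trial-specific memory quality or feature
precision during 'remember' events. Collecting the coefficient over all
ordered ROI pairs yields an asymmetric effective-connectivity matrix per
subject, summarized at the network level (PM / AT / hippocampus) and tested
across subjects with one-tailed t tests and Benjamini-Hochberg FDR.

Also provides the univariate parametric-modulation GLM (ROI activity
regressed on event boxcars plus the quality modulator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .events import convolved_regressor, centered_modulator
from .synthgen import ROITimeSeriesSet, StudyDesign

NETWORK_ORDER = ("PM", "AT", "HIPP")


def build_quality_modulator(
    scored_trials: pd.DataFrame, design: StudyDesign
) -> np.ndarray:
    """Memory-quality parametric modulator over remember events.

    Per-trial 0-3 quality scores are mean-centered across all remember
    events, placed on the 6 s remember boxcars (zero elsewhere) and
    HRF-convolved at TR; runs are concatenated.
    """
    vals = centered_modulator(scored_trials["quality"].to_numpy())
    return _modulator_regressor(scored_trials, vals, design)


def build_precision_modulator(
    scored_trials: pd.DataFrame, feature: str, design: StudyDesign
) -> np.ndarray:
    """Feature-precision modulator, centered within correct trials only."""
    vals = centered_modulator(
        scored_trials[f"precision_{feature}"].to_numpy(),
        mask=scored_trials[f"success_{feature}"].to_numpy() == 1,
    )
    return _modulator_regressor(scored_trials, vals, design)


def build_remember_boxcar(scored_trials: pd.DataFrame, design: StudyDesign) -> np.ndarray:
    return _modulator_regressor(
        scored_trials, np.ones(len(scored_trials)), design)


def _modulator_regressor(trials: pd.DataFrame, values: np.ndarray,
                         design: StudyDesign) -> np.ndarray:
    parts = []
    for run in sorted(trials["run"].unique()):
        mask = (trials["run"] == run).to_numpy()
        parts.append(convolved_regressor(
            trials.loc[mask, "onset_remember_s"].to_numpy(),
            design.event_duration_s, values[mask],
            design.scans_per_run, design.tr_seconds))
    return np.concatenate(parts)


def _run_intercepts(run_ids: np.ndarray) -> tuple[np.ndarray, list[str]]:
    runs = np.unique(run_ids)
    cols = np.column_stack([(run_ids == r).astype(float) for r in runs])
    return cols, [f"run_{r}" for r in runs]


def fit_gppi(
    seed_ts: np.ndarray,
    target_ts: np.ndarray,
    psych: dict[str, np.ndarray],
    run_ids: np.ndarray,
) -> dict[str, dict[str, float]]:
    """One seed->target gPPI fit; returns interaction betas and SEs.

    Model: target ~ run intercepts + seed + each psych regressor + each
    seed x psych product. With several modulators in ``psych`` all enter
    one model, so each interaction beta is that modulator's unique
    contribution.
    """
    seed_ts = np.asarray(seed_ts, float)
    target_ts = np.asarray(target_ts, float)
    if seed_ts.shape != target_ts.shape:
        raise ValueError("seed and target series must have equal length")
    icols, inames = _run_intercepts(run_ids)
    names = inames + ["seed"]
    cols = [icols, seed_ts[:, None]]
    for name, reg in psych.items():
        if reg.shape[0] != seed_ts.shape[0]:
            raise ValueError(f"psych regressor {name!r} length mismatch")
        cols.append(np.asarray(reg, float)[:, None])
        names.append(f"psych_{name}")
    for name, reg in psych.items():
        cols.append((seed_ts * np.asarray(reg, float))[:, None])
        names.append(f"interaction_{name}")
    X = np.hstack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"gPPI design matrix rank-deficient ({rank} < {X.shape[1]})")
    beta, res_ss, *_ = np.linalg.lstsq(X, target_ts, rcond=None)
    dof = X.shape[0] - X.shape[1]
    resid = target_ts - X @ beta
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    out = {}
    for i, name in enumerate(names):
        if name.startswith("interaction_"):
            out[name.removeprefix("interaction_")] = {
                "beta": float(beta[i]), "se": float(se[i])}
    return out


@dataclass
class GPPIResult:
    """Per-subject seed x target interaction-beta matrices, one per modulator."""

    betas: dict[str, np.ndarray]  # modulator -> (n_roi, n_roi), diag nan
    roi_names: tuple[str, ...]
    network_labels: tuple[str, ...]


def gppi_matrix(
    ts: ROITimeSeriesSet,
    psych: dict[str, np.ndarray],
    seeds: list[str] | None = None,
) -> GPPIResult:
    """Fit the gPPI model for every ordered (seed, target) ROI pair.

    ``seeds`` restricts the seed set (e.g. the four representational seed
    regions); targets always span all other ROIs.
    """
    rois = list(ts.roi_names)
    seeds = rois if seeds is None else list(seeds)
    mats = {name: np.full((len(rois), len(rois)), np.nan) for name in psych}
    for seed_name in seeds:
        i = rois.index(seed_name)
        seed_sig = ts.data[:, i]
        for j, target_name in enumerate(rois):
            if j == i:
                continue
            fit = fit_gppi(seed_sig, ts.data[:, j], psych, ts.run_ids)
            for name, coef in fit.items():
                mats[name][i, j] = coef["beta"]
    return GPPIResult(betas=mats, roi_names=ts.roi_names,
                      network_labels=ts.network_labels)


def network_summary(beta_matrix: np.ndarray, network_labels) -> pd.DataFrame:
    """Mean interaction beta per ordered (seed network -> target network).

    Produces the 3x3 directed table over PM / AT / HIPP; the HIPP->HIPP
    cell is the within-hippocampus (anterior<->posterior) coupling.
    Diagonal ROI pairs are excluded.
    """
    labels = np.asarray(network_labels)
    rows = []
    for src in NETWORK_ORDER:
        for dst in NETWORK_ORDER:
            ii = np.flatnonzero(labels == src)
            jj = np.flatnonzero(labels == dst)
            vals = [beta_matrix[i, j] for i in ii for j in jj if i != j]
            vals = [v for v in vals if np.isfinite(v)]
            rows.append({
                "seed_network": src, "target_network": dst,
                "mean_beta": float(np.mean(vals)) if vals else np.nan,
                "n_pairs": len(vals),
            })
    return pd.DataFrame(rows)


def group_inference(
    summaries: list[pd.DataFrame],
    tails: str = "one",
    fdr: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sample t per network cell across subjects, with BH FDR.

    ``tails='one'`` tests the increase direction (better memory -> stronger
    coupling). FDR runs across the family of tested cells.
    """
    stacked = pd.concat(summaries, keys=range(len(summaries)), names=["subject_idx"])
    rows = []
    for (src, dst), grp in stacked.groupby(["seed_network", "target_network"], sort=False):
        vals = grp["mean_beta"].dropna().to_numpy()
        alternative = "greater" if tails == "one" else "two-sided"
        res = stats.ttest_1samp(vals, popmean=0.0, alternative=alternative)
        rows.append({
            "seed_network": src, "target_network": dst,
            "mean_beta": float(vals.mean()), "se": float(stats.sem(vals)),
            "t": float(res.statistic), "df": len(vals) - 1, "p": float(res.pvalue),
        })
    table = pd.DataFrame(rows)
    if fdr:
        reject, p_fdr, *_ = multipletests(table["p"], alpha=alpha, method="fdr_bh")
        table["p_fdr"] = p_fdr
        table["significant_fdr"] = reject
        table["significant_raw"] = table["p"] < alpha
    return table


def matrix_pattern_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher-z similarity of two beta matrices over finite off-diag cells."""
    mask = np.isfinite(a) & np.isfinite(b)
    np.fill_diagonal(mask, False)
    r, _ = stats.pearsonr(a[mask], b[mask])
    return float(np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7)))


def activity_glm(
    ts: ROITimeSeriesSet,
    event_regressors: dict[str, np.ndarray],
    quality_modulator: np.ndarray,
) -> pd.DataFrame:
    """Univariate parametric-modulation GLM, per ROI.

    Each ROI's series is regressed on run intercepts, the event boxcar
    regressors and the quality modulator; returns the modulator beta (and
    SE) per ROI.
    """
    icols, inames = _run_intercepts(ts.run_ids)
    names = inames + list(event_regressors) + ["quality"]
    X = np.hstack(
        [icols]
        + [np.asarray(r, float)[:, None] for r in event_regressors.values()]
        + [np.asarray(quality_modulator, float)[:, None]]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("activity GLM design matrix rank-deficient")
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    qi = names.index("quality")
    return pd.DataFrame({
        "roi": list(ts.roi_names),
        "network": list(ts.network_labels),
        "beta_quality": beta[qi],
        "se": se[qi],
    })


def activity_group_stats(tables: list[pd.DataFrame], alpha: float = 0.05) -> pd.DataFrame:
    """Group t (one-tailed) on per-ROI modulation betas with BH FDR."""
    stacked = pd.concat(tables)
    rows = []
    for roi, grp in stacked.groupby("roi", sort=False):
        vals = grp["beta_quality"].to_numpy()
        res = stats.ttest_1samp(vals, 0.0, alternative="greater")
        rows.append({"roi": roi, "network": grp["network"].iloc[0],
                     "mean_beta": float(vals.mean()),
                     "t": float(res.statistic), "df": len(vals) - 1,
                     "p": float(res.pvalue)})
    table = pd.DataFrame(rows)
    reject, p_fdr, *_ = multipletests(table["p"], alpha=alpha, method="fdr_bh")
    table["p_fdr"] = p_fdr
    table["significant_fdr"] = reject
    return table
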