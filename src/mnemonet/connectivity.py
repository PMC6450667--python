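"""Background functional connectivity and network metrics.

The background-connectivity pipeline removes task-evoked and nuisance
signal from each run (demean, linear detrend, high-pass at 1/128 Hz,
regression of nuisance and all task + memory regressors), concatenates the
residuals, and computes condition-specific HRF-weighted Pearson correlation
matrices between ROIs. Matrices are thresholded (entries below the cut set
to zero, weights retained) before graph metrics: Louvain modularity Q and
within- / between-network density. Encoding-vs-retrieval comparisons use
paired t tests and 1-df repeated-measures F tests computed from
within-subject contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .events import (
    convolved_regressor,
    centered_modulator,
    condition_weights,
    dct_highpass_basis,
)
from .dependency import fisher_z, group_ttest
from .synthgen import ROITimeSeriesSet, StudyDesign

CONDITIONS = ("encoding", "remember")
MODULATOR_NAMES = (
    "emotion_memory", "color_success", "scene_success",
    "color_precision", "scene_precision",
)


@dataclass
class EventModel:
    """Task + memory regressors at TR resolution, per run and concatenated.

    ``regressors`` is a (total scans, K) matrix; ``names`` labels columns
    as '<condition>_box' or '<condition>_<modulator>'. ``weights`` holds
    the per-condition nonnegative HRF weight vectors used for weighted
    correlations. ``raw`` keeps the pre-convolution per-trial modulator
    values for inspection.
    """

    regressors: np.ndarray
    names: list[str]
    run_ids: np.ndarray
    weights: dict[str, np.ndarray]
    raw: dict[str, np.ndarray]


def _modulator_values(scored: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-trial modulator values with the prescribed centering.

    Success-type modulators (emotion memory, color/scene success) are
    centered over all trials; precision modulators over correct trials of
    that feature, zero elsewhere.
    """
    out = {
        "emotion_memory": centered_modulator(scored["emotion_score"].to_numpy()),
        "color_success": centered_modulator(scored["success_color"].to_numpy()),
        "scene_success": centered_modulator(scored["success_scene"].to_numpy()),
    }
    for f in ("color", "scene"):
        out[f"{f}_precision"] = centered_modulator(
            scored[f"precision_{f}"].to_numpy(),
            mask=scored[f"success_{f}"].to_numpy() == 1,
        )
    return out


def build_event_model(scored_trials: pd.DataFrame, design: StudyDesign) -> EventModel:
    """Condition boxcars plus the five memory modulators per condition.

    ``scored_trials`` is one subject's trial table after scoring. Each
    condition (encoding, remember) gets a 6 s boxcar regressor and five
    parametric modulators, all HRF-convolved at TR within each run.
    """
    raw = _modulator_values(scored_trials)
    n = design.scans_per_run
    tr = design.tr_seconds
    runs = sorted(scored_trials["run"].unique())
    names = []
    for cond in CONDITIONS:
        names.append(f"{cond}_box")
        names.extend(f"{cond}_{m}" for m in MODULATOR_NAMES)

    blocks, run_ids = [], []
    for run in runs:
        mask = (scored_trials["run"] == run).to_numpy()
        cols = []
        for cond in CONDITIONS:
            onsets = scored_trials.loc[mask, f"onset_{cond if cond == 'encoding' else 'remember'}_s"].to_numpy()
            cols.append(convolved_regressor(
                onsets, design.event_duration_s, np.ones(mask.sum()), n, tr))
            for m in MODULATOR_NAMES:
                cols.append(convolved_regressor(
                    onsets, design.event_duration_s, raw[m][mask], n, tr))
        blocks.append(np.column_stack(cols))
        run_ids.append(np.full(n, run))

    weights = {}
    for cond in CONDITIONS:
        key = "onset_encoding_s" if cond == "encoding" else "onset_remember_s"
        onsets_by_run = [
            scored_trials.loc[scored_trials["run"] == r, key].to_numpy() for r in runs
        ]
        weights[cond] = condition_weights(onsets_by_run, design.event_duration_s, n, tr)

    return EventModel(
        regressors=np.vstack(blocks),
        names=names,
        run_ids=np.concatenate(run_ids),
        weights=weights,
        raw=raw,
    )


class CollinearityError(ValueError):
    pass


def _dependent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of columns linearly dependent on earlier ones (QR diagonal)."""
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.max() > 0 else 1.0
    return np.flatnonzero(diag / scale < 1e-10)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    bad = [names[i] for i in _dependent_columns(X)]
    if bad:
        raise CollinearityError(f"design matrix rank-deficient; offending columns: {bad}")


def denoise(
    ts: ROITimeSeriesSet,
    model: EventModel | None,
    include_task: bool = True,
    highpass_cutoff_s: float = 128.0,
    on_collinear: str = "raise",
) -> ROITimeSeriesSet:
    """Per-run residualization, residuals concatenated across runs.

    Each run is demeaned, linearly detrended, high-pass filtered at
    1/128 Hz (discrete cosine basis), and regressed against the nuisance
    regressors and — when ``include_task`` — all task and memory
    regressors, in one least-squares projection.

    A rank-deficient design raises :class:`CollinearityError` naming the
    offending columns; ``on_collinear='drop'`` instead removes dependent
    task/memory columns (a modulator constant within a short run duplicates
    the event boxcar) with a log warning.
    """
    if on_collinear not in ("raise", "drop"):
        raise ValueError("on_collinear must be 'raise' or 'drop'")
    resid = np.empty_like(ts.data)
    for run, idx in ts.run_slices():
        n = idx.size
        cols = [np.ones(n), np.linspace(-1, 1, n)]
        names = ["intercept", "trend"]
        dct = dct_highpass_basis(n, ts.tr, highpass_cutoff_s)
        cols.extend(dct.T)
        names.extend(f"dct_{i+1}" for i in range(dct.shape[1]))
        nuis = ts.nuisance[idx]
        cols.extend(nuis.T)
        names.extend(f"nuisance_{i+1}" for i in range(nuis.shape[1]))
        if include_task and model is not None:
            task = model.regressors[model.run_ids == run]
            cols.extend(task.T)
            names.extend(model.names)
        X = np.column_stack(cols)
        if on_collinear == "drop":
            bad = _dependent_columns(X)
            while bad.size:
                dropped = [names[i] for i in bad]
                logging.getLogger("mnemonet").warning(
                    "run %s: dropping collinear regressors %s", run, dropped)
                keep = np.setdiff1d(np.arange(X.shape[1]), bad)
                X = X[:, keep]
                names = [names[i] for i in keep]
                bad = _dependent_columns(X)
        _check_rank(X, names)
        beta, *_ = np.linalg.lstsq(X, ts.data[idx], rcond=None)
        resid[idx] = ts.data[idx] - X @ beta
    return ROITimeSeriesSet(
        data=resid, run_ids=ts.run_ids.copy(), roi_names=ts.roi_names,
        network_labels=ts.network_labels, tr=ts.tr,
        nuisance=ts.nuisance, trials=ts.trials,
    )


@dataclass
class ConnectivityMatrix:
    """ROI x ROI matrix with network labels; diagonal fixed at zero."""

    values: np.ndarray
    roi_names: tuple[str, ...]
    network_labels: tuple[str, ...]
    condition: str = ""
    symmetric: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.roi_names),
                            columns=list(self.roi_names))


def weighted_correlation_matrix(
    ts: ROITimeSeriesSet, weights: np.ndarray, condition: str = ""
) -> ConnectivityMatrix:
    """Weighted Pearson correlations between all ROI pairs.

    r_xy = sum w (x - xbar_w)(y - ybar_w) / sqrt(sum w (x - xbar_w)^2 *
    sum w (y - ybar_w)^2) with weighted means; equal weights reduce this to
    the ordinary Pearson correlation.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != ts.data.shape[0]:
        raise ValueError("weights length must equal number of scans")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not be all zero")
    w = w / total
    x = ts.data - w @ ts.data
    cov = (x * w[:, None]).T @ x
    var = np.diag(cov).copy()
    if np.any(var <= 0):
        flagged = [ts.roi_names[i] for i in np.flatnonzero(var <= 0)]
        raise ValueError(f"zero-variance ROI(s) under the given weights: {flagged}")
    denom = np.sqrt(np.outer(var, var))
    corr = cov / denom
    return ConnectivityMatrix(corr, ts.roi_names, ts.network_labels, condition)


def threshold_matrix(m: ConnectivityMatrix, cut: float) -> ConnectivityMatrix:
    """Zero every entry below ``cut``; surviving weights are retained."""
    if not -1.0 <= cut <= 1.0:
        raise ValueError("cut must lie in [-1, 1]")
    vals = np.where(m.values >= cut, m.values, 0.0)
    return ConnectivityMatrix(vals, m.roi_names, m.network_labels, m.condition, m.symmetric)


def modularity_q(values: np.ndarray, communities) -> float:
    """Newman weighted modularity of a partition at resolution 1."""
    g = _to_graph(values)
    if g.size(weight="weight") == 0:
        return 0.0
    return float(nx.community.modularity(g, communities, weight="weight"))


def _to_graph(values: np.ndarray) -> nx.Graph:
    n = values.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            w = values[i, j]
            if w > 0:
                g.add_edge(i, j, weight=float(w))
    return g


def louvain_modularity(
    m: ConnectivityMatrix, seed: int = 0, n_restarts: int = 100
) -> tuple[float, np.ndarray]:
    """Best-of-restarts Louvain partition of the thresholded weighted graph.

    Returns (Q, community labels). An empty graph (all zeros) defines Q = 0
    with singleton communities.
    """
    vals = m.values
    if np.any(vals < 0):
        raise ValueError("louvain_modularity requires nonnegative weights")
    g = _to_graph(vals)
    if g.size(weight="weight") == 0:
        return 0.0, np.arange(vals.shape[0])
    ss = np.random.SeedSequence(seed)
    best_q, best_part = -np.inf, None
    for child in ss.spawn(n_restarts):
        part = nx.community.louvain_communities(
            g, weight="weight", seed=int(child.generate_state(1)[0] % (2**31))
        )
        q = nx.community.modularity(g, part, weight="weight")
        if q > best_q:
            best_q, best_part = q, part
    labels = np.empty(vals.shape[0], dtype=int)
    for ci, comm in enumerate(best_part):
        for node in comm:
            labels[node] = ci
    return float(best_q), labels


def network_density(
    m: ConnectivityMatrix, include_zeros: bool = True
) -> dict[str, float]:
    """Mean connection strength within and between networks.

    By default the mean runs over all ROI pairs, counting thresholded-out
    (zero) entries; ``include_zeros=False`` averages surviving edges only.
    """
    labels = np.asarray(m.network_labels)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = m.values[iu]
    out = {}
    for key, mask in (("within", same), ("between", ~same)):
        v = vals[mask]
        if not include_zeros:
            v = v[v > 0]
        out[key] = float(v.mean()) if v.size else float("nan")
    return out


def condition_metrics(
    ts_denoised: ROITimeSeriesSet,
    model: EventModel,
    cut: float = 0.25,
    louvain_seed: int = 0,
    n_restarts: int = 100,
) -> dict[str, float]:
    """Per-subject Q and density for both conditions at one threshold."""
    out = {}
    for cond in CONDITIONS:
        mat = weighted_correlation_matrix(ts_denoised, model.weights[cond], cond)
        thr = threshold_matrix(mat, cut)
        q, _ = louvain_modularity(thr, seed=louvain_seed, n_restarts=n_restarts)
        dens = network_density(thr)
        out[f"Q_{cond}"] = q
        out[f"within_{cond}"] = dens["within"]
        out[f"between_{cond}"] = dens["between"]
    return out


def compare_conditions(metrics: pd.DataFrame) -> pd.DataFrame:
    """Group statistics for the encoding-vs-retrieval comparison.

    Expects one row per subject with columns Q_encoding, Q_remember,
    within_encoding, within_remember, between_encoding, between_remember.
    Returns the paired t on modularity and the 2 (task) x 2 (within/
    between) repeated-measures F tests, each 1-df F computed as the squared
    paired t of the corresponding within-subject contrast.
    """
    rows = []
    dq = metrics["Q_remember"] - metrics["Q_encoding"]
    t_mod = group_ttest(dq, mu0=0.0, tails="two")
    rows.append({"effect": "modularity_remember_minus_encoding",
                 "stat": "t", "value": t_mod["t"], "df": t_mod["df"], "p": t_mod["p"],
                 "mean": t_mod["mean"]})

    task = (metrics["within_remember"] + metrics["between_remember"]) / 2 \
        - (metrics["within_encoding"] + metrics["between_encoding"]) / 2
    network = (metrics["within_remember"] + metrics["within_encoding"]) / 2 \
        - (metrics["between_remember"] + metrics["between_encoding"]) / 2
    interaction = (metrics["between_remember"] - metrics["between_encoding"]) \
        - (metrics["within_remember"] - metrics["within_encoding"])
    for name, contrast in (
        ("density_task_main", task),
        ("density_network_main", network),
        ("density_interaction_between_vs_within", interaction),
    ):
        t = group_ttest(contrast, mu0=0.0, tails="two")
        rows.append({"effect": name, "stat": "F", "value": t["t"] ** 2,
                     "df": t["df"], "p": t["p"], "mean": t["mean"]})
    return pd.DataFrame(rows)


def group_average_matrix(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Fisher-z average of per-subject correlation matrices (back in r)."""
    zs = []
    for m in matrices:
        z = np.vectorize(fisher_z)(m.values)
        np.fill_diagonal(z, 0.0)
        zs.append(z)
    mean_z = np.mean(zs, axis=0)
    first = matrices[0]
    return ConnectivityMatrix(np.tanh(mean_z), first.roi_names,
                              first.network_labels, first.condition)
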