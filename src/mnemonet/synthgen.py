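"""Synthetic study generator: behavioral trial tables and ROI time series
with known ground truth.

Emulates a continuous-report episodic memory experiment: subjects encode
object-scene-sound events (a color from a 360-degree wheel, a location in a
360-degree panorama, a negative or neutral sound) over study-test blocks,
then reconstruct each feature. Response errors follow a von Mises + uniform
mixture with feature-specific concentration and guess rate; a shared
per-trial latent memory state plants an across-feature success dependency
while leaving precision independent. ROI time series are BOLD-like multi-run
signals with block-structured network covariance, HRF-convolved event
responses, optional retrieval-specific between-network coupling, and planted
seed x modulator interaction terms for effective-connectivity recovery
tests.

Every stochastic operation takes an explicit integer seed; generation is
bit-reproducible given (seed, params).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .circular import wrap_degrees
from .events import convolved_regressor, centered_modulator
from . import scoring

DEFAULT_ROIS = (
    # posterior-medial (PM) system
    "ANG", "PREC", "PCC", "RSC", "PHC",
    # anterior-temporal (AT) system
    "PRC", "AMYG", "FUS", "ITC", "OFC",
    # hippocampus, anterior / posterior
    "aHIPP", "pHIPP",
)
DEFAULT_NETWORKS = ("PM",) * 5 + ("AT",) * 5 + ("HIPP",) * 2

# thresholds used when planting modulator ground truth (degrees)
PLANT_THRESHOLDS = {"color": 57.0, "scene": 30.0}


class ConstraintError(ValueError):
    """Raised when the within-block angular separation is infeasible."""


@dataclass(frozen=True)
class StudyDesign:
    """Dimensions and timing of the (synthetic) study.

    The full profile matches a 28-subject design: 6 study-test blocks of 24
    trials (144 events), 12 bilateral ROIs over PM / AT / hippocampus, one
    scan run per block of 466 volumes at TR 1.5 s, 6 s events, and a
    45-degree minimum within-block separation for same-panorama features.
    """

    n_subjects: int = 28
    n_blocks: int = 6
    trials_per_block: int = 24
    n_panoramas: int = 6
    roi_names: tuple[str, ...] = DEFAULT_ROIS
    network_labels: tuple[str, ...] = DEFAULT_NETWORKS
    tr_seconds: float = 1.5
    scans_per_run: int = 466
    event_duration_s: float = 6.0
    min_separation_deg: float = 45.0
    encoding_start_s: float = 10.0
    encoding_spacing_s: float = 7.0
    remember_gap_s: float = 20.0
    remember_spacing_s: float = 20.0

    def __post_init__(self):
        if not 0 < self.min_separation_deg <= 180:
            raise ValueError("min_separation_deg must lie in (0, 180]")
        if len(self.roi_names) != len(self.network_labels):
            raise ValueError("one network label per ROI required")
        last = self.remember_onset(self.trials_per_block - 1) + self.event_duration_s
        if last > self.run_duration_s:
            raise ValueError(
                f"events end at {last:.1f}s but runs last {self.run_duration_s:.1f}s"
            )

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def run_duration_s(self) -> float:
        return self.scans_per_run * self.tr_seconds

    def encoding_onset(self, idx: int) -> float:
        return self.encoding_start_s + idx * self.encoding_spacing_s

    def remember_onset(self, idx: int) -> float:
        start = self.encoding_onset(self.trials_per_block - 1) + self.event_duration_s
        return start + self.remember_gap_s + idx * self.remember_spacing_s

    @classmethod
    def full(cls) -> "StudyDesign":
        return cls()

    @classmethod
    def small(cls) -> "StudyDesign":
        """Fast test profile: 4 subjects, 2 runs x 120 scans, 6 trials each."""
        return cls(
            n_subjects=4,
            n_blocks=2,
            trials_per_block=6,
            scans_per_run=120,
            encoding_start_s=4.0,
            remember_gap_s=8.0,
            remember_spacing_s=18.0,
        )


@dataclass(frozen=True)
class BehavioralParams:
    """Ground-truth behavioral generating parameters.

    ``k_*`` and ``gamma_*`` are the von Mises concentration and guess rate
    of each visual feature's error mixture; defaults follow the regime of a
    real cohort (color k 5.4 / gamma 0.33, scene k 27 / gamma 0.36; emotion
    correct 0.76). ``dependency_strength`` shifts each feature's in-memory
    probability by +/- its value according to a shared per-trial Bernoulli
    latent state, planting success dependency while leaving precision (k)
    uncoupled across features.
    """

    k_color: float = 5.4
    k_scene: float = 27.0
    gamma_color: float = 0.33
    gamma_scene: float = 0.36
    p_emotion_correct: float = 0.76
    p_high_confidence: float = 0.70
    dependency_strength: float = 0.15

    def __post_init__(self):
        for name in ("gamma_color", "gamma_scene", "p_emotion_correct", "p_high_confidence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.k_color <= 0 or self.k_scene <= 0:
            raise ValueError("concentrations must be > 0")
        if not 0.0 <= self.dependency_strength <= 0.5:
            raise ValueError("dependency_strength must lie in [0, 0.5]")


@dataclass(frozen=True)
class NeuralParams:
    """Ground-truth neural generating parameters (simulation plumbing).

    The latent ROI covariance has 1 on the diagonal, ``within_cov`` inside a
    network block and ``between_cov`` across networks;
    ``retrieval_between_boost`` is added to between-network covariance
    during remember-event windows. ``modulations`` plants gPPI-style
    interaction terms: (seed_roi, target_roi, modulator, beta) where
    modulator is 'quality', 'precision_color' or 'precision_scene'.
    """

    within_cov: float = 0.6
    between_cov: float = 0.1
    retrieval_between_boost: float = 0.2
    noise_sd: float = 0.5
    event_amplitude: float = 1.0
    hrf_kind: str = "glover"
    nuisance_count: int = 6
    nuisance_loading: float = 0.3
    modulations: tuple[tuple[str, str, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _min_circular_sep(values: np.ndarray) -> float:
    d = np.abs(wrap_degrees(values[:, None] - values[None, :]))
    np.fill_diagonal(d, np.inf)
    return float(d.min()) if d.size > 1 else np.inf


def _sample_separated(rng, m: int, min_sep: float, max_tries: int = 2000) -> np.ndarray:
    """Rejection-sample m angles in [0, 360) with min pairwise circular
    separation; raises ConstraintError when infeasible."""
    if m * min_sep > 360.0:
        raise ConstraintError(
            f"{m} angles with >= {min_sep} degree separation do not fit on the circle"
        )
    if m == 1:
        return rng.uniform(0, 360, size=1)
    for _ in range(max_tries):
        vals = rng.uniform(0, 360, size=m)
        if _min_circular_sep(vals) >= min_sep:
            return vals
    # fall back to a jittered even spacing, always feasible
    slack = (360.0 - m * min_sep) / m
    base = np.arange(m) * (min_sep + slack)
    return wrap_degrees(base + rng.uniform(0, slack, size=m) + rng.uniform(0, 360)) % 360.0


def generate_design(design: StudyDesign, seed: int) -> pd.DataFrame:
    """Trial table with target angles, valence, panoramas and onsets.

    Within each block, same-panorama trials are at least
    ``min_separation_deg`` apart in both color and panorama location, and
    valence (negative=1 / neutral=0) is balanced.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for subject in range(1, design.n_subjects + 1):
        for block in range(1, design.n_blocks + 1):
            tpb = design.trials_per_block
            reps = int(np.ceil(tpb / design.n_panoramas))
            panoramas = np.tile(np.arange(1, design.n_panoramas + 1), reps)[:tpb]
            rng.shuffle(panoramas)
            valence = np.zeros(tpb, dtype=int)
            valence[: tpb // 2] = 1
            rng.shuffle(valence)
            colors = np.empty(tpb)
            scenes = np.empty(tpb)
            for p in np.unique(panoramas):
                idx = np.flatnonzero(panoramas == p)
                colors[idx] = _sample_separated(rng, idx.size, design.min_separation_deg)
                scenes[idx] = _sample_separated(rng, idx.size, design.min_separation_deg)
            for t in range(tpb):
                rows.append({
                    "subject": subject,
                    "block": block,
                    "trial": t + 1,
                    "run": block,
                    "panorama": int(panoramas[t]),
                    "valence": int(valence[t]),
                    "target_color_deg": colors[t] % 360.0,
                    "target_scene_deg": scenes[t] % 360.0,
                    "onset_encoding_s": design.encoding_onset(t),
                    "onset_remember_s": design.remember_onset(t),
                })
    return pd.DataFrame(rows)


def generate_behavior(trials: pd.DataFrame, params: BehavioralParams, seed: int) -> pd.DataFrame:
    """Draw responses from the mixture with a planted latent memory state.

    Each trial has a Bernoulli(0.5) latent state shifting every feature's
    in-memory probability by +/- dependency_strength. In-memory responses
    are von Mises around the target; otherwise uniform on the circle.
    Wrapped errors are stored in (-180, 180].
    """
    rng = np.random.default_rng(seed)
    out = trials.copy()
    n = len(out)
    state = rng.random(n) < 0.5
    shift = params.dependency_strength * np.where(state, 1.0, -1.0)

    for feature, k, gamma in (
        ("color", params.k_color, params.gamma_color),
        ("scene", params.k_scene, params.gamma_scene),
    ):
        p_mem = np.clip((1.0 - gamma) + shift, 0.0, 1.0)
        in_mem = rng.random(n) < p_mem
        vm = np.rad2deg(rng.vonmises(0.0, k, size=n))
        guess = rng.uniform(-180.0, 180.0, size=n)
        err = np.where(in_mem, vm, guess)
        err = wrap_degrees(err)
        out[f"resp_{feature}_deg"] = (out[f"target_{feature}_deg"].to_numpy() + err) % 360.0
        out[f"true_mem_{feature}"] = in_mem.astype(int)

    p_emo = np.clip(params.p_emotion_correct + shift, 0.0, 1.0)
    out["emotion_correct"] = (rng.random(n) < p_emo).astype(int)
    out["emotion_confidence"] = (rng.random(n) < params.p_high_confidence).astype(int)
    out["true_state"] = state.astype(int)
    return out


@dataclass
class ROITimeSeriesSet:
    """Multi-run ROI time series with companions.

    ``data`` is (total scans, n_rois); ``run_ids`` marks run membership;
    ``nuisance`` holds simulated confound regressors; ``trials`` is the
    subject's trial table (onsets, scores) used to build event models.
    """

    data: np.ndarray
    run_ids: np.ndarray
    roi_names: tuple[str, ...]
    network_labels: tuple[str, ...]
    tr: float
    nuisance: np.ndarray
    trials: pd.DataFrame

    @property
    def runs(self) -> np.ndarray:
        return np.unique(self.run_ids)

    def run_slices(self):
        for r in self.runs:
            yield r, np.flatnonzero(self.run_ids == r)

    def write_tsv(self, ts_path, nuisance_path=None) -> None:
        df = pd.DataFrame(self.data, columns=list(self.roi_names))
        df.insert(0, "run", self.run_ids)
        df.to_csv(ts_path, sep="\t", index=False)
        if nuisance_path is not None:
            nz = pd.DataFrame(
                self.nuisance,
                columns=[f"nuisance_{i+1}" for i in range(self.nuisance.shape[1])],
            )
            nz.insert(0, "run", self.run_ids)
            nz.to_csv(nuisance_path, sep="\t", index=False)


def network_covariance(labels, within: float, between: float) -> np.ndarray:
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, within, between)
    np.fill_diagonal(cov, 1.0)
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-10:
        raise ValueError(
            f"implied ROI covariance is not positive semi-definite (min eig {eig.min():.3g})"
        )
    return cov


def _plant_modulator_series(trials_run, modulator: str, n_scans: int, tr: float,
                            duration: float) -> np.ndarray:
    """Ground-truth modulator regressor for one run (convolved, centered)."""
    scored = scoring.score_trials(trials_run, PLANT_THRESHOLDS)
    onsets = scored["onset_remember_s"].to_numpy()
    if modulator == "quality":
        vals = centered_modulator(scored["quality"].to_numpy())
    elif modulator in ("precision_color", "precision_scene"):
        f = modulator.split("_")[1]
        vals = centered_modulator(
            scored[f"precision_{f}"].to_numpy(), mask=scored[f"success_{f}"].to_numpy() == 1
        )
    else:
        raise ValueError(f"unknown modulator {modulator!r}")
    return convolved_regressor(onsets, duration, vals, n_scans, tr)


def generate_timeseries(
    trials: pd.DataFrame, nparams: NeuralParams, design: StudyDesign
) -> ROITimeSeriesSet:
    """Simulate one subject's multi-run ROI time series.

    Per run: ROI signals = network-structured latent noise + HRF-convolved
    event responses + planted seed x modulator interaction terms + nuisance
    contamination + white noise. During remember-event windows (onset to
    onset + duration + 5 s hemodynamic lag) the between-network covariance
    is raised by ``retrieval_between_boost``.
    """
    subjects = trials["subject"].unique()
    if len(subjects) != 1:
        raise ValueError("generate_timeseries expects a single subject's trials")
    rng = np.random.default_rng(nparams.seed)
    labels = design.network_labels
    cov_base = network_covariance(labels, nparams.within_cov, nparams.between_cov)
    cov_rem = network_covariance(
        labels,
        nparams.within_cov,
        min(nparams.between_cov + nparams.retrieval_between_boost, nparams.within_cov),
    )
    chol_base = np.linalg.cholesky(cov_base + 1e-12 * np.eye(design.n_rois))
    chol_rem = np.linalg.cholesky(cov_rem + 1e-12 * np.eye(design.n_rois))
    roi_index = {name: i for i, name in enumerate(design.roi_names)}

    data_runs, nuis_runs, run_ids = [], [], []
    n = design.scans_per_run
    times = np.arange(n) * design.tr_seconds
    for run in sorted(trials["run"].unique()):
        sub = trials[trials["run"] == run]
        z = rng.standard_normal((n, design.n_rois))
        latent = z @ chol_base.T
        rem_mask = np.zeros(n, dtype=bool)
        for onset in sub["onset_remember_s"]:
            rem_mask |= (times >= onset) & (times < onset + design.event_duration_s + 5.0)
        latent[rem_mask] = z[rem_mask] @ chol_rem.T

        enc = convolved_regressor(
            sub["onset_encoding_s"].to_numpy(), design.event_duration_s,
            np.ones(len(sub)), n, design.tr_seconds)
        rem = convolved_regressor(
            sub["onset_remember_s"].to_numpy(), design.event_duration_s,
            np.ones(len(sub)), n, design.tr_seconds)
        signal = latent + nparams.event_amplitude * (enc + rem)[:, None]
        signal = signal + nparams.noise_sd * rng.standard_normal((n, design.n_rois))

        # planted effective-connectivity interactions, formed on the noisy
        # (BOLD-space) seed signal as in the gPPI convention being emulated
        for seed_roi, target_roi, modulator, beta in nparams.modulations:
            mod = _plant_modulator_series(sub, modulator, n, design.tr_seconds,
                                          design.event_duration_s)
            seed_sig = signal[:, roi_index[seed_roi]]
            signal[:, roi_index[target_roi]] = (
                signal[:, roi_index[target_roi]] + beta * seed_sig * mod
            )

        nuis = np.cumsum(rng.standard_normal((n, nparams.nuisance_count)), axis=0)
        nuis = (nuis - nuis.mean(0)) / np.maximum(nuis.std(0), 1e-12)
        loadings = rng.normal(0.0, nparams.nuisance_loading,
                              size=(nparams.nuisance_count, design.n_rois))
        signal = signal + nuis @ loadings

        data_runs.append(signal)
        nuis_runs.append(nuis)
        run_ids.append(np.full(n, run))

    return ROITimeSeriesSet(
        data=np.vstack(data_runs),
        run_ids=np.concatenate(run_ids),
        roi_names=design.roi_names,
        network_labels=design.network_labels,
        tr=design.tr_seconds,
        nuisance=np.vstack(nuis_runs),
        trials=trials.reset_index(drop=True),
    )


def write_ground_truth(path, design: StudyDesign, bparams: BehavioralParams,
                       nparams: NeuralParams, seed: int) -> None:
    """JSON sidecar recording every ground-truth generating parameter."""
    payload = {
        "seed": seed,
        "design": asdict(design),
        "behavioral": asdict(bparams),
        "neural": asdict(nparams),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=list)
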