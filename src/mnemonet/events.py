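"""Event regressor construction at TR resolution.

Events (encoding and 'remember' periods) are modelled as boxcars convolved
with the canonical double-gamma hemodynamic response function (HRF).
Parametric modulators place a per-trial value on the event's boxcar before
convolution; success-type modulators are mean-centered over all trials of
the condition and precision modulators over correct trials only (zero on
incorrect trials), so each convolved covariate carries only the
trial-to-trial variation of interest.
"""

from __future__ import annotations

import numpy as np
from nilearn.glm.first_level.hemodynamic_models import compute_regressor

HRF_MODEL = "glover"  # canonical double-gamma: peak ~6 s, undershoot ~16 s


def convolved_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    n_scans: int,
    tr: float,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at TR, for one run.

    Events with zero amplitude are kept (they contribute nothing) so the
    caller can pass centered modulator values directly.
    """
    onsets = np.asarray(onsets, dtype=float)
    durations = np.broadcast_to(np.asarray(durations, dtype=float), onsets.shape)
    amplitudes = np.asarray(amplitudes, dtype=float)
    frame_times = np.arange(n_scans) * tr
    if onsets.size == 0 or not np.any(amplitudes):
        return np.zeros(n_scans)
    reg, _ = compute_regressor(
        (onsets, durations, amplitudes), HRF_MODEL, frame_times, oversampling=16
    )
    return reg[:, 0]


def centered_modulator(values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Mean-center ``values`` within ``mask`` (all trials when None).

    Entries outside the mask are set to zero — precision modulators are
    defined only on correct trials.
    """
    v = np.asarray(values, dtype=float).copy()
    if mask is None:
        return v - np.nanmean(v)
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(v)
    if mask.any():
        out[mask] = v[mask] - np.nanmean(v[mask])
    return np.nan_to_num(out)


def condition_weights(
    onsets_by_run: list[np.ndarray],
    duration: float,
    n_scans: int,
    tr: float,
) -> np.ndarray:
    """Nonnegative HRF weights for one task condition, concatenated runs.

    The condition's event boxcar is convolved with the HRF, negative lobes
    are clipped to zero, and the vector is normalized to sum to 1.
    """
    parts = []
    for onsets in onsets_by_run:
        reg = convolved_regressor(onsets, duration, np.ones(len(onsets)), n_scans, tr)
        parts.append(np.clip(reg, 0.0, None))
    w = np.concatenate(parts)
    total = w.sum()
    if total <= 0:
        raise ValueError("condition weights are all zero")
    return w / total


def dct_highpass_basis(n_scans: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete cosine basis spanning drifts slower than ``cutoff_s``.

    Returns an (n_scans, K) matrix with K = floor(2 * n_scans * tr /
    cutoff_s) cosine functions (the constant term is excluded; the caller
    adds an intercept). Regressing these out implements high-pass filtering
    at 1/cutoff_s Hz as a least-squares projection.
    """
    n_basis = int(np.floor(2.0 * n_scans * tr / cutoff_s))
    t = np.arange(n_scans)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2 * n_scans)) for k in range(1, n_basis + 1)
    ]
    if not cols:
        return np.zeros((n_scans, 0))
    return np.column_stack(cols)
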