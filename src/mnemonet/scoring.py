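"""Trial-level memory scoring: success classification, precision, the 0-3
composite quality score, and chance-level subject exclusion.

Color and scene responses are classified correct when the wrapped absolute
error falls at or under a feature-specific threshold (derived from the
aggregate mixture fit, or fixed). Precision of a correct trial is the
reversed absolute error, 180 - |error|, so higher = more precise. The
composite quality score sums an emotion term (0 / 0.5 / 1 for incorrect /
low-confidence correct / high-confidence correct) with one term per visual
feature scaled to [0, 1]: 0 when unsuccessful, 1 - |error|/threshold
otherwise (an error of 0 scores 1; an error at the threshold scores 0),
giving a trial total in [0, 3].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circular import wrap_error

FEATURES = ("color", "scene")
EXCLUSION_MEAN_ABS_ERROR = 75.0  # degrees; at-chance performance is 90


def _errors(trials: pd.DataFrame, feature: str) -> pd.Series:
    resp = trials[f"resp_{feature}_deg"]
    targ = trials[f"target_{feature}_deg"]
    ok = resp.notna() & targ.notna()
    err = pd.Series(np.nan, index=trials.index, dtype=float)
    err[ok] = wrap_error(resp[ok].to_numpy(), targ[ok].to_numpy())
    return err


def classify_trials(trials: pd.DataFrame, thresholds: dict[str, float]) -> pd.DataFrame:
    """Attach per-trial success flags and the 0/0.5/1 emotion score.

    ``thresholds`` maps feature name ('color', 'scene') to a threshold in
    (0, 180] degrees; the boundary is inclusive (an error exactly at the
    threshold is correct). Missing responses classify as unsuccessful and
    are flagged in ``missing_<feature>``.
    """
    for f in FEATURES:
        t = thresholds[f]
        if not 0.0 < t <= 180.0:
            raise ValueError(f"threshold for {f} must lie in (0, 180], got {t}")
    out = trials.copy()
    for f in FEATURES:
        err = _errors(out, f)
        out[f"error_{f}_deg"] = err
        out[f"missing_{f}"] = err.isna()
        out[f"success_{f}"] = ((err.abs() <= thresholds[f]) & err.notna()).astype(int)
    correct = out["emotion_correct"].fillna(0).astype(bool)
    high = out["emotion_confidence"].fillna(0).astype(bool)
    out["emotion_score"] = np.where(correct, np.where(high, 1.0, 0.5), 0.0)
    return out


def precision_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Reversed absolute error, 180 - |error|, on successful trials only.

    Unsuccessful trials get NaN — precision is undefined when the response
    is classified as a guess.
    """
    out = scores.copy()
    for f in FEATURES:
        prec = 180.0 - out[f"error_{f}_deg"].abs()
        out[f"precision_{f}"] = prec.where(out[f"success_{f}"] == 1)
    return out


def memory_quality(
    scores: pd.DataFrame,
    thresholds: dict[str, float],
    scaling: str = "threshold",
) -> pd.DataFrame:
    """Per-trial composite memory quality in [0, 3].

    quality = emotion_score + q_color + q_scene, where q_f = 0 on
    unsuccessful trials and otherwise scales the error into [0, 1]:
    ``scaling='threshold'`` uses 1 - |error|/threshold (continuous at the
    classification boundary, the default); ``scaling='range180'`` uses
    1 - |error|/180.
    """
    if scaling not in ("threshold", "range180"):
        raise ValueError(f"unknown scaling {scaling!r}")
    out = scores.copy()
    quality = out["emotion_score"].astype(float).copy()
    for f in FEATURES:
        denom = thresholds[f] if scaling == "threshold" else 180.0
        q = (1.0 - out[f"error_{f}_deg"].abs() / denom).clip(lower=0.0)
        q = q.where(out[f"success_{f}"] == 1, 0.0)
        out[f"quality_{f}"] = q
        quality = quality + q
    out["quality"] = quality
    return out


def score_trials(
    trials: pd.DataFrame,
    thresholds: dict[str, float],
    scaling: str = "threshold",
) -> pd.DataFrame:
    """Classification + precision + quality in one pass."""
    return memory_quality(precision_scores(classify_trials(trials, thresholds)), thresholds, scaling)


def exclude_subjects(trials: pd.DataFrame, cutoff: float = EXCLUSION_MEAN_ABS_ERROR) -> pd.DataFrame:
    """Flag subjects whose color or scene mean absolute error is at chance.

    A subject is excluded when mean |wrapped error| >= ``cutoff`` (default
    75 degrees; uniform guessing gives an expected 90) on either visual
    feature. Returns a per-subject table with the mean errors and an
    ``included`` flag.
    """
    rows = []
    for subject, sub in trials.groupby("subject"):
        means = {}
        for f in FEATURES:
            err = _errors(sub, f)
            means[f"mean_abs_error_{f}"] = float(err.abs().mean())
        excluded = any(means[f"mean_abs_error_{f}"] >= cutoff for f in FEATURES)
        rows.append({"subject": subject, **means, "included": not excluded})
    return pd.DataFrame(rows)


def write_scores_csv(scores: pd.DataFrame, path) -> None:
    cols = [
        "subject", "block", "trial",
        "success_color", "success_scene", "emotion_score",
        "precision_color", "precision_scene", "quality",
    ]
    scores[cols].to_csv(path, index=False)
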