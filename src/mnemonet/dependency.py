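"""Feature-binding dependency statistics and precision correlations.

Whether episodic features are remembered together beyond what independent
retrieval would predict is quantified by the corrected dependency: with
binary success outcomes A and B across trials,

    observed  = P(AB) + P(A'B')          (remembered or forgotten together)
    expected  = P(A)P(B) + P(A')P(B')    (independent model)
    corrected = observed - expected

Precision relationships use Pearson correlations (Fisher z transformed)
between the precision of correctly remembered features and the success of
the other feature, and between the two precisions on trials where both
features were correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_R_CLIP = 1.0 - 1e-7

FEATURE_PAIRS = (("emotion", "color"), ("emotion", "scene"), ("color", "scene"))


@dataclass(frozen=True)
class DependencyResult:
    pair: str
    observed: float
    expected: float
    corrected: float


def corrected_dependency(success_a, success_b, pair: str = "") -> DependencyResult:
    """Observed vs independent-model dependency of two binary outcomes."""
    a = np.asarray(success_a, dtype=float)
    b = np.asarray(success_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 trials")
    p_a, p_b = a.mean(), b.mean()
    observed = float(np.mean((a == 1) & (b == 1)) + np.mean((a == 0) & (b == 0)))
    expected = float(p_a * p_b + (1 - p_a) * (1 - p_b))
    return DependencyResult(pair=pair, observed=observed, expected=expected,
                            corrected=observed - expected)


def fisher_z(r: float) -> float:
    """atanh with clipping so degenerate perfect correlations stay finite."""
    return float(np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP)))


def _corr_z(x: np.ndarray, y: np.ndarray, min_n: int = 3) -> tuple[float, int]:
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_n or np.std(x[mask]) == 0 or np.std(y[mask]) == 0:
        return np.nan, n
    r, _ = stats.pearsonr(x[mask], y[mask])
    return fisher_z(r), n


def precision_correlations(scores: pd.DataFrame) -> dict[str, float]:
    """Fisher-z precision/success correlations for one subject's trials.

    Returns z values for: color precision (on color-correct trials) vs
    scene success; scene precision vs color success; and color vs scene
    precision restricted to trials where both features were correct. NaN
    with a reported count when fewer than 3 usable trials.
    """
    pc = scores["precision_color"].to_numpy(dtype=float)
    ps = scores["precision_scene"].to_numpy(dtype=float)
    sc = scores["success_color"].to_numpy(dtype=float)
    ss = scores["success_scene"].to_numpy(dtype=float)

    z_pc_ss, n1 = _corr_z(pc, ss)
    z_ps_sc, n2 = _corr_z(ps, sc)
    both = (sc == 1) & (ss == 1)
    z_pp, n3 = _corr_z(np.where(both, pc, np.nan), np.where(both, ps, np.nan))
    return {
        "z_color_precision_scene_success": z_pc_ss, "n_color_precision_scene_success": n1,
        "z_scene_precision_color_success": z_ps_sc, "n_scene_precision_color_success": n2,
        "z_precision_precision": z_pp, "n_precision_precision": n3,
    }


def subject_dependency_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-subject corrected dependency (all feature pairs) + precision z's.

    Emotion success for dependency is any correct emotion response
    (emotion_score > 0), collapsing over confidence.
    """
    rows = []
    for subject, sub in scores.groupby("subject"):
        success = {
            "emotion": (sub["emotion_score"] > 0).astype(int).to_numpy(),
            "color": sub["success_color"].to_numpy(),
            "scene": sub["success_scene"].to_numpy(),
        }
        row: dict = {"subject": subject}
        for a, b in FEATURE_PAIRS:
            dep = corrected_dependency(success[a], success[b], pair=f"{a}-{b}")
            row[f"dependency_{a}_{b}"] = dep.corrected
            row[f"observed_{a}_{b}"] = dep.observed
            row[f"expected_{a}_{b}"] = dep.expected
        row.update(precision_correlations(sub))
        rows.append(row)
    return pd.DataFrame(rows)


def group_ttest(values, mu0: float = 0.0, tails: str = "two",
                paired_with=None) -> dict[str, float]:
    """One-sample (or paired) t test with df = n - 1.

    ``tails='one'`` tests the greater-than-mu0 direction. A zero-variance
    sample yields an infinite t, flagged via ``degenerate``.
    """
    x = np.asarray(values, dtype=float)
    if paired_with is not None:
        x = x - np.asarray(paired_with, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("group_ttest needs n >= 2")
    alternative = "greater" if tails == "one" else "two-sided"
    sd = x.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(float(x.mean()))):
        diff = float(x.mean()) - mu0
        if abs(diff) < 1e-12:
            t = 0.0
        else:
            t = np.inf if diff > 0 else -np.inf
        p = 0.0 if t != 0 else (0.5 if tails == "one" else 1.0)
        return {"t": t, "df": n - 1, "p": p, "mean": float(x.mean()), "degenerate": True}
    res = stats.ttest_1samp(x, popmean=mu0, alternative=alternative)
    return {"t": float(res.statistic), "df": n - 1, "p": float(res.pvalue),
            "mean": float(x.mean()), "degenerate": False}


def group_dependency_stats(table: pd.DataFrame, tails: str = "two") -> pd.DataFrame:
    """Group tests on each dependency / correlation column of the table."""
    rows = []
    cols = [c for c in table.columns if c.startswith(("dependency_", "z_"))]
    for c in cols:
        res = group_ttest(table[c].dropna(), mu0=0.0, tails=tails)
        rows.append({"measure": c, **res})
    return pd.DataFrame(rows)
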