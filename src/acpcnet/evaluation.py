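"""Localization-error statistics and the model-comparison protocol.

Errors are 3D Euclidean distances (mm) between predicted and ground-truth
landmarks. Outliers are defined robustly: an error is an outlier if it lies
more than k (default 3) scaled median absolute deviations from the sample
median, where the scaled MAD is c * median(|A_i - median(A)|) with
c = -1/(sqrt(2) * erfcinv(3/2)) ~= 1.4826, the constant that makes the MAD
a consistent estimator of the standard deviation for Gaussian data.

Model comparison mirrors the study protocol: outliers removed per model,
one-way ANOVA across models per landmark, then pairwise unpaired Welch
t-tests — one-tailed against the designated baseline (alternative: model
error smaller than baseline), two-tailed between non-baseline models — with
a Bonferroni-divided significance level (default divisor: factorial of the
model count).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import erfcinv

from .volumes_io import FiducialSet

__all__ = [
    "StatConfig",
    "scaled_mad_constant",
    "localization_errors",
    "scaled_mad_filter",
    "summarize_errors",
    "compare_models",
    "annotation_consensus",
    "make_error_table",
]


def scaled_mad_constant() -> float:
    """c = -1/(sqrt(2)*erfcinv(3/2)); makes MAD estimate sigma for normals."""
    return float(-1.0 / (math.sqrt(2.0) * erfcinv(1.5)))


@dataclass
class StatConfig:
    mad_k: float = 3.0
    mad_c: float = field(default_factory=scaled_mad_constant)
    alpha: float = 0.05
    n_comparisons: int | None = None  # default: factorial of the model count

    def __post_init__(self) -> None:
        if self.mad_k <= 0:
            raise ValueError("mad_k must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def localization_errors(pred: FiducialSet, truth: FiducialSet) -> dict[str, float]:
    """3D Euclidean distance per matching label, in mm."""
    if set(pred.labels) != set(truth.labels):
        raise ValueError(
            f"label mismatch: predicted {sorted(pred.labels)} vs truth {sorted(truth.labels)}"
        )
    return {lab: float(np.linalg.norm(pred[lab] - truth[lab])) for lab in truth.labels}


def scaled_mad_filter(errors, cfg: StatConfig | None = None):
    """Flag values more than k scaled MADs from the median.

    Returns (kept values, outlier flags, scaled MAD). If the scaled MAD is
    zero while values differ, every non-median value is flagged (with a
    warning) — the robust scale has collapsed.
    """
    cfg = cfg or StatConfig()
    a = np.asarray(errors, dtype=float)
    if a.ndim != 1 or a.size < 3:
        raise ValueError("need a 1D sample with at least 3 values")
    med = float(np.median(a))
    dev = np.abs(a - med)
    smad = cfg.mad_c * float(np.median(dev))
    if smad == 0.0:
        flags = dev > 0
        if flags.any():
            warnings.warn(
                "scaled MAD is zero with non-identical values; flagging all "
                "non-median values",
                RuntimeWarning,
                stacklevel=2,
            )
    else:
        flags = dev > cfg.mad_k * smad
    return a[~flags], flags, smad


def summarize_errors(errors) -> tuple[float, float, float, int]:
    """(mean, sample sd, max, n) — the 'Mean ± Std Dev (Max)' summary."""
    a = np.asarray(errors, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError("need at least 2 values for a sample standard deviation")
    return float(a.mean()), float(a.std(ddof=1)), float(a.max()), int(a.size)


def make_error_table(records) -> pd.DataFrame:
    """Rows of (volume_id, model_id, landmark, error_mm) -> tidy DataFrame."""
    df = pd.DataFrame(records, columns=["volume_id", "model_id", "landmark", "error_mm"])
    if (df["error_mm"] < 0).any() or not np.isfinite(df["error_mm"]).all():
        raise ValueError("errors must be finite and nonnegative")
    return df


def _format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.4g}"


def compare_models(
    table: pd.DataFrame, cfg: StatConfig | None = None, baseline: str | None = None
) -> dict:
    """Per-landmark ANOVA plus Bonferroni-corrected pairwise Welch t-tests.

    ``table`` must hold outlier-free errors with columns
    (volume_id, model_id, landmark, error_mm). Comparisons against
    ``baseline`` are one-tailed (alternative: the model's error is smaller);
    all other pairs are two-tailed. Each significance level is alpha divided
    by ``cfg.n_comparisons`` (default: factorial of the model count).
    """
    cfg = cfg or StatConfig()
    models = sorted(table["model_id"].unique())
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    n_comp = cfg.n_comparisons or math.factorial(len(models))
    adjusted_alpha = cfg.alpha / n_comp
    report: dict = {
        "models": models,
        "baseline": baseline,
        "n_comparisons": n_comp,
        "adjusted_alpha": adjusted_alpha,
        "t_test": "unpaired Welch (unequal variances)",
        "landmarks": {},
    }
    for lm, sub in table.groupby("landmark"):
        samples = {m: sub.loc[sub["model_id"] == m, "error_mm"].to_numpy() for m in models}
        for m, s in samples.items():
            if s.size < 3:
                raise ValueError(f"model {m!r} has fewer than 3 observations for {lm}")
        fstat, fp = stats.f_oneway(*samples.values())
        pairwise = []
        for i, a in enumerate(models):
            for b in models[i + 1 :]:
                if baseline is not None and baseline in (a, b):
                    model, base = (a, b) if b == baseline else (b, a)
                    t, p = stats.ttest_ind(
                        samples[model], samples[base], equal_var=False, alternative="less"
                    )
                    tail = "one-tailed"
                    pair = (model, base)
                else:
                    t, p = stats.ttest_ind(samples[a], samples[b], equal_var=False)
                    tail = "two-tailed"
                    pair = (a, b)
                pairwise.append(
                    {
                        "pair": pair,
                        "tail": tail,
                        "t": float(t),
                        "p": float(p),
                        "p_display": _format_p(float(p)),
                        "significant": bool(p < adjusted_alpha),
                    }
                )
        report["landmarks"][lm] = {
            "anova_F": float(fstat),
            "anova_p": float(fp),
            "anova_p_display": _format_p(float(fp)),
            "pairwise": pairwise,
        }
    return report


def annotation_consensus(sets: list[FiducialSet], flag_threshold_mm: float = 2.0):
    """Average multi-annotator fiducials and flag disagreements.

    Consensus is the coordinate-wise mean per label; a landmark is flagged
    iff any pairwise inter-annotator distance strictly exceeds
    ``flag_threshold_mm`` (such labels get visual review in the annotation
    protocol this mirrors).
    Returns (consensus FiducialSet, {label: [pairwise distances]}, {label: flag}).
    """
    if not sets:
        raise ValueError("need at least one annotator")
    labels = sets[0].labels
    for s in sets[1:]:
        if set(s.labels) != set(labels):
            raise ValueError("annotators must label the same landmark set")
    consensus = []
    distances: dict[str, list[float]] = {}
    flags: dict[str, bool] = {}
    for lab in labels:
        pts = np.stack([s[lab] for s in sets])
        consensus.append((lab, pts.mean(axis=0)))
        dists = [
            float(np.linalg.norm(pts[i] - pts[j]))
            for i in range(len(sets))
            for j in range(i + 1, len(sets))
        ]
        distances[lab] = dists
        flags[lab] = any(d > flag_threshold_mm for d in dists)
    return FiducialSet(points=consensus), distances, flags
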