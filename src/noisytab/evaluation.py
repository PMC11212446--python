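"""Threshold tuning, classification metrics, and bootstrap inference.

The operating point follows the triage use case: the decision threshold is
chosen on the validation split as the highest threshold whose sensitivity
still meets a clinical target (default 0.85), which maximizes specificity
subject to the sensitivity constraint.  Uncertainty is quantified with
percentile bootstrap confidence intervals over test-set resamples, and
models are compared with a paired bootstrap sharing resample indices.

Orientation of the paired p-value: model A is the candidate; ``p`` is the
fraction of paired resamples on which A fails to beat B (ties count one
half), so small ``p`` means A is consistently better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "EvalReport",
    "tune_threshold",
    "compute_metrics",
    "bootstrap_ci",
    "paired_bootstrap_pvalue",
    "evaluate_scores",
    "auroc",
    "auprc",
]


def auroc(labels, scores) -> float:
    """AUROC via the rank statistic (ties count one half)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    return float(roc_auc_score(labels, scores))


def auprc(labels, scores) -> float:
    """Area under the precision-recall curve (step integration)."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("AUPRC undefined: no positive labels")
    return float(average_precision_score(labels, scores))


def tune_threshold(
    val_labels, val_scores, target_sensitivity: float = 0.85
) -> float:
    """Highest threshold whose validation sensitivity meets the target.

    Candidate thresholds are the midpoints between consecutive sorted unique
    scores plus one value below the minimum and one above the maximum.  A
    sample is called positive when ``score >= threshold``, so the returned
    (highest feasible) threshold maximizes specificity subject to the
    sensitivity constraint.  With ``target_sensitivity == 0`` the
    above-maximum threshold (predicting all-negative) is admissible and
    returned.  If no candidate attains the target a warning is issued and
    the below-minimum threshold (sensitivity 1) is returned.
    """
    y = np.asarray(val_labels)
    s = np.asarray(val_scores, dtype=np.float64)
    if y.sum() < 1:
        raise ValueError("validation split must contain at least one positive")
    uniq = np.unique(s)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    n_pos = y.sum()
    best = None
    for thr in candidates:  # ascending; keep the highest feasible
        sens = ((s >= thr) & (y == 1)).sum() / n_pos
        if sens >= target_sensitivity:
            best = thr
    if best is None:
        warnings.warn(
            f"no threshold attains sensitivity {target_sensitivity}; "
            "falling back to the minimal threshold",
            stacklevel=2,
        )
        return float(uniq[0] - 1.0)
    return float(best)


def compute_metrics(labels, scores, threshold: float) -> dict[str, float]:
    """Threshold-free and operating-point metrics in one dictionary.

    Returns AUROC, AUPRC, and the confusion-matrix metrics (sensitivity,
    specificity, PPV, NPV) at ``score >= threshold``.  PPV/NPV are NaN when
    no sample is predicted positive/negative.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return {
        "auroc": auroc(y, s),
        "auprc": auprc(y, s),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
    }


def _resample_indices(
    rng: np.random.Generator, labels: np.ndarray, n_boot: int, require_both: bool
) -> np.ndarray:
    """Draw bootstrap index rows; redraw rows whose resample has one class."""
    n = len(labels)
    idx = rng.integers(0, n, size=(n_boot, n))
    if require_both:
        redraws = 0
        for b in range(n_boot):
            while len(np.unique(labels[idx[b]])) < 2:
                idx[b] = rng.integers(0, n, size=n)
                redraws += 1
                if redraws > 10 * n_boot:
                    raise ValueError(
                        "metric undefined on most resamples: labels too imbalanced"
                    )
        if redraws:
            warnings.warn(f"redrew {redraws} single-class bootstrap resamples", stacklevel=3)
    return idx


def bootstrap_ci(
    labels,
    scores,
    metric=auroc,
    n: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    indices: np.ndarray | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for ``metric`` over test-set resamples.

    ``metric`` is a callable ``(labels, scores) -> float``.  Resamples are
    drawn with replacement under ``seed``; rows with a single class are
    redrawn (and counted in a warning).  ``indices`` may supply a
    precomputed (n_boot, n_samples) index matrix, e.g. to share resamples
    with an independent recomputation.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if indices is None:
        rng = np.random.default_rng(seed)
        indices = _resample_indices(rng, y, n, require_both=metric in (auroc, auprc))
    stats = np.array([metric(y[row], s[row]) for row in indices])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def paired_bootstrap_pvalue(
    labels,
    scores_a,
    scores_b,
    metric=auroc,
    n: int = 1000,
    seed: int = 0,
    indices: np.ndarray | None = None,
) -> float:
    """One-sided paired bootstrap comparison of two models on shared resamples.

    Model A is the candidate: ``p`` is the fraction of paired resamples on
    which A's metric is below B's, plus half the fraction of exact ties.
    Identical score vectors therefore give ``p = 0.5``; A strictly better on
    every resample gives ``p = 0.0``.
    """
    y = np.asarray(labels)
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if len(a) != len(y) or len(b) != len(y):
        raise ValueError("labels, scores_a and scores_b must share length")
    if indices is None:
        rng = np.random.default_rng(seed)
        indices = _resample_indices(rng, y, n, require_both=metric in (auroc, auprc))
    wins_b = ties = 0
    for row in indices:
        ma = metric(y[row], a[row])
        mb = metric(y[row], b[row])
        if ma < mb:
            wins_b += 1
        elif ma == mb:
            ties += 1
    return (wins_b + 0.5 * ties) / len(indices)


@dataclass
class EvalReport:
    """Point metrics with bootstrap CIs at a tuned threshold."""

    metrics: dict[str, float]
    ci: dict[str, tuple[float, float]]
    threshold: float
    n_bootstrap: int
    notes: str = (
        "percentile bootstrap; paired p-values are one-sided with the first "
        "model as candidate (small p = candidate better)"
    )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, value in self.metrics.items():
            lo, hi = self.ci.get(name, (float("nan"), float("nan")))
            rows.append({"metric": name, "value": value, "ci_lower": lo, "ci_upper": hi})
        df = pd.DataFrame(rows)
        df["threshold"] = self.threshold
        df["n_bootstrap"] = self.n_bootstrap
        return df

    def __str__(self) -> str:
        lines = [f"threshold = {self.threshold:.4f} ({self.n_bootstrap} bootstrap resamples)"]
        for name, value in self.metrics.items():
            lo, hi = self.ci.get(name, (float("nan"), float("nan")))
            interval = "" if np.isnan(lo) else f" ({lo:.3f}-{hi:.3f})"
            lines.append(f"  {name:>12s}: {value:.3f}{interval}")
        lines.append(self.notes)
        return "\n".join(lines)


def evaluate_scores(
    labels,
    scores,
    threshold: float,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Full evaluation at a given threshold: point metrics plus bootstrap CIs."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    point = compute_metrics(y, s, threshold)
    rng = np.random.default_rng(seed)
    indices = _resample_indices(rng, y, n_bootstrap, require_both=True)
    ci: dict[str, tuple[float, float]] = {}
    for name in ("auroc", "auprc", "sensitivity", "specificity"):
        if name == "auroc":
            fn = auroc
        elif name == "auprc":
            fn = auprc
        else:
            fn = lambda yy, ss, _n=name: compute_metrics(yy, ss, threshold)[_n]
        ci[name] = bootstrap_ci(y, s, metric=fn, n=n_bootstrap, indices=indices)
    return EvalReport(metrics=point, ci=ci, threshold=threshold, n_bootstrap=n_bootstrap)
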