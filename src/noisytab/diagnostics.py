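"""Mechanism diagnostics: latent-space similarity strata and confidence traces.

Two analyses explain *why* neighbour consistency helps under label noise:

* **Similarity strata** — pairwise cosine similarities of the latent
  representations, stratified by whether the pair is correctly labelled and
  whether it belongs to the same class.  A robust model shows a wide gap
  between same-class and different-class similarity among cleanly labelled
  pairs.
* **Confidence traces** — per-epoch mean predicted confidence in the
  *assigned* (possibly wrong) training label, split by the noise flag.
  Rising confidence on mislabelled samples is the memorization signature;
  regularized models keep it low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MLPClassifier
from .synthetic_data import LabeledTable
from .training import TrainHistory

__all__ = [
    "SimilarityStrata",
    "ConfidenceTrace",
    "similarity_strata",
    "confidence_trace",
]

STRATA = (
    "same_class_clean",
    "same_label_mislabeled",
    "different_class_clean",
    "different_label_mislabeled",
)


@dataclass
class SimilarityStrata:
    """Cosine-similarity samples per stratum with their summary statistics.

    Strata partition the evaluated pairs: pairs with both labels clean are
    split by true-class equality; pairs involving at least one mislabelled
    sample are split by assigned-label equality.  ``summary`` holds mean and
    median per stratum (NaN for empty strata, flagged in ``empty``).
    """

    samples: dict[str, np.ndarray]
    summary: dict[str, dict[str, float]]
    empty: tuple[str, ...]

    @property
    def class_separation_gap(self) -> float:
        """mean(same-class clean) - mean(different-class clean): bigger is better."""
        return (
            self.summary["same_class_clean"]["mean"]
            - self.summary["different_class_clean"]["mean"]
        )

    def to_frame(self, bins: int = 50) -> pd.DataFrame:
        """Histogram export (one row per stratum x bin) for CSV serialization."""
        rows = []
        for name, values in self.samples.items():
            if len(values) == 0:
                continue
            counts, edges = np.histogram(values, bins=bins, range=(-1.0, 1.0))
            for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
                rows.append({"stratum": name, "bin_low": lo, "bin_high": hi, "count": int(c)})
        return pd.DataFrame(rows)


def similarity_strata(
    model: MLPClassifier,
    table: LabeledTable,
    max_pairs: int = 100_000,
    seed: int = 0,
) -> SimilarityStrata:
    """Stratify pairwise latent cosine similarities by label correctness.

    Uses the same hidden layer (``ncr_layer``) whose representation drives
    the NCR term during training.  When the table has more than
    ``max_pairs`` pairs, a seeded uniform subsample of pairs is evaluated.

    Raises
    ------
    ValueError
        If the table lacks noise metadata (``noise_flags``/``clean_labels``).
    """
    if table.noise_flags is None or table.clean_labels is None:
        raise ValueError("similarity_strata requires noise_flags and clean_labels")
    V = model.forward(table.features).v
    norms = np.linalg.norm(V, axis=1)
    norms[norms == 0] = 1.0  # zero rows -> similarity 0 via zero numerator
    U = V / norms[:, None]

    n = len(table)
    n_pairs = n * (n - 1) // 2
    rng = np.random.default_rng(seed)
    if n_pairs <= max_pairs:
        ii, jj = np.triu_indices(n, k=1)
    else:
        ii = rng.integers(0, n, size=max_pairs)
        jj = rng.integers(0, n, size=max_pairs)
        keep = ii != jj
        ii, jj = ii[keep], jj[keep]
    sims = np.einsum("ij,ij->i", U[ii], U[jj])

    clean_pair = (table.noise_flags[ii] == 0) & (table.noise_flags[jj] == 0)
    same_class = table.clean_labels[ii] == table.clean_labels[jj]
    same_label = table.labels[ii] == table.labels[jj]
    membership = {
        "same_class_clean": clean_pair & same_class,
        "same_label_mislabeled": ~clean_pair & same_label,
        "different_class_clean": clean_pair & ~same_class,
        "different_label_mislabeled": ~clean_pair & ~same_label,
    }
    samples = {name: sims[mask] for name, mask in membership.items()}
    summary = {
        name: {
            "mean": float(np.mean(vals)) if len(vals) else float("nan"),
            "median": float(np.median(vals)) if len(vals) else float("nan"),
        }
        for name, vals in samples.items()
    }
    empty = tuple(name for name, vals in samples.items() if len(vals) == 0)
    return SimilarityStrata(samples=samples, summary=summary, empty=empty)


@dataclass
class ConfidenceTrace:
    """Per-epoch mean confidence in the assigned label, by noise flag."""

    epochs: np.ndarray
    mean_clean: np.ndarray
    mean_mislabeled: np.ndarray

    @property
    def final_gap(self) -> float:
        """Final-epoch mean confidence on clean minus mislabelled samples."""
        return float(self.mean_clean[-1] - self.mean_mislabeled[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "mean_confidence_clean": self.mean_clean,
                "mean_confidence_mislabeled": self.mean_mislabeled,
            }
        )


def confidence_trace(history: TrainHistory, noise_flags) -> ConfidenceTrace:
    """Split recorded per-sample confidences into clean and mislabelled means.

    ``history`` must have been produced with ``record_confidence=True``.
    The confidence of sample *i* at an epoch is the predicted probability of
    its assigned label: ``p_i`` when the label is 1 and ``1 - p_i`` when 0.
    """
    if history.confidences is None or not history.confidences:
        raise ValueError("history carries no per-sample confidences; "
                         "train with record_confidence=True")
    flags = np.asarray(noise_flags)
    conf = np.stack(history.confidences)  # (epochs, n)
    if conf.shape[1] != len(flags):
        raise ValueError(
            f"noise_flags length {len(flags)} does not match {conf.shape[1]} samples"
        )
    clean = flags == 0
    if clean.all() or (~clean).all():
        # one partition empty: report NaN for it rather than failing
        mean_clean = conf[:, clean].mean(axis=1) if clean.any() else np.full(len(conf), np.nan)
        mean_noisy = conf[:, ~clean].mean(axis=1) if (~clean).any() else np.full(len(conf), np.nan)
    else:
        mean_clean = conf[:, clean].mean(axis=1)
        mean_noisy = conf[:, ~clean].mean(axis=1)
    return ConfidenceTrace(
        epochs=np.arange(conf.shape[0]),
        mean_clean=mean_clean,
        mean_mislabeled=mean_noisy,
    )
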