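"""Training loop with NCR warm-up scheduling, and grid search under k-fold CV.

The loop trains the fully connected baseline with one of the supported
methods:

``baseline``
    plain binary cross-entropy;
``smoothing``
    cross-entropy against smoothed targets;
``mixup``
    cross-entropy on convex combinations of batch pairs;
``ncr``
    cross-entropy plus the neighbour-consistency term after a warm-up;
``mixup+ncr``
    both mechanisms together (NCR is computed on the mixed batch).

Three random streams are derived independently from the run seed — weight
initialization, epoch shuffling/batching, and mix-up — so corruption, init
and batch order are separately reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import autodiff as ad
from .losses import (
    MixupSpec,
    NCRSpec,
    SmoothingSpec,
    cross_entropy,
    mixup_batch,
    ncr_loss,
    smooth_labels,
)
from .model import Adam, MLPClassifier, MLPConfig
from .synthetic_data import LabeledTable

__all__ = [
    "METHODS",
    "TrainConfig",
    "TrainHistory",
    "TrainingDivergedError",
    "train_model",
    "grid_search_cv",
]

METHODS = ("baseline", "smoothing", "mixup", "ncr", "mixup+ncr")


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    """Complete specification of one training run."""

    mlp: MLPConfig = field(default_factory=MLPConfig)
    method: str = "baseline"
    smoothing: SmoothingSpec | None = None
    mixup: MixupSpec | None = None
    ncr: NCRSpec | None = None
    seed: int = 0
    record_confidence: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.method == "smoothing" and self.smoothing is None:
            object.__setattr__(self, "smoothing", SmoothingSpec())
        if "mixup" in self.method and self.mixup is None:
            object.__setattr__(self, "mixup", MixupSpec())
        if "ncr" in self.method and self.ncr is None:
            object.__setattr__(self, "ncr", NCRSpec())


@dataclass
class TrainHistory:
    """Per-epoch record of both loss terms and validation discrimination.

    ``confidences`` (present when requested) holds, per epoch, each training
    sample's predicted probability of its *assigned* (possibly noisy) label.
    """

    ce: list[float] = field(default_factory=list)
    ncr: list[float] = field(default_factory=list)
    val_auroc: list[float] = field(default_factory=list)
    confidences: list[np.ndarray] | None = None


def _epoch_targets(labels: np.ndarray, config: TrainConfig,
                   eps_rng: np.random.Generator) -> np.ndarray:
    """Per-epoch soft targets for the full training set (positive-class column)."""
    y = labels.astype(np.float64)
    if config.method != "smoothing":
        return y
    spec = config.smoothing
    assert spec is not None
    if spec.mode == "resampled":
        spec = replace(spec, epsilon=float(eps_rng.uniform(0.0, spec.epsilon)))
    return smooth_labels(labels, spec)[:, 1]


def train_model(
    train: LabeledTable,
    val: LabeledTable,
    config: TrainConfig,
) -> tuple[MLPClassifier, TrainHistory]:
    """Train the fully connected classifier and record its history.

    Expects preprocessed (fully observed, standardized) splits.  The NCR
    term is active only from epoch ``warmup_epochs`` onward and only on
    batches larger than ``k``; its per-epoch mean is recorded separately
    from the cross-entropy term.

    Raises
    ------
    TrainingDivergedError
        If the loss becomes non-finite, with the offending epoch and batch.
    """
    if np.isnan(train.features).any() or np.isnan(val.features).any():
        raise ValueError("training requires preprocessed features without missing values")
    cfg = config.mlp
    model = MLPClassifier(train.n_features, cfg)
    opt = Adam(model.parameters, lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng([config.seed, 1])
    mix_rng = np.random.default_rng([config.seed, 2])
    eps_rng = np.random.default_rng([config.seed, 3])

    use_mix = "mixup" in config.method
    use_ncr = "ncr" in config.method
    ncr_spec = config.ncr if use_ncr else None
    if use_ncr and ncr_spec.k >= cfg.batch_size:
        raise ValueError(
            f"NCR needs k < batch_size, got k={ncr_spec.k}, batch_size={cfg.batch_size}"
        )

    history = TrainHistory(confidences=[] if config.record_confidence else None)
    n = len(train)
    X_all, y_all = train.features, train.labels

    for epoch in range(cfg.n_epochs):
        order = shuffle_rng.permutation(n)
        targets_all = _epoch_targets(y_all, config, eps_rng)
        ce_sum = ncr_sum = 0.0
        n_batches = 0
        ncr_active = use_ncr and epoch >= ncr_spec.warmup_epochs  # type: ignore[union-attr]
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            Xb, tb = X_all[idx], targets_all[idx]
            if use_mix:
                Xb, tb, _ = mixup_batch(Xb, tb, config.mixup, rng=mix_rng)
            V, Z = model.forward_tensors(Xb)
            p = ad.sigmoid(Z)
            loss = ce = cross_entropy(p, tb)
            ncr_val = 0.0
            if ncr_active and len(idx) > ncr_spec.k:  # type: ignore[union-attr]
                reg = ncr_loss(V, Z, ncr_spec)  # type: ignore[arg-type]
                ncr_val = reg.item()
                loss = ce + ncr_spec.weight * reg  # type: ignore[union-attr]
            if not np.isfinite(loss.item()):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches} "
                    f"(ce={ce.item():.4g}, ncr={ncr_val:.4g})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            ce_sum += ce.item()
            ncr_sum += ncr_val
            n_batches += 1
        history.ce.append(ce_sum / n_batches)
        history.ncr.append(ncr_sum / n_batches)
        history.val_auroc.append(
            float(roc_auc_score(val.labels, model.predict_proba(val.features)))
        )
        if history.confidences is not None:
            p_train = model.predict_proba(X_all)
            history.confidences.append(np.where(y_all == 1, p_train, 1.0 - p_train))
    return model, history


def grid_search_cv(
    param_grid: list[TrainConfig],
    train: LabeledTable,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[TrainConfig, list[float]]:
    """Pick the grid point with the best mean validation-fold AUROC.

    Folds are stratified on the (possibly noisy) labels so that every
    validation fold contains both classes even at low prevalence.  Ties are
    broken in favour of the earlier grid entry.  Returns the winning config
    and the per-grid-point mean AUROCs.
    """
    if not param_grid:
        raise ValueError("param_grid must contain at least one configuration")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(train.features, train.labels))
    means: list[float] = []
    for config in param_grid:
        scores = []
        for tr_idx, va_idx in folds:
            model, _ = train_model(train.subset(tr_idx), train.subset(va_idx), config)
            scores.append(
                roc_auc_score(
                    train.labels[va_idx], model.predict_proba(train.features[va_idx])
                )
            )
        means.append(float(np.mean(scores)))
    best = int(np.argmax(means))  # argmax keeps the first index on ties
    return param_grid[best], means
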