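"""Noise-mitigation training objectives: label smoothing, mix-up, and NCR.

All three mechanisms regularize a classifier against memorizing corrupted
labels:

* **Label smoothing** replaces one-hot targets with ``1 - eps`` on the
  assigned class and ``eps / (C - 1)`` elsewhere.
* **Mix-up** trains on convex combinations of feature/label pairs, with the
  mixing weight drawn from a Beta(alpha, alpha) distribution and a per-batch
  probability of mixing at all.
* **Neighbour Consistency Regularization (NCR)** penalizes the divergence
  between a sample's predicted class distribution and the similarity-weighted
  mixture of the predictions of its k nearest neighbours in the latent
  (post-ReLU) feature space of the network, so that samples that look alike
  are pushed to be classified alike regardless of their (possibly wrong)
  labels.

The total objective is ``L_CE + weight * L_NCR``, with the NCR term switched
on only after a warm-up number of epochs of plain cross-entropy.

Functions here accept either plain numpy arrays or :class:`~noisytab.autodiff.Tensor`
nodes; they always return a ``Tensor`` so gradients can flow during training
(use ``.item()`` / ``.data`` for the numeric value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "SmoothingSpec",
    "MixupSpec",
    "NCRSpec",
    "smooth_labels",
    "mixup_batch",
    "cosine_similarity_matrix",
    "ncr_loss",
    "cross_entropy",
    "total_loss",
]

_EPS = 1e-7  # probability clamp before logarithms


@dataclass(frozen=True)
class SmoothingSpec:
    """Label-smoothing hyperparameters.

    ``mode="fixed"`` treats ``epsilon`` as a tuned constant; ``"resampled"``
    redraws ``epsilon ~ U[0, epsilon_max]`` each epoch (the training loop
    handles the redraw), for experiments that treat the smoothing amount as
    stochastic.
    """

    epsilon: float = 0.1
    n_classes: int = 2
    mode: str = "fixed"

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError(f"epsilon must lie in [0, 1), got {self.epsilon}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.mode not in ("fixed", "resampled"):
            raise ValueError(f"mode must be 'fixed' or 'resampled', got {self.mode!r}")


@dataclass(frozen=True)
class MixupSpec:
    """Mix-up hyperparameters: Beta shape ``alpha_beta`` and per-batch apply probability."""

    alpha_beta: float = 0.4
    p_apply: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise ValueError(f"alpha_beta must be positive, got {self.alpha_beta}")
        if not 0.0 <= self.p_apply <= 1.0:
            raise ValueError(f"p_apply must lie in [0, 1], got {self.p_apply}")


@dataclass(frozen=True)
class NCRSpec:
    """Neighbour-consistency hyperparameters.

    ``k`` neighbours are found within the mini-batch; ``weight`` scales the
    NCR term in the total objective; the term is inactive for the first
    ``warmup_epochs`` epochs; ``divergence`` selects KL (as-printed
    direction: D(prediction || neighbour mixture)), Jensen-Shannon, or mean
    absolute error between the two distributions.
    """

    k: int = 10
    weight: float = 1.0
    warmup_epochs: int = 30
    divergence: str = "kl"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.weight < 0:
            raise ValueError(f"weight must be non-negative, got {self.weight}")
        if self.warmup_epochs < 0:
            raise ValueError(f"warmup_epochs must be non-negative, got {self.warmup_epochs}")
        if self.divergence not in ("kl", "js", "mae"):
            raise ValueError(f"divergence must be 'kl', 'js' or 'mae', got {self.divergence!r}")


def smooth_labels(labels: np.ndarray, spec: SmoothingSpec) -> np.ndarray:
    """Return per-sample target distributions of shape (n, C).

    The assigned class receives ``1 - epsilon`` and every other class
    ``epsilon / (C - 1)``, so each row sums to 1.
    """
    labels = np.asarray(labels, dtype=np.int64)
    C = spec.n_classes
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= C:
        raise ValueError(f"labels must lie in [0, {C - 1}]")
    targets = np.full((len(labels), C), spec.epsilon / (C - 1))
    targets[np.arange(len(labels)), labels] = 1.0 - spec.epsilon
    return targets


def mixup_batch(
    X: np.ndarray,
    Y: np.ndarray,
    spec: MixupSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Mix a batch against a seeded permutation of itself.

    One mixing weight ``lam ~ Beta(alpha, alpha)`` is drawn per batch; with
    probability ``1 - p_apply`` the batch is returned unmixed (``lam = 1``).
    ``Y`` may hold scalar targets in [0, 1] or per-sample distributions; the
    same convex combination applies either way.

    Returns ``(X_mix, Y_mix, lam)``.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if len(X) < 2:
        warnings.warn("mix-up skipped: batch has fewer than 2 samples", stacklevel=2)
        return X, Y, 1.0
    if rng.random() >= spec.p_apply:
        return X, Y, 1.0
    lam = float(rng.beta(spec.alpha_beta, spec.alpha_beta))
    perm = rng.permutation(len(X))
    X_mix = lam * X + (1.0 - lam) * X[perm]
    Y_mix = lam * Y + (1.0 - lam) * Y[perm]
    return X_mix, Y_mix, lam


def cosine_similarity_matrix(V) -> Tensor:
    """Pairwise cosine similarities between the rows of ``V``.

    ``S[i, j] = v_i . v_j / (||v_i|| ||v_j||)``; rows of all zeros get
    similarity 0 to every other row (their norm is clamped away from zero
    and the zero numerator does the rest).
    """
    V = V if isinstance(V, Tensor) else Tensor(V)
    sq = (V * V).sum(axis=1)
    norms = ad.sqrt(ad.clip(sq, 1e-24, np.inf))
    G = V @ V.T
    return G / (norms.reshape(-1, 1) * norms.reshape(1, -1))


def _binary_distributions(Z) -> Tensor:
    """Stack sigmoid logits into two-class distributions (1 - p, p) of shape (m, 2)."""
    Z = Z if isinstance(Z, Tensor) else Tensor(Z)
    p = ad.sigmoid(Z.reshape(-1))
    return ad.stack([1.0 - p, p], axis=1)


def _topk_mask(sim: np.ndarray, k: int) -> np.ndarray:
    """0/1 mask selecting, per row, the k most similar columns (ties to lower index)."""
    m = sim.shape[0]
    # stable sort on descending similarity keeps lower indices first among ties
    order = np.argsort(-sim, axis=1, kind="stable")
    mask = np.zeros_like(sim)
    rows = np.repeat(np.arange(m), k)
    mask[rows, order[:, :k].ravel()] = 1.0
    return mask


def ncr_loss(V, Z, spec: NCRSpec) -> Tensor:
    """Neighbour-consistency loss over a mini-batch.

    For each sample *i*: self-similarity is zeroed; negative similarities are
    clamped to 0; the ``k`` most similar rows are selected; their
    similarities are normalized into weights summing to 1; the weighted
    mixture of the neighbours' predicted distributions is formed; and the
    chosen divergence between sample *i*'s own predicted distribution and
    that mixture is accumulated.  The mean over the batch is returned.  A
    sample whose retained similarities are all zero contributes 0.

    Gradients flow into both ``Z`` (through the distributions) and ``V``
    (through the similarity weights); the discrete neighbour selection is
    treated as constant, as in standard top-k training practice.
    """
    V = V if isinstance(V, Tensor) else Tensor(V)
    Z = Z if isinstance(Z, Tensor) else Tensor(Z)
    m = V.shape[0]
    if spec.k >= m:
        raise ValueError(f"k ({spec.k}) must be smaller than the batch size ({m})")

    S = cosine_similarity_matrix(V)
    S = ad.clip(S, 0.0, np.inf)  # defensive: post-ReLU features cannot go negative
    off_diag = 1.0 - np.eye(m)
    S = S * off_diag  # zero self-similarity

    mask = _topk_mask(S.data, spec.k)  # selection is non-differentiable by construction
    kept = S * mask
    row_sums = kept.sum(axis=1)
    live = (row_sums.data > 0).astype(np.float64)  # all-zero rows contribute 0
    safe_sums = ad.clip(row_sums, 1e-24, np.inf)
    weights = kept / safe_sums.reshape(-1, 1)

    P = _binary_distributions(Z)  # (m, 2) predicted distributions
    Q = weights @ P  # neighbour mixtures

    Pc = ad.clip(P, _EPS, 1.0 - _EPS)
    Qc = ad.clip(Q, _EPS, 1.0 - _EPS)
    if spec.divergence == "kl":
        per_sample = (Pc * (ad.log(Pc) - ad.log(Qc))).sum(axis=1)
    elif spec.divergence == "js":
        Mc = ad.clip((Pc + Qc) * 0.5, _EPS, 1.0 - _EPS)
        kl_pm = (Pc * (ad.log(Pc) - ad.log(Mc))).sum(axis=1)
        kl_qm = (Qc * (ad.log(Qc) - ad.log(Mc))).sum(axis=1)
        per_sample = (kl_pm + kl_qm) * 0.5
    else:  # mae
        diff = P - Q
        per_sample = ((diff * diff + 1e-24) ** 0.5).sum(axis=1) * 0.5
    return (per_sample * live).sum() * (1.0 / m)


def cross_entropy(p, targets) -> Tensor:
    """Mean binary cross-entropy supporting soft targets.

    ``p`` holds predicted positive-class probabilities; ``targets`` is either
    a vector of (possibly soft) positive-class targets in [0, 1] or an
    (n, 2) matrix of class distributions, of which the second column is used.
    """
    p = p if isinstance(p, Tensor) else Tensor(p)
    t = np.asarray(targets.data if isinstance(targets, Tensor) else targets, dtype=np.float64)
    if t.ndim == 2:
        t = t[:, 1]
    pc = ad.clip(p.reshape(-1), _EPS, 1.0 - _EPS)
    return -(Tensor(t) * ad.log(pc) + Tensor(1.0 - t) * ad.log(1.0 - pc)).mean()


def total_loss(p, targets, V, Z, epoch: int, ncr: NCRSpec) -> Tensor:
    """Combined objective: cross-entropy plus ``weight * ncr_loss``.

    The NCR term is exactly zero (not computed) while ``epoch`` is below
    ``ncr.warmup_epochs`` or when ``ncr.weight`` is 0, in which case the
    result equals plain cross-entropy.
    """
    ce = cross_entropy(p, targets)
    if ncr.weight == 0 or epoch < ncr.warmup_epochs:
        return ce
    return ce + ncr.weight * ncr_loss(V, Z, ncr)
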