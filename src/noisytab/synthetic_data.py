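"""Synthetic EHR-like tabular cohorts with known clean labels and controlled label noise.

Real triage cohorts of the kind this package targets (lab tests and vital
signs for emergency presentations, ~5% disease prevalence, asymmetric label
error driven by imperfect test sensitivity) are access-restricted.  This
module generates cohorts with the same statistical shape — continuous
correlated features, strong class imbalance, missing values — and, because
the generator knows the true labels, supports exact class-conditional label
corruption and downstream diagnostics keyed on which labels were flipped.

The generative model is a two-class multivariate normal with a single shared
latent factor: for sample *i* with standard-normal latent :math:`g_i` and
independent noise :math:`e_{ij}`,

.. math::

   x_{ij} = \\mu_j(y_i) + \\sqrt{\\rho}\\, g_i + \\sqrt{1-\\rho}\\, e_{ij},

so every feature has unit variance, every pair of features has correlation
:math:`\\rho`, and the positive class is shifted by ``separation`` standard
deviations in every feature.  This admits a closed-form Bayes discriminant
(a linear score), used as an oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "NoiseSpec",
    "LabeledTable",
    "generate_cohort",
    "inject_label_noise",
    "split_cohort",
    "bayes_discriminant",
    "write_csv",
    "read_csv",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Parameters
    ----------
    n_samples : int
        Number of presentations to generate.
    n_features : int
        Number of continuous features (standing in for labs/vitals).
    prevalence : float
        Fraction of positive cases, in (0, 1).  The generated cohort contains
        exactly ``round(prevalence * n_samples)`` positives.
    separation : float
        Mean shift of the positive class in units of the per-feature
        standard deviation.  0 makes the classes indistinguishable.
    correlation : float
        Shared-factor correlation between every pair of features, in [0, 1).
    missing_rate : float
        Probability that any individual feature entry is missing, in [0, 1).
    seed : int
        Seed for the generator's random stream.
    """

    n_samples: int
    n_features: int
    prevalence: float = 0.05
    separation: float = 1.0
    correlation: float = 0.3
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be positive, got {self.n_samples}")
        if self.n_features < 1:
            raise ValueError(f"n_features must be positive, got {self.n_features}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must lie in (0, 1), got {self.prevalence}")
        if self.separation < 0:
            raise ValueError(f"separation must be non-negative, got {self.separation}")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError(f"correlation must lie in [0, 1), got {self.correlation}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")
        if int(np.rint(self.prevalence * self.n_samples)) < 1:
            raise ValueError(
                "prevalence too small: round(prevalence * n_samples) must be >= 1"
            )


@dataclass(frozen=True)
class NoiseSpec:
    """Class-conditional label-corruption rates.

    ``fn_rate`` is the fraction of true positives whose label is flipped to
    negative (false negatives, e.g. imperfect PCR sensitivity); ``fp_rate``
    is the fraction of true negatives flipped to positive.
    """

    fn_rate: float
    fp_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fn_rate <= 1.0:
            raise ValueError(f"fn_rate must lie in [0, 1], got {self.fn_rate}")
        if not 0.0 <= self.fp_rate <= 1.0:
            raise ValueError(f"fp_rate must lie in [0, 1], got {self.fp_rate}")


@dataclass
class LabeledTable:
    """A feature matrix with (possibly noisy) binary labels.

    ``labels`` is what a model trains on; ``clean_labels`` is the
    generator-known truth; ``noise_flags[i] == 1`` iff ``labels[i]`` was
    flipped away from ``clean_labels[i]``.  Missing feature entries are NaN.
    """

    features: np.ndarray
    labels: np.ndarray
    clean_labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    noise_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.clean_labels is None:
            self.clean_labels = self.labels.copy()
        self.clean_labels = np.asarray(self.clean_labels, dtype=np.int64)
        if self.noise_flags is None:
            self.noise_flags = (self.labels != self.clean_labels).astype(np.int64)
        self.noise_flags = np.asarray(self.noise_flags, dtype=np.int64)
        n = len(self.labels)
        if self.features.shape[0] != n:
            raise ValueError("features and labels disagree on sample count")
        if len(self.clean_labels) != n or len(self.noise_flags) != n:
            raise ValueError("labels, clean_labels, noise_flags must share length")
        if np.any((self.noise_flags == 1) != (self.labels != self.clean_labels)):
            raise ValueError("noise_flags inconsistent with labels vs clean_labels")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, idx: np.ndarray) -> "LabeledTable":
        return LabeledTable(
            features=self.features[idx],
            labels=self.labels[idx],
            clean_labels=self.clean_labels[idx],
            noise_flags=self.noise_flags[idx],
        )


def generate_cohort(spec: CohortSpec) -> LabeledTable:
    """Draw a cohort from the shared-factor two-class Gaussian model.

    The number of positives is exactly ``round(prevalence * n_samples)``
    (round half to even); positive rows are placed at seeded-random
    positions.  Each feature entry is independently masked as missing with
    probability ``missing_rate``.  ``noise_flags`` are all zero.
    """
    rng = np.random.default_rng([spec.seed, 0])  # tagged stream: cohort generation
    n, d = spec.n_samples, spec.n_features
    n_pos = int(np.rint(spec.prevalence * n))

    labels = np.zeros(n, dtype=np.int64)
    labels[rng.permutation(n)[:n_pos]] = 1

    shared = rng.standard_normal(n)
    noise = rng.standard_normal((n, d))
    features = (
        np.sqrt(spec.correlation) * shared[:, None]
        + np.sqrt(1.0 - spec.correlation) * noise
    )
    features[labels == 1] += spec.separation

    if spec.missing_rate > 0:
        mask = rng.random((n, d)) < spec.missing_rate
        features[mask] = np.nan

    return LabeledTable(features=features, labels=labels)


def inject_label_noise(table: LabeledTable, noise: NoiseSpec) -> LabeledTable:
    """Flip labels class-conditionally, always starting from the clean labels.

    Exactly ``round(fn_rate * n_positives)`` clean positives become 0 and
    ``round(fp_rate * n_negatives)`` clean negatives become 1, chosen
    uniformly at random under ``noise.seed``.  Because flips are computed
    from ``clean_labels``, re-applying the same spec is idempotent in
    outcome.  Features and clean labels are never modified.
    """
    clean = table.clean_labels
    if not np.isin(clean, (0, 1)).all() or not np.isin(table.labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    rng = np.random.default_rng([noise.seed, 1])  # tagged stream: label corruption
    pos_idx = np.flatnonzero(clean == 1)
    neg_idx = np.flatnonzero(clean == 0)
    n_fn = int(np.rint(noise.fn_rate * len(pos_idx)))
    n_fp = int(np.rint(noise.fp_rate * len(neg_idx)))
    flip = np.concatenate(
        [
            rng.choice(pos_idx, size=n_fn, replace=False) if n_fn else [],
            rng.choice(neg_idx, size=n_fp, replace=False) if n_fp else [],
        ]
    ).astype(np.int64)
    labels = clean.copy()
    labels[flip] = 1 - labels[flip]
    flags = np.zeros_like(clean)
    flags[flip] = 1
    return LabeledTable(
        features=table.features,
        labels=labels,
        clean_labels=clean.copy(),
        noise_flags=flags,
    )


def split_cohort(
    table: LabeledTable,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[LabeledTable, LabeledTable, LabeledTable]:
    """Randomly partition rows into train/validation/test splits.

    Validation and test sizes are ``round(fraction * n)``; the remainder goes
    to the training split.  The partition is row-disjoint and exhaustive, and
    reproducible for a fixed seed.
    """
    if any(f <= 0 for f in fractions):
        raise ValueError(f"fractions must be positive, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(table)
    n_val = int(np.rint(fractions[1] * n))
    n_test = int(np.rint(fractions[2] * n))
    n_train = n - n_val - n_test
    # tagged stream so a shared integer seed cannot collide with generation
    perm = np.random.default_rng([seed, 2]).permutation(n)
    return (
        table.subset(perm[:n_train]),
        table.subset(perm[n_train : n_train + n_val]),
        table.subset(perm[n_train + n_val :]),
    )


def bayes_discriminant(spec: CohortSpec):
    """Return the optimal linear scorer for cohorts drawn from ``spec``.

    Both classes share covariance :math:`\\Sigma = (1-\\rho) I + \\rho J`, so
    the log-likelihood ratio is linear with weights
    :math:`w = \\Sigma^{-1} (\\mu_1 - \\mu_0)`.  The returned callable maps a
    complete (non-missing) feature matrix to a score that is a monotone
    transform of the true posterior probability of class 1 — the AUROC
    ceiling any classifier can reach on this cohort.
    """
    d = spec.n_features
    cov = (1.0 - spec.correlation) * np.eye(d) + spec.correlation * np.ones((d, d))
    w = np.linalg.solve(cov, np.full(d, spec.separation))

    def score(features: np.ndarray) -> np.ndarray:
        return np.asarray(features, dtype=np.float64) @ w

    return score


# -- CSV interchange -------------------------------------------------------


def _to_frame(table: LabeledTable) -> pd.DataFrame:
    cols = {f"f{j}": table.features[:, j] for j in range(table.n_features)}
    cols["label"] = table.labels
    cols["clean_label"] = table.clean_labels
    cols["noise_flag"] = table.noise_flags
    return pd.DataFrame(cols)


def write_csv(table: LabeledTable, path) -> None:
    """Write a table as CSV: one row per presentation, missing values empty."""
    _to_frame(table).to_csv(path, index=False, na_rep="")


def read_csv(path) -> LabeledTable:
    """Read a table written by :func:`write_csv` (or any CSV with a ``label`` column)."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("CSV must contain a 'label' column")
    feature_cols = [c for c in df.columns if c not in ("label", "clean_label", "noise_flag")]
    return LabeledTable(
        features=df[feature_cols].to_numpy(dtype=np.float64),
        labels=df["label"].to_numpy(dtype=np.int64),
        clean_labels=df["clean_label"].to_numpy(dtype=np.int64)
        if "clean_label" in df.columns
        else None,
        noise_flags=df["noise_flag"].to_numpy(dtype=np.int64)
        if "noise_flag" in df.columns
        else None,
    )
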