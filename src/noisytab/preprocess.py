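"""Median imputation and standardization, fitted on the training split only.

Statistics are computed once on the training data and applied unchanged to
validation and test splits, so no information leaks across splits: medians
over the observed (non-missing) training entries, then means and standard
deviations of the imputed training matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .synthetic_data import LabeledTable

__all__ = ["PreprocessState", "fit_preprocess", "apply_preprocess"]


@dataclass(frozen=True)
class PreprocessState:
    """Per-feature imputation and scaling statistics from a training split."""

    medians: np.ndarray
    means: np.ndarray
    stds: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.medians)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "medians": self.medians.tolist(),
                    "means": self.means.tolist(),
                    "stds": self.stds.tolist(),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "PreprocessState":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            medians=np.asarray(d["medians"], dtype=np.float64),
            means=np.asarray(d["means"], dtype=np.float64),
            stds=np.asarray(d["stds"], dtype=np.float64),
        )


def fit_preprocess(train: LabeledTable, on_constant: str = "error") -> PreprocessState:
    """Fit per-feature medians, then post-imputation means and stds.

    The median of an even number of observed values is the mean of the two
    central order statistics (numpy's convention).  A feature that is
    constant after imputation has zero standard deviation; by default this
    raises, since silently dividing by zero would poison training.  With
    ``on_constant="unit_scale"`` such features are passed through with unit
    scale instead.

    Raises
    ------
    ValueError
        If a feature has no observed value in the training split, or a
        constant feature is found under ``on_constant="error"``.
    """
    if on_constant not in ("error", "unit_scale"):
        raise ValueError(f"on_constant must be 'error' or 'unit_scale', got {on_constant!r}")
    X = train.features
    observed = ~np.isnan(X)
    empty = np.flatnonzero(observed.sum(axis=0) == 0)
    if empty.size:
        raise ValueError(f"feature {empty[0]} has no observed value in the training split")
    medians = np.nanmedian(X, axis=0)
    imputed = np.where(np.isnan(X), medians, X)
    means = imputed.mean(axis=0)
    stds = imputed.std(axis=0)
    constant = np.flatnonzero(stds == 0)
    if constant.size:
        if on_constant == "error":
            raise ValueError(
                f"feature {constant[0]} is constant on the training split after imputation"
            )
        stds = stds.copy()
        stds[constant] = 1.0
    return PreprocessState(medians=medians, means=means, stds=stds)


def apply_preprocess(state: PreprocessState, table: LabeledTable) -> LabeledTable:
    """Impute with training medians and standardize with training statistics.

    The output contains no missing entries.  Applying to the training split
    itself yields columns with mean 0 and std 1; on any other split the
    transformation is the same affine map, so column moments are whatever
    the data dictates (this asymmetry is the no-leakage contract).
    """
    if table.n_features != state.n_features:
        raise ValueError(
            f"feature-count mismatch: state has {state.n_features}, table has {table.n_features}"
        )
    X = table.features
    imputed = np.where(np.isnan(X), state.medians, X)
    scaled = (imputed - state.means) / state.stds
    return LabeledTable(
        features=scaled,
        labels=table.labels.copy(),
        clean_labels=table.clean_labels.copy(),
        noise_flags=table.noise_flags.copy(),
    )
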