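"""Desk-scale experiment runner: noise sweep x method matrix, and NCR ablations.

The sweep reproduces the study design on synthetic cohorts: for every
(noise level, seed) the *same* corrupted training split is shared by all
methods, thresholds are tuned on the validation split to a target
sensitivity, and evaluation always uses the clean test labels (test sets are
never corrupted).  Besides per-cell metrics, the runner reports each
method's mean and standard deviation of AUROC across noise levels — the
consistency statistic: a noise-robust method keeps a small standard
deviation as corruption grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .diagnostics import confidence_trace, similarity_strata
from .evaluation import compute_metrics, tune_threshold
from .losses import MixupSpec, NCRSpec, SmoothingSpec
from .model import MLPConfig, train_gbt_baseline
from .preprocess import apply_preprocess, fit_preprocess
from .synthetic_data import (
    CohortSpec,
    LabeledTable,
    NoiseSpec,
    generate_cohort,
    inject_label_noise,
    split_cohort,
)
from .training import TrainConfig, train_model

__all__ = [
    "SweepSpec",
    "run_sweep",
    "summarize_sweep",
    "run_ncr_ablation",
    "run_memorization_diagnostics",
    "ABLATION_AXES",
]

DEFAULT_NOISE_LEVELS = (0.0, 0.1, 0.2, 0.3, 0.4)
ABLATION_AXES = ("warmup_epoch", "ncr_weight", "k", "ncr_layer", "batch_size")


@dataclass(frozen=True)
class SweepSpec:
    """Noise sweep x method matrix on a synthetic cohort.

    ``noise_levels`` are false-negative rates applied to the cases;
    ``fp_rate`` stays fixed across levels (mirroring near-perfect test
    specificity).  ``n_seeds`` independent cohorts/initializations are run
    per cell.
    """

    cohort: CohortSpec = field(default_factory=lambda: CohortSpec(n_samples=6000, n_features=20))
    noise_levels: tuple[float, ...] = DEFAULT_NOISE_LEVELS
    fp_rate: float = 0.005
    methods: tuple[str, ...] = ("baseline", "ncr")
    n_seeds: int = 5
    mlp: MLPConfig = field(default_factory=MLPConfig)
    ncr: NCRSpec = field(default_factory=NCRSpec)
    mixup: MixupSpec = field(default_factory=MixupSpec)
    smoothing: SmoothingSpec = field(default_factory=SmoothingSpec)
    gbt_params: dict | None = None
    target_sensitivity: float = 0.85

    def __post_init__(self) -> None:
        for fn in self.noise_levels:
            NoiseSpec(fn_rate=fn, fp_rate=self.fp_rate)  # validates ranges
        known = {"baseline", "smoothing", "mixup", "ncr", "mixup+ncr", "gbt"}
        unknown = set(self.methods) - known
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def _noise_seed(seed: int, fn_rate: float) -> int:
    """Deterministic corruption seed per (seed, noise level), shared across methods."""
    return seed * 1009 + int(round(fn_rate * 1000))


def _prepare_splits(spec: SweepSpec, seed: int):
    cohort = generate_cohort(replace(spec.cohort, seed=spec.cohort.seed + seed))
    train, val, test = split_cohort(cohort, seed=seed)
    state = fit_preprocess(train)
    return train, apply_preprocess(state, val), apply_preprocess(state, test), state


def _train_config(spec: SweepSpec, method: str, seed: int, **kwargs) -> TrainConfig:
    return TrainConfig(
        mlp=replace(spec.mlp, seed=seed),
        method=method,
        smoothing=spec.smoothing,
        mixup=replace(spec.mixup, seed=seed),
        ncr=spec.ncr,
        seed=seed,
        **kwargs,
    )


def run_sweep(spec: SweepSpec, progress=None) -> pd.DataFrame:
    """Run the full (noise level x method x seed) matrix.

    Returns one row per cell with the clean-test metrics at the tuned
    threshold.  A failing cell is recorded with ``error`` filled and NaN
    metrics; the sweep continues.  ``progress`` may be a callable invoked
    with a short status string per cell.
    """
    rows = []
    for seed in range(spec.n_seeds):
        train_raw, val, test, state = _prepare_splits(spec, seed)
        for fn_rate in spec.noise_levels:
            noise = NoiseSpec(fn_rate=fn_rate, fp_rate=spec.fp_rate,
                              seed=_noise_seed(seed, fn_rate))
            noisy_train = apply_preprocess(state, inject_label_noise(train_raw, noise))
            for method in spec.methods:
                if progress:
                    progress(f"seed={seed} fn={fn_rate:.2f} method={method}")
                row = {"noise": fn_rate, "method": method, "seed": seed}
                try:
                    if method == "gbt":
                        scorer = train_gbt_baseline(noisy_train, spec.gbt_params)
                    else:
                        model, _ = train_model(
                            noisy_train, val, _train_config(spec, method, seed)
                        )
                        scorer = model.predict_proba
                    thr = tune_threshold(
                        val.labels, scorer(val.features), spec.target_sensitivity
                    )
                    row["threshold"] = thr
                    row.update(
                        compute_metrics(test.clean_labels, scorer(test.features), thr)
                    )
                    row["error"] = ""
                except Exception as exc:  # record and continue
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_sweep(results: pd.DataFrame) -> pd.DataFrame:
    """Per-method consistency summary across noise levels.

    Seeds are averaged within each (method, noise) cell first; the reported
    ``std_auroc_across_noise`` is the standard deviation of those per-level
    means over the noise levels (ddof=0).
    """
    ok = results[results["error"] == ""] if "error" in results else results
    per_level = ok.groupby(["method", "noise"])["auroc"].mean().reset_index()
    out = (
        per_level.groupby("method")["auroc"]
        .agg(mean_auroc="mean", std_auroc_across_noise=lambda x: float(np.std(x, ddof=0)))
        .reset_index()
    )
    return out


def run_ncr_ablation(
    spec: SweepSpec, axis: str, values: tuple, progress=None
) -> pd.DataFrame:
    """Sweep one NCR-related hyperparameter, holding everything else fixed.

    ``axis`` is one of ``warmup_epoch``, ``ncr_weight``, ``k``, ``ncr_layer``
    or ``batch_size``; each value runs a full NCR-only noise sweep and rows
    are tagged with the axis and value.
    """
    if axis not in ABLATION_AXES:
        raise ValueError(f"axis must be one of {ABLATION_AXES}, got {axis!r}")
    frames = []
    for value in values:
        if axis == "warmup_epoch":
            mod = replace(spec, ncr=replace(spec.ncr, warmup_epochs=int(value)))
        elif axis == "ncr_weight":
            mod = replace(spec, ncr=replace(spec.ncr, weight=float(value)))
        elif axis == "k":
            mod = replace(spec, ncr=replace(spec.ncr, k=int(value)))
        elif axis == "ncr_layer":
            mod = replace(spec, mlp=replace(spec.mlp, ncr_layer=int(value)))
        else:  # batch_size
            mod = replace(spec, mlp=replace(spec.mlp, batch_size=int(value)))
        df = run_sweep(replace(mod, methods=("ncr",)), progress=progress)
        df["axis"] = axis
        df["value"] = value
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_memorization_diagnostics(
    spec: SweepSpec,
    fn_rate: float = 0.4,
    seeds: tuple[int, ...] = (0, 1, 2),
    methods: tuple[str, ...] = ("baseline", "ncr"),
    n_epochs: int | None = 150,
) -> dict[str, dict[str, list]]:
    """Paired diagnostic runs at one noise level with per-sample tracking.

    For each seed and method, trains with confidence recording on the same
    corrupted split and collects the confidence trace (clean vs mislabelled
    training samples) and the latent similarity strata on the corrupted
    training set.  Returns, per method, lists of :class:`ConfidenceTrace`
    and :class:`SimilarityStrata` objects plus the derived scalar signatures.

    Memorization of mislabelled samples is a late-training phenomenon, so
    these runs default to a longer schedule (``n_epochs=150``) than the
    performance sweep; pass ``n_epochs=None`` to keep the sweep's setting.
    """
    if n_epochs is not None:
        spec = replace(spec, mlp=replace(spec.mlp, n_epochs=n_epochs))
    out: dict[str, dict[str, list]] = {
        m: {"traces": [], "strata": [], "final_conf_mislabeled": [], "separation_gap": []}
        for m in methods
    }
    for seed in seeds:
        train_raw, val, _test, state = _prepare_splits(spec, seed)
        noise = NoiseSpec(fn_rate=fn_rate, fp_rate=spec.fp_rate,
                          seed=_noise_seed(seed, fn_rate))
        noisy_train = apply_preprocess(state, inject_label_noise(train_raw, noise))
        for method in methods:
            cfg = _train_config(spec, method, seed, record_confidence=True)
            model, history = train_model(noisy_train, val, cfg)
            trace = confidence_trace(history, noisy_train.noise_flags)
            strata = similarity_strata(model, noisy_train, seed=seed)
            out[method]["traces"].append(trace)
            out[method]["strata"].append(strata)
            out[method]["final_conf_mislabeled"].append(float(trace.mean_mislabeled[-1]))
            out[method]["separation_gap"].append(strata.class_separation_gap)
    return out
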