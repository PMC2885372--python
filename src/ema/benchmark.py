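"""Benchmark protocols: repeated synthetic runs and subsampling studies.

Two protocols are provided.  ``run_synthetic_benchmark`` repeats the
standard controlled experiment (fresh synthetic training/validation draw
per run, 25/475 samples by default) and aggregates selection-size,
recovery-rate and validation-accuracy statistics over the runs.
``run_subsample_benchmark`` applies the generic sampling-rate protocol to a
given dataset: per run a stratified fraction ``r`` of each class forms the
training set and either a fixed hold-out set or the complement is scored.

Per-run seeds are ``base_seed + run`` so any single run can be replayed in
isolation; the aggregate statistics are a pure function of the per-run log.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, FeatureSet
from .margin import DEFAULT_C, fit_max_margin
from .pipeline import EMAConfig, extract_features, ttest_filter
from .synthetic import SyntheticConfig, generate_synthetic, true_feature_indices

__all__ = [
    "MethodSummary",
    "BenchmarkSummary",
    "validation_accuracy",
    "hit_miss_rates",
    "summarize_runs",
    "run_synthetic_benchmark",
    "run_subsample_benchmark",
]

logger = logging.getLogger(__name__)

RUN_COLUMNS = [
    "run", "seed", "method", "n_selected", "n_true",
    "hit_rate", "miss_rate", "accuracy",
]


def validation_accuracy(
    train: ExpressionDataset,
    valid: ExpressionDataset,
    features: FeatureSet,
    C: float = DEFAULT_C,
) -> float:
    """Accuracy of a max-margin linear classifier on held-out samples.

    The classifier is fit on ``train`` restricted to the selected genes and
    scored on ``valid``; a zero decision value counts as an error.
    """
    if features.f0 == 0:
        raise ValueError("cannot fit a classifier on an empty feature set")
    if not np.array_equal(train.gene_ids, valid.gene_ids):
        raise ValueError("train and validation sets must share gene_ids")
    plane = fit_max_margin(train, C=C, genes=features.indices)
    scores = plane.decision(valid.values[:, features.indices])
    return float(np.mean(np.sign(scores) == valid.labels))


def hit_miss_rates(features, truth) -> tuple[float, float]:
    """Hitting and missing (redundancy) rate of a selection against truth.

    ``r_h = f_A / |truth|`` is the fraction of true feature genes recovered;
    ``r_m = (f - f_A) / f`` the fraction of selected genes that are not true
    features.  An empty selection has undefined ``r_m``; it is reported as 0
    with a warning.
    """
    sel = np.asarray(getattr(features, "indices", features), dtype=int)
    truth = np.asarray(list(truth), dtype=int)
    if truth.size == 0:
        raise ValueError("truth set must be nonempty")
    f_a = int(np.isin(sel, truth).sum())
    r_h = f_a / truth.size
    if sel.size == 0:
        warnings.warn("empty selection: missing rate undefined, reported as 0")
        return r_h, 0.0
    return r_h, (sel.size - f_a) / sel.size


@dataclass
class MethodSummary:
    """Aggregate statistics of one method over the benchmark runs."""

    n_runs: int
    count_mean: float
    count_std: float
    count_median: float
    count_min: float
    count_max: float
    true_mean: float
    hit_rate_mean: float
    miss_rate_mean: float
    accuracy_mean: float
    accuracy_std: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class BenchmarkSummary:
    """Per-run log plus per-method aggregates of a benchmark."""

    runs: pd.DataFrame
    methods: dict[str, MethodSummary] = field(default_factory=dict)
    n_runs: int = 0
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            self.methods = summarize_runs(self.runs)


def summarize_runs(runs: pd.DataFrame) -> dict[str, MethodSummary]:
    """Aggregate a per-run log into per-method statistics.

    Pure function of the log: re-running it on a persisted ``runs`` table
    reproduces the summary exactly.  Sample standard deviations (ddof=1)
    are reported, 0 for a single run.
    """
    out: dict[str, MethodSummary] = {}
    for method, grp in runs.groupby("method", sort=False):
        counts = grp["n_selected"].to_numpy(dtype=float)
        acc = grp["accuracy"].to_numpy(dtype=float)
        acc_ok = acc[np.isfinite(acc)]
        std = float(np.std(counts, ddof=1)) if counts.size > 1 else 0.0
        acc_std = float(np.std(acc_ok, ddof=1)) if acc_ok.size > 1 else 0.0
        out[str(method)] = MethodSummary(
            n_runs=int(counts.size),
            count_mean=float(counts.mean()),
            count_std=std,
            count_median=float(np.median(counts)),
            count_min=float(counts.min()),
            count_max=float(counts.max()),
            true_mean=float(grp["n_true"].mean()),
            hit_rate_mean=float(grp["hit_rate"].mean()),
            miss_rate_mean=float(grp["miss_rate"].mean()),
            accuracy_mean=float(acc_ok.mean()) if acc_ok.size else float("nan"),
            accuracy_std=acc_std,
        )
    return out


def _apply_methods(
    methods, train, valid, truth, ema_cfg, ttt_cutoff, run, seed,
) -> list[dict]:
    rows = []
    for method in methods:
        if method == "ema":
            sel = extract_features(train, ema_cfg).features
        elif method == "ttt":
            sel = ttest_filter(train, cutoff=ttt_cutoff,
                               variant=ema_cfg.ttest_variant)
        else:
            raise ValueError(f"unknown method {method!r}; expected 'ema'/'ttt'")
        if truth is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r_h, r_m = hit_miss_rates(sel, truth)
            n_true = int(np.isin(sel.indices, truth).sum())
        else:
            r_h = r_m = n_true = float("nan")
        if valid is not None and sel.f0 > 0:
            acc = validation_accuracy(train, valid, sel, C=ema_cfg.C)
        else:
            acc = float("nan")
        rows.append(dict(
            run=run, seed=seed, method=method, n_selected=sel.f0,
            n_true=n_true, hit_rate=r_h, miss_rate=r_m, accuracy=acc,
        ))
    return rows


def run_synthetic_benchmark(
    methods=("ema", "ttt"),
    n_runs: int = 100,
    base_seed: int = 0,
    synth_cfg: SyntheticConfig | None = None,
    ema_cfg: EMAConfig | None = None,
    ttt_cutoff: float = 0.005,
) -> BenchmarkSummary:
    """Repeat the controlled synthetic experiment ``n_runs`` times.

    Per run: draw fresh training/validation sets (seed ``base_seed + run``),
    run each method on the training set, score recovery of the true feature
    block and validation accuracy.  Fully reproducible from ``base_seed``.
    Per-run failures are logged and recorded as missing rows; the summary
    aggregates the successful runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    synth_cfg = SyntheticConfig() if synth_cfg is None else synth_cfg
    ema_cfg = EMAConfig() if ema_cfg is None else ema_cfg
    truth = true_feature_indices(synth_cfg)

    rows: list[dict] = []
    n_failed = 0
    for run in range(n_runs):
        seed = base_seed + run
        cfg = SyntheticConfig(**{**synth_cfg.__dict__, "seed": seed})
        train, valid = generate_synthetic(cfg)
        try:
            rows.extend(_apply_methods(
                methods, train, valid, truth, ema_cfg, ttt_cutoff, run, seed,
            ))
        except Exception:
            n_failed += 1
            logger.exception("benchmark run %d (seed %d) failed", run, seed)
    if n_failed:
        logger.warning("%d of %d runs failed; summary covers the rest",
                       n_failed, n_runs)
    runs = pd.DataFrame(rows, columns=RUN_COLUMNS)
    if runs.empty:
        raise RuntimeError("all benchmark runs failed")
    return BenchmarkSummary(runs=runs, n_runs=n_runs, base_seed=base_seed)


def _stratified_pick(rng, labels, rate):
    train_idx, rest_idx = [], []
    for cls in (-1, 1):
        members = np.flatnonzero(labels == cls)
        k = int(np.floor(rate * members.size))
        if k < 2:
            raise ValueError(
                f"sampling rate {rate} leaves {k} < 2 training samples of class {cls}"
            )
        picked = rng.choice(members, size=k, replace=False)
        train_idx.append(picked)
        rest_idx.append(np.setdiff1d(members, picked))
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(rest_idx))


def _rows_subset(ds: ExpressionDataset, idx: np.ndarray) -> ExpressionDataset:
    return ExpressionDataset(
        values=ds.values[idx],
        labels=ds.labels[idx],
        gene_ids=ds.gene_ids.copy(),
        sample_ids=ds.sample_ids[idx],
    )


def run_subsample_benchmark(
    ds: ExpressionDataset,
    rate: float,
    n_runs: int = 100,
    base_seed: int = 0,
    valid: ExpressionDataset | None = None,
    methods=("ema",),
    ema_cfg: EMAConfig | None = None,
    ttt_cutoff: float = 0.005,
    truth=None,
) -> BenchmarkSummary:
    """Sampling-rate protocol on a fixed dataset.

    Per run, ``floor(rate * n_class)`` samples of each class (at least 2)
    are drawn without replacement as the training set.  If ``valid`` is
    given it is the fixed hold-out set; otherwise the complement of the
    training draw is scored, so ``rate`` must leave it nonempty.
    ``truth`` (optional true feature indices) enables hit/miss rates.
    """
    if not 0 < rate <= 1:
        raise ValueError("sampling rate must be in (0, 1]")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    ema_cfg = EMAConfig() if ema_cfg is None else ema_cfg

    rows: list[dict] = []
    for run in range(n_runs):
        seed = base_seed + run
        rng = np.random.default_rng(seed)
        train_idx, rest_idx = _stratified_pick(rng, ds.labels, rate)
        train = _rows_subset(ds, train_idx)
        if valid is not None:
            hold_out = valid
        else:
            if rest_idx.size == 0:
                raise ValueError(
                    "rate leaves an empty complement; supply a validation set"
                )
            hold_out = _rows_subset(ds, rest_idx)
        rows.extend(_apply_methods(
            methods, train, hold_out, truth, ema_cfg, ttt_cutoff, run, seed,
        ))
    runs = pd.DataFrame(rows, columns=RUN_COLUMNS)
    return BenchmarkSummary(runs=runs, n_runs=n_runs, base_seed=base_seed)
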