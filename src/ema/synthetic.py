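"""Synthetic two-class expression benchmark and ideal margin-curve fixtures.

The benchmark emulates a controlled microarray study: each pattern has
``d_total`` genes of which the first ``n_feature`` are true feature genes
whose class-conditional distributions are Gaussian with a constant mean
separation of 0.4, and the rest are background genes drawn uniformly for
both classes.  With the defaults (500 genes, 20 features, 25 training and
475 validation patterns, balanced classes) the generator reproduces the
standard configuration used throughout the package's benchmarks.

Feature-gene parameters follow the linear schedules

    mu_i    = 0.3  - i * 0.05/20     (class -1 mean)
    sigma_i = 0.15 - i * 0.05/20     (class -1 SD)
    alpha_i = 0.7  - i * 0.05/20     (class +1 mean)
    beta_i  = 0.15 - i * 0.05/20     (class +1 SD)

for 1-based feature index ``i``, so ``alpha_i - mu_i = 0.4`` for every
feature while the within-class SD shrinks from 0.1475 to 0.10.  The 0.05/20
step is a fixed constant of the schedule (it does not rescale with
``n_feature``); SDs must stay positive.

Gaussian draws are not clipped: the extraction method is
translation-invariant, so occasional negative intensities are harmless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ExpressionDataset
from .margin import MarginCurve

__all__ = [
    "SyntheticConfig",
    "FeatureGeneParams",
    "feature_gene_params",
    "generate_synthetic",
    "generate_ideal_curve",
    "true_feature_indices",
]

_STEP = 0.05 / 20.0


@dataclass
class FeatureGeneParams:
    """Class-conditional Gaussian parameters of one feature gene."""

    mu: float
    sigma: float
    alpha: float
    beta: float


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic benchmark generator.

    ``class_balance`` is the fraction of positive-class samples; with an odd
    sample count the training set rounds the positive count up and the
    validation set rounds it down.  ``sd_scale`` multiplies every
    class-conditional SD of the feature genes (1.0 = the standard benchmark;
    smaller values sharpen the margin-curve knee for controlled studies).
    """

    d_total: int = 500
    n_feature: int = 20
    n_train: int = 25
    n_valid: int = 475
    class_balance: float = 0.5
    background_range: tuple[float, float] = (0.0, 1.0)
    sd_scale: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.n_feature <= self.d_total:
            raise ValueError("need 0 < n_feature <= d_total")
        if self.n_train < 0 or self.n_valid < 0:
            raise ValueError("sample counts must be nonnegative")
        if not 0.0 <= self.class_balance <= 1.0:
            raise ValueError("class_balance must be in [0, 1]")
        lo, hi = self.background_range
        if not lo < hi:
            raise ValueError("background_range must be a nonempty interval")
        if self.sd_scale <= 0:
            raise ValueError("sd_scale must be positive")
        # Validate the whole parameter schedule up front.
        feature_gene_params(self.n_feature, self.n_feature)


def feature_gene_params(i: int, n_feature: int = 20) -> FeatureGeneParams:
    """Gaussian parameters of the ``i``-th feature gene (1-based)."""
    if not 1 <= i <= n_feature:
        raise ValueError(f"feature index must be in [1, {n_feature}], got {i}")
    p = FeatureGeneParams(
        mu=0.3 - i * _STEP,
        sigma=0.15 - i * _STEP,
        alpha=0.7 - i * _STEP,
        beta=0.15 - i * _STEP,
    )
    if p.sigma <= 0 or p.beta <= 0:
        raise ValueError(f"feature index {i} yields a non-positive SD")
    return p


def true_feature_indices(cfg: SyntheticConfig) -> np.ndarray:
    """0-based column indices of the true feature genes (the first block)."""
    return np.arange(cfg.n_feature)


def _gene_ids(d: int) -> np.ndarray:
    width = len(str(d))
    return np.array([f"g{k:0{width}d}" for k in range(1, d + 1)], dtype=object)


def _draw(rng: np.random.Generator, cfg: SyntheticConfig, n: int, n_pos: int,
          prefix: str) -> ExpressionDataset:
    n_neg = n - n_pos
    labels = np.r_[np.full(n_neg, -1), np.full(n_pos, 1)]
    values = np.empty((n, cfg.d_total))
    idx = np.arange(1, cfg.n_feature + 1)
    mu, sigma = 0.3 - idx * _STEP, (0.15 - idx * _STEP) * cfg.sd_scale
    alpha, beta = 0.7 - idx * _STEP, (0.15 - idx * _STEP) * cfg.sd_scale
    values[:n_neg, : cfg.n_feature] = rng.normal(mu, sigma, (n_neg, cfg.n_feature))
    values[n_neg:, : cfg.n_feature] = rng.normal(alpha, beta, (n_pos, cfg.n_feature))
    lo, hi = cfg.background_range
    values[:, cfg.n_feature:] = rng.uniform(lo, hi, (n, cfg.d_total - cfg.n_feature))
    sample_ids = np.array([f"{prefix}{j + 1}" for j in range(n)], dtype=object)
    return ExpressionDataset(values, labels, _gene_ids(cfg.d_total), sample_ids)


def generate_synthetic(
    cfg: SyntheticConfig | None = None,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Draw disjoint training and validation sets from the benchmark model.

    Deterministic under a fixed ``cfg.seed`` (train is drawn first, then
    validation, from one generator stream).
    """
    cfg = SyntheticConfig() if cfg is None else cfg
    rng = np.random.default_rng(cfg.seed)
    n_pos_train = int(np.ceil(cfg.n_train * cfg.class_balance))
    n_pos_valid = int(np.floor(cfg.n_valid * cfg.class_balance))
    train = _draw(rng, cfg, cfg.n_train, n_pos_train, "train_s")
    valid = _draw(rng, cfg, cfg.n_valid, n_pos_valid, "valid_s")
    return train, valid


def generate_ideal_curve(
    n_R: int,
    f_max: int,
    slope_R: float,
    slope_I: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> MarginCurve:
    """Piecewise-linear margin-curve fixture with a known breakpoint.

    ``W(i) = slope_R * i`` up to the breakpoint ``n_R`` and continues with
    slope ``slope_I`` beyond it; i.i.d. Gaussian oscillation of SD
    ``noise_sd`` is superimposed.  Models the idealised expected error
    margin: a steep relevant-gene segment followed by a shallow
    irrelevant-gene segment, blurred by finite-sample oscillation.
    """
    if not 1 <= n_R < f_max:
        raise ValueError(f"breakpoint must satisfy 1 <= n_R < f_max, got {n_R}")
    if not slope_R > slope_I >= 0:
        raise ValueError("need slope_R > slope_I >= 0")
    i = np.arange(1, f_max + 1, dtype=float)
    W = np.where(i <= n_R, slope_R * i, slope_R * n_R + slope_I * (i - n_R))
    if noise_sd:
        W = W + np.random.default_rng(seed).normal(0.0, noise_sd, f_max)
    return MarginCurve(
        values=W,
        meta={"n_R": n_R, "slope_R": slope_R, "slope_I": slope_I,
              "noise_sd": noise_sd, "seed": seed},
    )
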