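"""End-to-end feature-gene extraction: rank, curve, critical point.

:func:`extract_features` chains the full error-margin analysis: build the
t-test relevance list, permute genes into relevance order, compute the
leave-one-out error-margin curve up to ``f_max`` genes, locate the critical
point of the continuity-constrained two-segment polynomial fit, and return
the ``f0`` most relevant genes.  :func:`ttest_filter` is the classical
filter baseline that keeps every gene whose p-value clears a fixed cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .breakpoint import SegmentedFit, find_critical_point
from .datasets import DatasetError, ExpressionDataset, FeatureSet
from .margin import DEFAULT_C, MarginCurve, margin_curve
from .ranking import RelevanceList, build_relevance_list, reorder

__all__ = ["EMAConfig", "EMAResult", "extract_features", "ttest_filter"]


@dataclass
class EMAConfig:
    """Tunable parameters of the extraction pipeline.

    ``f_max`` caps the number of most-relevant genes scanned (the number of
    feature genes is assumed well below it); ``gamma`` is the polynomial
    order of the two fitted curve segments; ``C`` the soft-margin penalty of
    the underlying linear SVM; ``ttest_variant`` selects pooled or Welch
    p-values for the ranking.
    """

    f_max: int = 100
    gamma: int = 2
    C: float = DEFAULT_C
    ttest_variant: str = "pooled"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.f_max < 1:
            raise ValueError("f_max must be >= 1")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class EMAResult:
    """Everything one extraction run produced."""

    features: FeatureSet
    curve: MarginCurve
    fits: list[SegmentedFit]
    relevance: RelevanceList
    config: EMAConfig = field(default_factory=EMAConfig)

    @property
    def f0(self) -> int:
        return self.features.f0


def extract_features(
    ds: ExpressionDataset,
    cfg: EMAConfig | None = None,
) -> EMAResult:
    """Run the full error-margin analysis on a two-class dataset.

    Returns the selected genes (the ``f0`` most relevant ones, reported in
    original gene coordinates, rank order), the margin curve, the
    per-candidate segmented fits and the relevance list.  Deterministic
    given ``(ds, cfg)``.
    """
    cfg = EMAConfig() if cfg is None else cfg
    if ds.n_samples < 3:
        raise DatasetError("need at least 3 samples for leave-one-out folds")
    f_max = min(cfg.f_max, ds.n_genes)

    try:
        relevance = build_relevance_list(ds, variant=cfg.ttest_variant)
    except Exception as err:
        raise type(err)(f"[ranking] {err}") from err
    ordered = reorder(ds, relevance)
    try:
        curve = margin_curve(ordered, f_max=f_max, C=cfg.C)
    except Exception as err:
        raise type(err)(f"[margin curve] {err}") from err
    try:
        f0, fits = find_critical_point(curve, gamma=cfg.gamma)
    except Exception as err:
        raise type(err)(f"[critical point] {err}") from err

    idx = relevance.order[:f0]
    features = FeatureSet(indices=idx, gene_ids=ds.gene_ids[idx])
    return EMAResult(
        features=features, curve=curve, fits=fits,
        relevance=relevance, config=cfg,
    )


def ttest_filter(
    ds: ExpressionDataset,
    cutoff: float = 0.005,
    variant: str = "pooled",
) -> FeatureSet:
    """Keep genes with two-sample t-test p-value strictly below ``cutoff``.

    The filter baseline: selection size depends directly on the cutoff and
    on sample size, unlike the margin-curve criterion.  Genes are returned
    in relevance order (ascending p).
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be a p-value in [0, 1]")
    L = build_relevance_list(ds, variant=variant)
    n_sel = int((L.pvalues < cutoff).sum())
    idx = L.order[:n_sel]
    return FeatureSet(indices=idx, gene_ids=ds.gene_ids[idx])
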