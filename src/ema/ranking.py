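"""Per-gene relevance ranking by two-sample t-test p-values.

Each gene's relevance is measured by the two-sided two-sample t-test between
its expression values in the negative and positive classes; the gene
relevance list orders genes by ascending p-value (descending relevance),
ties broken by original gene index.  The classical pooled-variance test is
the default; Welch's unequal-variance variant is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import DatasetError, ExpressionDataset

__all__ = ["RelevanceList", "gene_pvalue", "build_relevance_list", "reorder"]

logger = logging.getLogger(__name__)


@dataclass
class RelevanceList:
    """Gene ordering by decreasing relevance.

    ``order[k]`` is the original index of the gene at rank ``k`` (rank 0 =
    most relevant).  ``pvalues`` and ``relevance`` are aligned to the
    ORIGINAL gene order, not to ranks.
    """

    order: np.ndarray
    pvalues: np.ndarray
    relevance: np.ndarray
    gene_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        self.relevance = np.asarray(self.relevance, dtype=float)
        d = self.order.size
        if sorted(self.order.tolist()) != list(range(d)):
            raise ValueError("order must be a permutation of 0..d-1")
        if self.pvalues.shape != (d,) or self.relevance.shape != (d,):
            raise ValueError("pvalues/relevance must align with order length")

    def __len__(self) -> int:
        return int(self.order.size)

    def inverse(self) -> np.ndarray:
        """Permutation sending rank position back to original position."""
        inv = np.empty_like(self.order)
        inv[self.order] = np.arange(self.order.size)
        return inv


def gene_pvalue(a, b, equal_var: bool = True) -> float:
    """Two-sided two-sample t-test p-value between value groups ``a``, ``b``.

    Degenerate input (all values identical in both groups, so the statistic
    is 0/0) returns p = 1 by convention and is logged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    if np.isnan(p):
        logger.info("degenerate t-test (zero variance, equal means): p := 1")
        return 1.0
    return p


def build_relevance_list(
    ds: ExpressionDataset,
    variant: str = "pooled",
) -> RelevanceList:
    """Rank all genes of ``ds`` by two-sample t-test p-value.

    ``variant`` is ``"pooled"`` (classical equal-variance test, default) or
    ``"welch"``.  Relevance is ``1 - p``; ranking by descending relevance is
    identical to ranking by ascending p, with ties broken by ascending
    original gene index (stable sort).
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    neg, pos = ds.class_split()
    if len(neg) < 2 or len(pos) < 2:
        raise DatasetError("both classes need >= 2 samples to rank genes")
    res = stats.ttest_ind(neg, pos, axis=0, equal_var=(variant == "pooled"))
    pvalues = np.asarray(res.pvalue, dtype=float)
    n_degen = int(np.isnan(pvalues).sum())
    if n_degen:
        logger.info("%d gene(s) with degenerate t-test; p := 1", n_degen)
        pvalues = np.nan_to_num(pvalues, nan=1.0)
    order = np.argsort(pvalues, kind="stable")
    return RelevanceList(
        order=order,
        pvalues=pvalues,
        relevance=1.0 - pvalues,
        gene_ids=ds.gene_ids.copy(),
    )


def reorder(ds: ExpressionDataset, L: RelevanceList) -> ExpressionDataset:
    """Permute gene columns of ``ds`` into relevance order (labels untouched)."""
    if L.gene_ids is not None and (
        len(L.gene_ids) != ds.n_genes or not np.array_equal(L.gene_ids, ds.gene_ids)
    ):
        raise DatasetError("relevance list was built from a different gene set")
    return ExpressionDataset(
        values=ds.values[:, L.order],
        labels=ds.labels.copy(),
        gene_ids=ds.gene_ids[L.order],
        sample_ids=ds.sample_ids.copy(),
    )
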