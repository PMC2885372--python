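"""Maximum-margin linear classification and the leave-one-out error margin.

The error margin of a linear decision function ``f(x) = <h, x> + b`` over a
labelled pattern set is the minimum geometric margin ``y_j f(x_j) / ||h||``.
For a hard-margin SVM this quantity is maximal and equal across the two
classes.  The *leave-one-out error margin* (LOOErM) of a training set is the
average, over folds that each omit one pattern, of the error margin of the
hyperplane fit to the remaining patterns, measured over those remaining
patterns (restricted to the correctly classified ones, which reduces the
non-separable case to the separable one).

The *error margin curve* ``W(i)`` is the LOOErM as a function of ``i``, the
number of most-relevant genes included, for a dataset already sorted in
relevance order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .datasets import ExpressionDataset

__all__ = [
    "Hyperplane",
    "MarginCurve",
    "DegenerateFoldError",
    "fit_max_margin",
    "geometric_margin",
    "loo_error_margin",
    "margin_curve",
]

logger = logging.getLogger(__name__)

#: Default soft-margin penalty: effectively hard-margin on unit-scale
#: expression data, while still defined for non-separable folds.
DEFAULT_C = 100.0


class DegenerateFoldError(RuntimeError):
    """No usable margin: single-class data or nothing correctly classified."""


@dataclass
class Hyperplane:
    """Linear decision function ``x -> <weights, x> + bias``."""

    weights: np.ndarray
    bias: float
    C: float = DEFAULT_C
    converged: bool = True

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.linalg.norm(self.weights) > 0:
            raise ValueError("hyperplane must have a nonzero weight vector")

    def decision(self, values: np.ndarray) -> np.ndarray:
        return np.atleast_2d(values) @ self.weights + self.bias


@dataclass
class MarginCurve:
    """``W(i)`` for ``i = 1..f_max`` plus provenance metadata."""

    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("margin curve must have at least one point")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("margin curve entries must be finite")

    @property
    def f_max(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.f_max


#: Solver stopping tolerance.  Tight enough that margins are reproducible
#: to ~1e-6 relative regardless of sample ordering; the problems here are
#: tiny, so the extra iterations are essentially free.
SOLVER_TOL = 1e-8


def _fit_linear(X: np.ndarray, y: np.ndarray, C: float):
    """Raw libsvm fit; returns (weights, bias, converged)."""
    svc = SVC(kernel="linear", C=C, tol=SOLVER_TOL)
    svc.fit(X, y)
    return svc.coef_[0].copy(), float(svc.intercept_[0]), svc.fit_status_ == 0


def fit_max_margin(
    ds: ExpressionDataset,
    C: float = DEFAULT_C,
    genes=None,
) -> Hyperplane:
    """Fit a soft-margin maximum-margin linear classifier.

    With separable data and large ``C`` the solution approaches the
    hard-margin optimum (support vectors at functional margin 1).

    Parameters
    ----------
    genes
        Optional gene-column subset (indices into ``ds``); default all genes.
    """
    if len(set(ds.labels)) < 2:
        raise DegenerateFoldError("both classes required to fit a classifier")
    X = ds.values if genes is None else ds.values[:, np.asarray(genes, dtype=int)]
    if X.shape[1] < 1:
        raise ValueError("at least one gene required")
    w, b, ok = _fit_linear(X, ds.labels, C)
    if not ok:
        logger.warning(
            "SVM solver did not fully converge (C=%g, dataset %s)",
            C,
            ds.content_hash(),
        )
    return Hyperplane(weights=w, bias=b, C=C, converged=ok)


def geometric_margin(
    plane: Hyperplane,
    values: np.ndarray,
    labels: np.ndarray,
    correct_only: bool = False,
) -> float:
    """Minimum signed distance ``y_j (<h, x_j> + b) / ||h||`` over patterns.

    With ``correct_only`` the minimum is over patterns with positive
    functional margin only; an empty eligible set raises
    :class:`DegenerateFoldError`.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = np.asarray(labels, dtype=float).ravel()
    margins = labels * plane.decision(values) / np.linalg.norm(plane.weights)
    if correct_only:
        margins = margins[margins > 0]
        if margins.size == 0:
            raise DegenerateFoldError("no correctly classified pattern")
    elif margins.size == 0:
        raise DegenerateFoldError("empty pattern set")
    return float(margins.min())


def _loo(X: np.ndarray, y: np.ndarray, C: float) -> float:
    """LOOErM over the pattern set (X, y); lean inner loop shared by the
    public entry points so curve values and direct calls agree exactly."""
    n = len(y)
    margins = []
    skipped = 0
    for j in range(n):
        keep = np.ones(n, dtype=bool)
        keep[j] = False
        yz = y[keep]
        if np.all(yz == yz[0]):
            skipped += 1
            continue
        Xz = X[keep]
        w, b, _ = _fit_linear(Xz, yz, C)
        m = yz * (Xz @ w + b) / np.linalg.norm(w)
        m = m[m > 0]
        if m.size == 0:
            skipped += 1
            continue
        margins.append(m.min())
    if skipped:
        logger.info("LOOErM: skipped %d degenerate fold(s) of %d", skipped, n)
    if not margins:
        raise DegenerateFoldError("all leave-one-out folds were degenerate")
    return float(np.mean(margins))


def loo_error_margin(
    ds: ExpressionDataset,
    genes=None,
    C: float = DEFAULT_C,
) -> float:
    """Leave-one-out error margin of ``ds`` restricted to ``genes``.

    Each fold omits one pattern, fits the max-margin hyperplane on the
    remainder ``Z``, and takes the geometric margin of that hyperplane over
    the correctly classified patterns of ``Z``.  Folds whose remainder is
    single-class or entirely misclassified are skipped (and logged); the
    result is the mean over the valid folds.
    """
    if ds.n_samples < 3:
        raise ValueError("need at least 3 samples for leave-one-out folds")
    X = ds.values if genes is None else ds.values[:, np.asarray(genes, dtype=int)]
    return _loo(X, ds.labels, C)


def margin_curve(
    ds: ExpressionDataset,
    f_max: int = 100,
    C: float = DEFAULT_C,
) -> MarginCurve:
    """Error margin curve ``W(i) = LOOErM(ds, genes 1..i)`` for ``i <= f_max``.

    ``ds`` must already be in relevance order (most relevant gene first);
    see :func:`ema.ranking.reorder`.
    """
    if not 1 <= f_max <= ds.n_genes:
        raise ValueError(f"f_max must be in [1, {ds.n_genes}], got {f_max}")
    X = ds.values
    y = ds.labels
    W = np.empty(f_max)
    for i in range(1, f_max + 1):
        W[i - 1] = _loo(X[:, :i], y, C)
    return MarginCurve(
        values=W,
        meta={"C": C, "f_max": f_max, "dataset": ds.content_hash()},
    )
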