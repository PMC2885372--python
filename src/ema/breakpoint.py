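"""Continuity-constrained two-segment polynomial fit and critical-point search.

The error margin curve is modelled as two polynomial segments of order
``gamma`` that meet at a candidate breakpoint ``c``:

    G(i | alpha_R) = A_1 i + ... + A_gamma i^gamma + B      for i <= c
    G(i | alpha_I) = C_1 i + ... + C_gamma i^gamma + D      for i > c

subject to the continuity constraint G(c | alpha_R) = G(c | alpha_I).  The
constraint is substituted into the objective (eliminating D), which leaves
an ordinary linear least-squares problem in (A, B, C); D is recovered from
the constraint afterwards.  The estimated number of feature genes is the
candidate breakpoint minimising the residual sum of squares, ties broken by
the smallest candidate (parsimony).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .margin import MarginCurve

__all__ = ["SegmentedFit", "SingularFitError", "segmented_fit", "find_critical_point"]


class SingularFitError(np.linalg.LinAlgError):
    """The two-segment design matrix is rank deficient."""


@dataclass
class SegmentedFit:
    """One candidate breakpoint's constrained least-squares fit.

    ``alpha_R = (A_1..A_gamma, B)`` and ``alpha_I = (C_1..C_gamma, D)`` hold
    the ascending-power coefficients followed by the constant term;
    ``epsilon`` is the residual sum of squares over the whole curve.
    """

    c: int
    gamma: int
    alpha_R: np.ndarray
    alpha_I: np.ndarray
    epsilon: float

    def predict(self, i) -> np.ndarray:
        """Evaluate the fitted piecewise polynomial at positions ``i``."""
        i = np.asarray(i, dtype=float)
        powers = i[..., None] ** np.arange(1, self.gamma + 1)
        left = powers @ self.alpha_R[:-1] + self.alpha_R[-1]
        right = powers @ self.alpha_I[:-1] + self.alpha_I[-1]
        return np.where(i <= self.c, left, right)


def _curve_values(curve) -> np.ndarray:
    return np.asarray(getattr(curve, "values", curve), dtype=float).ravel()


def segmented_fit(curve, c: int, gamma: int = 2) -> SegmentedFit:
    """Constrained least-squares fit of two polynomial segments meeting at ``c``.

    Minimises ``sum_{i<=c} (W(i) - G(i|alpha_R))^2 +
    sum_{i>c} (W(i) - G(i|alpha_I))^2`` subject to continuity at ``c``.
    Both segments must be identifiable: ``gamma + 1 <= c <= f_max - gamma``.
    """
    W = _curve_values(curve)
    f_max = W.size
    if gamma < 1:
        raise ValueError("polynomial order gamma must be >= 1")
    if not gamma + 1 <= c <= f_max - gamma:
        raise ValueError(
            f"breakpoint c={c} outside identifiable range "
            f"[{gamma + 1}, {f_max - gamma}] for gamma={gamma}, f_max={f_max}"
        )

    i = np.arange(1, f_max + 1, dtype=float)
    powers = i[:, None] ** np.arange(1, gamma + 1)  # (f_max, gamma)
    c_pow = float(c) ** np.arange(1, gamma + 1)
    left = i <= c

    # Unknowns: [A_1..A_gamma, B, C_1..C_gamma]; D eliminated via continuity.
    X = np.zeros((f_max, 2 * gamma + 1))
    X[left, :gamma] = powers[left]
    X[left, gamma] = 1.0
    X[~left, :gamma] = c_pow
    X[~left, gamma] = 1.0
    X[~left, gamma + 1:] = powers[~left] - c_pow

    coef, _, rank, _ = np.linalg.lstsq(X, W, rcond=None)
    if rank < X.shape[1]:
        raise SingularFitError(
            f"rank-deficient two-segment design at c={c}, gamma={gamma} "
            f"(f_max={f_max} too small or curve degenerate)"
        )
    resid = W - X @ coef
    A, B, C = coef[:gamma], coef[gamma], coef[gamma + 1:]
    D = float(A @ c_pow + B - C @ c_pow)  # continuity constraint
    return SegmentedFit(
        c=int(c),
        gamma=int(gamma),
        alpha_R=np.r_[A, B],
        alpha_I=np.r_[C, D],
        epsilon=float(resid @ resid),
    )


def find_critical_point(
    curve,
    gamma: int = 2,
    c_range=None,
) -> tuple[int, list[SegmentedFit]]:
    """Breakpoint minimising the constrained two-segment fit residual.

    Scans candidate breakpoints (default: the whole identifiable range
    ``[gamma + 1, f_max - gamma]``), fits each, and returns
    ``(f0, fits)`` where ``f0`` is the argmin of epsilon and ``fits`` is the
    full profile for reporting.  Near-equal residuals (relative difference
    below ~1e-9, or both within the numerical noise floor of the curve
    scale) count as ties, resolved toward the smallest candidate.
    Individual fit failures are skipped; if every candidate fails, the last
    error is re-raised.
    """
    W = _curve_values(curve)
    f_max = W.size
    if c_range is None:
        c_range = range(gamma + 1, f_max - gamma + 1)
    candidates = [int(c) for c in c_range]
    if not candidates:
        raise ValueError("empty candidate range")

    scale = max(1.0, float(np.abs(W).max()))
    atol = (1e-10 * scale) ** 2 * f_max  # noise floor for an exact fit
    rtol = 1e-9

    fits: list[SegmentedFit] = []
    best: SegmentedFit | None = None
    last_err: Exception | None = None
    for c in sorted(candidates):
        try:
            fit = segmented_fit(W, c, gamma)
        except (ValueError, np.linalg.LinAlgError) as err:
            last_err = err
            continue
        fits.append(fit)
        if best is None or fit.epsilon < best.epsilon - (rtol * best.epsilon + atol):
            best = fit
    if best is None:
        raise SingularFitError(
            f"no candidate breakpoint admitted a fit (last error: {last_err})"
        )
    return best.c, fits
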