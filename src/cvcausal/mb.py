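"""Linear model-based (MB) complexity and causality.

The effect series is described by a multivariate linear regression on the
lagged components of every series in the universe (no intercept — the
universe is zero-mean).  Coefficients minimize the in-sample mean square
prediction error λ²; since the universe has unit variance, λ² at the
Akaike-optimal order is directly a normalized complexity index in [0, 1].
Causality from a source is the fractional decrement of the NCI when the
source is included, computed by re-fitting in the reduced universe at the
order optimized in the full universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .embedding import EmbeddingMatrix, EmbeddingSpec, drop_source, full_embedding
from .exceptions import DegenerateInputError, FitError, InsufficientDataError
from .results import CausalityResult, ComplexityResult
from .series import Universe

_LAMBDA_FLOOR = 1e-12
_COND_LIMIT = 1e8


@dataclass(frozen=True)
class MvarFit:
    """Least-squares fit of the effect on the complete candidate grid."""

    coefficients: np.ndarray
    residual_variance: float
    order: int
    condition_number: float


def _ols(matrix: EmbeddingMatrix) -> tuple[np.ndarray, float, float]:
    X, y = matrix.X, matrix.target
    if X.shape[1] == 0:
        return np.empty(0), float(np.mean(y**2)), 1.0
    if X.shape[0] <= X.shape[1]:
        raise InsufficientDataError(
            f"{X.shape[0]} rows for {X.shape[1]} coefficients: underdetermined"
        )
    cond = float(np.linalg.cond(X))
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise FitError(f"regressor matrix ill-conditioned (cond={cond:.3g})")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(np.mean(resid**2)), cond


def fit_mvar(universe: Universe, spec: EmbeddingSpec, order: int | None = None) -> MvarFit:
    """Fit the multivariate linear regression at one model order.

    ``order`` overrides ``spec.max_lag``; λ² is the mean of the squared
    in-sample one-step prediction errors over beats ``p+1 .. N``.
    """
    if order is not None:
        spec = spec.with_max_lag(order)
    matrix = full_embedding(universe, spec)
    coef, lam2, cond = _ols(matrix)
    return MvarFit(coef, lam2, spec.max_lag, cond)


def akaike_select_order(universe: Universe, spec: EmbeddingSpec,
                        orders: Iterable[int] = range(1, 9)) -> tuple[int, list[float]]:
    """Pick the model order minimizing the Akaike figure of merit.

    AIC(p) = (N - p) * ln(λ²(p)) + 2 * q(p) with q(p) the number of
    estimated coefficients; λ² is floored at 1e-12 so noiseless inputs
    (λ² = 0) win immediately rather than producing -inf.
    """
    orders = list(orders)
    if not orders:
        raise DegenerateInputError("empty order range")
    profile = []
    for p in orders:
        fit = fit_mvar(universe, spec, order=p)
        n_eff = universe.n_beats - p
        q = fit.coefficients.size
        profile.append(n_eff * np.log(max(fit.residual_variance, _LAMBDA_FLOOR)) + 2 * q)
        if fit.residual_variance <= _LAMBDA_FLOOR:
            # perfectly predictable: this order wins immediately (higher
            # orders would only be rank-deficient re-fits of an exact law)
            return p, profile
    best = orders[int(np.argmin(profile))]
    return best, profile


def nci_mb(universe: Universe, spec: EmbeddingSpec,
           orders: Iterable[int] = range(1, 9)) -> ComplexityResult:
    """Normalized MB complexity: λ² at the Akaike-optimal order.

    0 means the effect is fully predictable in the universe, 1 fully
    unpredictable.
    """
    p_opt, profile = akaike_select_order(universe, spec, orders)
    fit = fit_mvar(universe, spec, order=p_opt)
    nci = float(np.clip(fit.residual_variance, 0.0, 1.0))
    label = universe.labels[spec.effect]
    return ComplexityResult("MB", spec.effect, nci, p_opt, tuple(profile), label=label)


def cr_mb(universe: Universe, spec: EmbeddingSpec, cause: int,
          orders: Iterable[int] = range(1, 9),
          normalization: str = "fractional") -> CausalityResult:
    """MB causality ratio from ``cause`` to the spec's effect.

    Both the full and reduced fits use the order optimized in the full
    universe; because the full design nests the reduced one over the same
    rows, the in-sample ratio is never positive.  ``normalization``
    selects the fractional form (default) or the absolute NCI difference.
    """
    if cause == spec.effect:
        raise DegenerateInputError("cause must differ from effect")
    p_opt, _ = akaike_select_order(universe, spec, orders)
    matrix = full_embedding(universe, spec.with_max_lag(p_opt))
    _, lam2_full, _ = _ols(matrix)
    _, lam2_red, _ = _ols(drop_source(matrix, cause))
    nci_full = float(np.clip(lam2_full, 0.0, 1.0))
    nci_red = float(np.clip(lam2_red, 0.0, 1.0))
    cr = _causality_ratio(nci_full, nci_red, normalization)
    return CausalityResult("MB", spec.effect, cause, cr, nci_full, nci_red,
                           effect_label=universe.labels[spec.effect],
                           cause_label=universe.labels[cause])


def _causality_ratio(nci_full: float, nci_reduced: float, normalization: str) -> float:
    if normalization == "absolute":
        return nci_full - nci_reduced
    if normalization != "fractional":
        raise DegenerateInputError(f"unknown normalization {normalization!r}")
    if nci_reduced == 0.0:
        raise DegenerateInputError("reduced-universe NCI is zero")
    return (nci_full - nci_reduced) / nci_reduced
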