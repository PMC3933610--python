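"""Model-free complexity and causality via local predictability (LP).

Each effect sample is predicted as the inverse-distance weighted mean of
the images of its k nearest embedding vectors (zero-order predictor,
maximum norm, Theiler exclusion).  Predictive skill is the squared
Pearson correlation r² between the series and its prediction; the
embedding is grown greedily to maximize r², the normalized complexity
index is ``1 - max r²``, and causality ratios follow from re-evaluating
the optimal embedding with the cause's components removed (no
re-selection; exactly 0 when none were selected).
"""

from __future__ import annotations

import numpy as np

from ._selection import evaluate_subset, forward_select
from .embedding import EmbeddingSpec, full_embedding
from .exceptions import DegenerateInputError, InputError
from .knn import DEFAULT_K, predict_all
from .mb import _causality_ratio
from .results import CausalityResult, ComplexityResult, SelectionTrace
from .series import Universe


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation between a series and its prediction.

    A constant prediction carries no predictive information and scores 0;
    a constant observed series makes the quantity undefined.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise InputError("observed/predicted must be equal-length vectors (>= 3)")
    if np.ptp(obs) == 0.0:
        raise DegenerateInputError("observed series is constant")
    if np.ptp(pred) == 0.0:
        return 0.0
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r * r)


def _lp_score(target: np.ndarray):
    def score(nidx: np.ndarray, ndist: np.ndarray) -> float:
        return r_squared(target, predict_all(nidx, ndist, target))
    return score


def forward_select_lp(universe: Universe, spec: EmbeddingSpec,
                      k: int = DEFAULT_K, exclusion: int | None = None) -> SelectionTrace:
    """Greedy r²-maximizing construction of the embedding space.

    ``exclusion`` defaults to the maximal lag of the spec, removing
    trivially overlapping vectors from the neighbor searches.
    """
    matrix = full_embedding(universe, spec)
    T = spec.max_lag if exclusion is None else exclusion
    return forward_select(matrix, _lp_score(matrix.target),
                          maximize=True, baseline=0.0, k=k, exclusion=T)


def nci_lp(trace: SelectionTrace, effect: int = 0, label: str = "") -> ComplexityResult:
    """Normalized LP complexity: ``1 - max r²`` over the selection trace."""
    nci = float(np.clip(1.0 - trace.optimal_value, 0.0, 1.0))
    return ComplexityResult("LP", effect, nci, trace.optimal_dim,
                            tuple(trace.criterion), trace.optimal_components,
                            trace, label=label)


def cr_lp(universe: Universe, spec: EmbeddingSpec, cause: int,
          k: int = DEFAULT_K, exclusion: int | None = None,
          trace: SelectionTrace | None = None,
          normalization: str = "fractional") -> CausalityResult:
    """LP causality ratio from ``cause`` to the spec's effect.

    The reduced index re-evaluates the optimal embedding minus the
    cause's components; when the optimal embedding holds no such
    component the ratio is exactly 0 (absence of causality).  A
    pre-computed selection ``trace`` may be passed to avoid re-running
    the forward selection.
    """
    if cause == spec.effect:
        raise DegenerateInputError("cause must differ from effect")
    if trace is None:
        trace = forward_select_lp(universe, spec, k=k, exclusion=exclusion)
    T = spec.max_lag if exclusion is None else exclusion
    optimal = trace.optimal_components
    nci_full = float(np.clip(1.0 - trace.optimal_value, 0.0, 1.0))
    if not any(c.source == cause for c in optimal):
        return CausalityResult("LP", spec.effect, cause, 0.0, nci_full, nci_full,
                               effect_label=universe.labels[spec.effect],
                               cause_label=universe.labels[cause])
    matrix = full_embedding(universe, spec)
    reduced = [c for c in optimal if c.source != cause]
    r2_red = evaluate_subset(matrix, reduced, _lp_score(matrix.target),
                             k=k, exclusion=T, empty_value=0.0)
    nci_red = float(np.clip(1.0 - r2_red, 0.0, 1.0))
    cr = _causality_ratio(nci_full, nci_red, normalization)
    return CausalityResult("LP", spec.effect, cause, cr, nci_full, nci_red,
                           effect_label=universe.labels[spec.effect],
                           cause_label=universe.labels[cause])
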