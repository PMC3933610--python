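"""Model-free complexity and causality via k-NN conditional entropy (CE).

The Shannon entropy of a sample is estimated as -ln of the probability
that two of its members lie within a tolerance ε of each other; the
conditional entropy of the effect given its embedding vector averages
this per-point over the images of each vector's k nearest neighbors.
The embedding is grown greedily to minimize CE; the normalized
complexity index divides the minimum CE by the unconditional entropy, so
0 means the universe removes all information from the effect and 1 means
it removes none.  ε follows the percentile rule: 10% of the distance
between the 84th and 16th percentile of the (normalized) effect series.
"""

from __future__ import annotations

import numpy as np

from ._selection import evaluate_subset, forward_select
from .embedding import EmbeddingMatrix, EmbeddingSpec, full_embedding
from .exceptions import DegenerateInputError, InsufficientDataError
from .knn import (
    DEFAULT_K,
    conditional_entropy_from_images,
    exclusion_infmask,
    neighbor_table,
    pair_within_eps_probability,
    pairwise_maxnorm,
)
from .mb import _causality_ratio
from .results import CausalityResult, ComplexityResult, SelectionTrace
from .series import Universe


def default_tolerance(values) -> float:
    """Percentile tolerance rule: 0.1 * (P84 - P16) of the effect series."""
    v = np.asarray(values, dtype=float)
    eps = 0.1 * (np.percentile(v, 84) - np.percentile(v, 16))
    if eps <= 0.0:
        raise DegenerateInputError("percentile tolerance is zero (constant series?)")
    return float(eps)


def shannon_entropy(values, eps: float) -> float:
    """k-free Shannon entropy estimate of a sample.

    -ln of the within-ε pair probability over all unordered distinct
    pairs, floored at 1/(pair count) so an empty count stays finite.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need at least 2 values")
    n_pairs = v.size * (v.size - 1) // 2
    prob = max(pair_within_eps_probability(v, eps), 1.0 / n_pairs)
    return float(-np.log(prob))


def conditional_entropy(matrix: EmbeddingMatrix, eps: float,
                        k: int = DEFAULT_K, exclusion: int = 0) -> float:
    """CE of the matrix target given its embedding vectors.

    The empty embedding (zero columns) reduces to the unconditional
    Shannon entropy of the target by definition.
    """
    if matrix.dim == 0:
        return shannon_entropy(matrix.target, eps)
    D = pairwise_maxnorm(matrix.X)
    nidx, _ = neighbor_table(D, k, exclusion_infmask(matrix.n_rows, exclusion))
    return conditional_entropy_from_images(matrix.target[nidx], eps)


def _ce_score(target: np.ndarray, eps: float):
    def score(nidx: np.ndarray, ndist: np.ndarray) -> float:
        return conditional_entropy_from_images(target[nidx], eps)
    return score


def forward_select_ce(universe: Universe, spec: EmbeddingSpec,
                      k: int = DEFAULT_K, exclusion: int | None = None,
                      eps: float | None = None) -> SelectionTrace:
    """Greedy CE-minimizing construction of the embedding space.

    The dimension-0 trace entry is the unconditional entropy of the
    target rows; ε defaults to the percentile rule applied to the full
    normalized effect series.
    """
    matrix = full_embedding(universe, spec)
    if eps is None:
        eps = default_tolerance(universe.series[spec.effect].values)
    T = spec.max_lag if exclusion is None else exclusion
    baseline = shannon_entropy(matrix.target, eps)
    return forward_select(matrix, _ce_score(matrix.target, eps),
                          maximize=False, baseline=baseline, k=k, exclusion=T)


def nci_ce(trace: SelectionTrace, unconditional_entropy: float | None = None,
           effect: int = 0, label: str = "") -> ComplexityResult:
    """Normalized CE complexity: min CE divided by the Shannon entropy."""
    se = trace.criterion[0] if unconditional_entropy is None else unconditional_entropy
    if se <= 0.0:
        raise DegenerateInputError("unconditional Shannon entropy is zero")
    nci = float(np.clip(trace.optimal_value / se, 0.0, 1.0))
    return ComplexityResult("CE", effect, nci, trace.optimal_dim,
                            tuple(trace.criterion), trace.optimal_components,
                            trace, label=label)


def cr_ce(universe: Universe, spec: EmbeddingSpec, cause: int,
          k: int = DEFAULT_K, exclusion: int | None = None,
          eps: float | None = None, trace: SelectionTrace | None = None,
          normalization: str = "fractional") -> CausalityResult:
    """CE causality ratio from ``cause`` to the spec's effect.

    Reduced index from the optimal embedding minus the cause's
    components (no re-selection); exactly 0 when none were selected.
    """
    if cause == spec.effect:
        raise DegenerateInputError("cause must differ from effect")
    if eps is None:
        eps = default_tolerance(universe.series[spec.effect].values)
    if trace is None:
        trace = forward_select_ce(universe, spec, k=k, exclusion=exclusion, eps=eps)
    T = spec.max_lag if exclusion is None else exclusion
    se = trace.criterion[0]
    if se <= 0.0:
        raise DegenerateInputError("unconditional Shannon entropy is zero")
    optimal = trace.optimal_components
    nci_full = float(np.clip(trace.optimal_value / se, 0.0, 1.0))
    if not any(c.source == cause for c in optimal):
        return CausalityResult("CE", spec.effect, cause, 0.0, nci_full, nci_full,
                               effect_label=universe.labels[spec.effect],
                               cause_label=universe.labels[cause])
    matrix = full_embedding(universe, spec)
    reduced = [c for c in optimal if c.source != cause]
    ce_red = evaluate_subset(matrix, reduced, _ce_score(matrix.target, eps),
                             k=k, exclusion=T, empty_value=se)
    nci_red = float(np.clip(ce_red / se, 0.0, 1.0))
    cr = _causality_ratio(nci_full, nci_red, normalization)
    return CausalityResult("CE", spec.effect, cause, cr, nci_full, nci_red,
                           effect_label=universe.labels[spec.effect],
                           cause_label=universe.labels[cause])
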