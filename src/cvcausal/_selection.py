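"""Greedy forward selection over the candidate lag grid (internal).

Both model-free estimators grow the embedding one lagged component at a
time: every remaining candidate is tentatively appended, the figure of
merit (r² for local prediction, conditional entropy) is evaluated with
the k-NN engine, and the best candidate is kept.  After selecting
``(source s, lag l)`` every candidate of source ``s`` with lag <= l is
pruned, and selection continues until no candidate remains.  Ties prefer
the earlier candidate in canonical order (sources in universe order,
lags ascending), making the procedure deterministic.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .embedding import EmbeddingMatrix, LaggedComponent, candidate_grid
from .knn import exclusion_infmask, neighbor_table, pairwise_maxnorm, update_maxnorm
from .results import SelectionTrace

# score(neighbor_idx, neighbor_dist) -> float, larger-is-better handled by caller
ScoreFn = Callable[[np.ndarray, np.ndarray], float]


def forward_select(matrix: EmbeddingMatrix, score: ScoreFn, *, maximize: bool,
                   baseline: float, k: int, exclusion: int) -> SelectionTrace:
    """Run the greedy selection on a full candidate embedding matrix.

    ``baseline`` is the dimension-0 criterion value.  ``exclusion`` is the
    Theiler half-width passed to the neighbor searches.
    """
    n = matrix.n_rows
    infmask = exclusion_infmask(n, exclusion)
    remaining = list(matrix.components)
    D = pairwise_maxnorm(np.empty((n, 0)))  # all-zero: empty embedding
    selected: list[LaggedComponent] = []
    criterion = [baseline]

    while remaining:
        best_val, best_idx = None, None
        for idx, comp in enumerate(remaining):
            col = matrix.X[:, matrix.column_of(comp)]
            D_try = update_maxnorm(D, col)
            nidx, ndist = neighbor_table(D_try, k, infmask, ordered=False)
            val = score(nidx, ndist)
            better = (
                best_val is None
                or (maximize and val > best_val)
                or (not maximize and val < best_val)
            )
            if better:
                best_val, best_idx = val, idx
        comp = remaining[best_idx]
        selected.append(comp)
        criterion.append(float(best_val))
        D = update_maxnorm(D, matrix.X[:, matrix.column_of(comp)])
        remaining = [c for c in remaining
                     if not (c.source == comp.source and c.lag <= comp.lag)]

    return SelectionTrace(tuple(selected), tuple(criterion), maximize)


def evaluate_subset(matrix: EmbeddingMatrix, components, score: ScoreFn,
                    *, k: int, exclusion: int, empty_value: float) -> float:
    """Criterion value of one fixed component set (no selection)."""
    if not components:
        return empty_value
    cols = [matrix.column_of(c) for c in components]
    D = pairwise_maxnorm(matrix.X[:, cols])
    nidx, ndist = neighbor_table(D, k, exclusion_infmask(matrix.n_rows, exclusion),
                                 ordered=False)
    return float(score(nidx, ndist))
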