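"""Non-uniform multivariate embedding.

The embedding vector for effect series ``i`` at beat ``n`` stacks, for
every source ``j`` in the universe, the lagged samples
``y_j(n - tau_j), ..., y_j(n - p)`` where ``tau_j`` is the minimum delay
of influence of ``j`` on ``i`` (``tau_i >= 1`` for the effect itself,
``tau_j >= 0`` otherwise, 0 allowing instantaneous effects) and ``p`` the
maximal lag.  Rows run over ``n = p+1 .. N`` so full and reduced
embeddings always share the same target samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InsufficientDataError, SpecificationError
from .series import Universe


@dataclass(frozen=True, order=True)
class LaggedComponent:
    """One candidate coordinate: (source series index, lag in beats)."""

    source: int
    lag: int


@dataclass(frozen=True)
class EmbeddingSpec:
    """Embedding specification for one effect series.

    Parameters
    ----------
    effect : int
        Index of the effect series in the universe.
    min_delays : tuple of int
        Minimum delay of influence per source, aligned with the universe
        order.  The self delay must be >= 1 (no instantaneous
        self-influence); other delays may be 0.
    max_lag : int
        Maximal lag ``p`` (same for every source).
    """

    effect: int
    min_delays: tuple[int, ...]
    max_lag: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "min_delays", tuple(int(t) for t in self.min_delays))
        p = self.max_lag
        if p < 1:
            raise SpecificationError("max_lag must be >= 1")
        if not 0 <= self.effect < len(self.min_delays):
            raise SpecificationError("effect index outside min_delays")
        for j, tau in enumerate(self.min_delays):
            lo = 1 if j == self.effect else 0
            if not lo <= tau <= p:
                raise SpecificationError(
                    f"delay {tau} for source {j} outside [{lo}, {p}]"
                )

    @property
    def n_sources(self) -> int:
        return len(self.min_delays)

    def with_max_lag(self, p: int) -> "EmbeddingSpec":
        """Same delays, different maximal lag (delays clipped up never)."""
        return EmbeddingSpec(self.effect, self.min_delays, p)


def candidate_grid(spec: EmbeddingSpec, n_sources: int | None = None) -> list[LaggedComponent]:
    """Enumerate the candidate lagged components for one effect.

    Sources appear in universe order, lags ascending within a source;
    the count equals ``sum_j (p - tau_j + 1)`` — the dimension of the
    complete multivariate embedding vector.
    """
    if n_sources is not None and n_sources != spec.n_sources:
        raise SpecificationError(
            f"spec covers {spec.n_sources} sources, asked for {n_sources}"
        )
    return [
        LaggedComponent(j, k)
        for j in range(spec.n_sources)
        for k in range(spec.min_delays[j], spec.max_lag + 1)
    ]


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Design matrix of embedding vectors plus the aligned target.

    Row ``r`` corresponds to beat ``n = p + 1 + r`` (1-based counter);
    column ``c`` holds ``y_source(n - lag)`` for ``components[c]``.
    """

    X: np.ndarray
    target: np.ndarray
    components: tuple[LaggedComponent, ...]
    effect: int
    max_lag: int

    def __post_init__(self) -> None:
        if self.X.shape != (self.target.size, len(self.components)):
            raise SpecificationError("embedding matrix shape mismatch")

    @property
    def n_rows(self) -> int:
        return self.target.size

    @property
    def dim(self) -> int:
        return len(self.components)

    def column_of(self, component: LaggedComponent) -> int:
        try:
            return self.components.index(component)
        except ValueError:
            raise SpecificationError(f"{component} not in embedding") from None


def full_embedding(universe: Universe, spec: EmbeddingSpec) -> EmbeddingMatrix:
    """Build the complete embedding matrix over the candidate grid."""
    if universe.n_series != spec.n_sources:
        raise SpecificationError(
            f"universe has {universe.n_series} series, spec expects {spec.n_sources}"
        )
    n, p = universe.n_beats, spec.max_lag
    if n <= p:
        raise InsufficientDataError(f"need more than max_lag={p} beats, got {n}")
    data = universe.matrix()
    comps = tuple(candidate_grid(spec))
    rows = n - p
    X = np.empty((rows, len(comps)))
    for c, comp in enumerate(comps):
        # row r is beat index p + r (0-based), column holds y[p + r - lag]
        X[:, c] = data[p - comp.lag: n - comp.lag, comp.source]
    target = data[p:, spec.effect]
    return EmbeddingMatrix(X, target, comps, spec.effect, p)


def subset_embedding(matrix: EmbeddingMatrix,
                     components: Sequence[LaggedComponent]) -> EmbeddingMatrix:
    """Column subset in the requested order; rows and target unchanged."""
    cols = [matrix.column_of(c) for c in components]
    X = matrix.X[:, cols] if cols else np.empty((matrix.n_rows, 0))
    return EmbeddingMatrix(X, matrix.target, tuple(components),
                           matrix.effect, matrix.max_lag)


def drop_source(matrix: EmbeddingMatrix, source: int) -> EmbeddingMatrix:
    """Reduced-universe embedding: remove every component of one source."""
    keep = [c for c in matrix.components if c.source != source]
    return subset_embedding(matrix, keep)
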