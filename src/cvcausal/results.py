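"""Result containers shared by the three estimators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .embedding import LaggedComponent


@dataclass(frozen=True)
class SelectionTrace:
    """Record of a greedy forward selection of lagged components.

    ``criterion[d]`` is the figure of merit of the embedding formed by the
    first ``d`` selected components; index 0 is the empty-embedding
    baseline (r^2 = 0 for local prediction, the unconditional Shannon
    entropy for conditional entropy).
    """

    components: tuple[LaggedComponent, ...]
    criterion: tuple[float, ...]
    maximize: bool

    def __post_init__(self) -> None:
        if len(self.criterion) != len(self.components) + 1:
            raise ValueError("criterion must have one entry per dimension incl. 0")

    @property
    def optimal_dim(self) -> int:
        """Dimension at the best criterion value (first optimum on ties)."""
        vals = np.asarray(self.criterion)
        return int(np.argmax(vals) if self.maximize else np.argmin(vals))

    @property
    def optimal_value(self) -> float:
        return float(self.criterion[self.optimal_dim])

    @property
    def optimal_components(self) -> tuple[LaggedComponent, ...]:
        return self.components[: self.optimal_dim]

    def to_dict(self) -> dict:
        return {
            "components": [(c.source, c.lag) for c in self.components],
            "criterion": list(self.criterion),
            "maximize": self.maximize,
            "optimal_dim": self.optimal_dim,
        }


@dataclass(frozen=True)
class ComplexityResult:
    """Normalized complexity index of one effect series.

    ``nci`` lies in [0, 1]: 0 means fully predictable (null complexity),
    1 fully unpredictable (maximal complexity).  ``optimal`` is the model
    order (MB) or embedding dimension (LP/CE) at which the index was
    taken, and ``profile`` the figure of merit across the searched
    orders/dimensions.
    """

    method: str
    effect: int
    nci: float
    optimal: int
    profile: tuple[float, ...] = ()
    selected: tuple[LaggedComponent, ...] = ()
    trace: SelectionTrace | None = None
    label: str = ""

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "effect": self.label or self.effect,
            "nci": self.nci,
            "optimal": self.optimal,
            "profile": list(self.profile),
        }
        if self.selected:
            out["selected"] = [(c.source, c.lag) for c in self.selected]
        return out


@dataclass(frozen=True)
class CausalityResult:
    """Causality ratio for one directed pair under one method.

    ``cr`` is the fractional change of the effect's NCI due to the
    inclusion of the cause in the reduced universe; ``cr < 0`` indicates
    Granger causality (MB, LP) or information transfer (CE).
    """

    method: str
    effect: int
    cause: int
    cr: float
    nci_full: float
    nci_reduced: float
    effect_label: str = ""
    cause_label: str = ""

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "effect": self.effect_label or self.effect,
            "cause": self.cause_label or self.cause,
            "cr": self.cr,
            "nci_full": self.nci_full,
            "nci_reduced": self.nci_reduced,
        }
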