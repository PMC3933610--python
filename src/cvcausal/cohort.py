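"""Cohort association stage: index-on-age correlation with a normality gate.

Mirrors the classical workflow of clinical autonomic studies: each index
is first screened with a Kolmogorov-Smirnov-family normality test; if
normality is not rejected the Pearson product-moment correlation with the
covariate is used, otherwise the Spearman rank correlation.  Two-sided
p-values, significance at alpha = 0.05.  The KS variant is the
Lilliefors correction (mean and variance estimated from the sample), the
appropriate null when no reference Gaussian is specified a priori.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .exceptions import DegenerateInputError, InputError

ALPHA = 0.05
MIN_SUBJECTS = 8


@dataclass(frozen=True)
class AssociationResult:
    """Correlation of one index with the covariate across subjects."""

    index_name: str
    n: int
    method: str  # "pearson" | "spearman"
    r: float
    p_value: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "index": self.index_name,
            "n": self.n,
            "method": self.method,
            "r": self.r,
            "p": self.p_value,
            "significant": self.significant,
        }


def normality_gate(values, alpha: float = ALPHA) -> bool:
    """True when the Lilliefors test fails to reject normality."""
    v = np.asarray(values, dtype=float)
    if v.size < MIN_SUBJECTS:
        raise InputError(f"need >= {MIN_SUBJECTS} values, got {v.size}")
    if np.ptp(v) == 0.0:
        return False  # degenerate: a point mass is not Gaussian
    _, p = lilliefors(v, dist="norm")
    return bool(p > alpha)


def associate(values, covariate, index_name: str = "",
              alpha: float = ALPHA) -> AssociationResult:
    """Normality-gated correlation of an index with a covariate.

    Pearson when the gate passes, Spearman otherwise; ``significant``
    flags two-sided p < alpha.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if v.shape != c.shape:
        raise InputError("values and covariate must be paired")
    if v.size < MIN_SUBJECTS:
        raise InputError(f"need >= {MIN_SUBJECTS} pairs, got {v.size}")
    if np.ptp(c) == 0.0 or np.ptp(v) == 0.0:
        raise DegenerateInputError("constant values or covariate")
    if normality_gate(v, alpha=alpha):
        method = "pearson"
        r, p = stats.pearsonr(v, c)
    else:
        method = "spearman"
        r, p = stats.spearmanr(v, c)
    return AssociationResult(index_name, v.size, method, float(r), float(p),
                             bool(p < alpha))
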