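"""Directed coupling detection: model-free vs model-based.

Simulates y(n) = 0.8*(x(n-1)^2 - 1) + w(n) with white-noise x — a purely
quadratic coupling, invisible to linear regression — and compares the
causality ratio CR from both routes.  CR < 0 flags a causal link; the
more negative, the stronger.
"""

import numpy as np

import cvcausal as cv
from cvcausal import BeatSeries, EmbeddingSpec, Universe, cr_lp, cr_mb, normalize

data, truth = cv.simulate_coupled(cv.unidirectional_quadratic(0.8, 1024), seed=5)
u = Universe(
    tuple(normalize(BeatSeries(data[:, i], label=l)) for i, l in enumerate(("x", "y"))),
    normalized=True,
)

spec_y = EmbeddingSpec(effect=1, min_delays=(1, 1), max_lag=8)
spec_x = EmbeddingSpec(effect=0, min_delays=(1, 1), max_lag=8)

print("planted truth: x -> y only")
print(f"CR_x->y  LP {cr_lp(u, spec_y, cause=0).cr:+.3f}   MB {cr_mb(u, spec_y, cause=0).cr:+.3f}")
print(f"CR_y->x  LP {cr_lp(u, spec_x, cause=1).cr:+.3f}   MB {cr_mb(u, spec_x, cause=1).cr:+.3f}")
print()
print("Local prediction sees the quadratic link (strongly negative CR);")
print("the linear model cannot (CR near 0), and neither route flags the")
print("absent reverse direction.")
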