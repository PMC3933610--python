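"""Synthetic beat-to-beat data with known ground truth.

Three generators stand in for the study recordings:

* coupled stochastic series (``simulate_coupled`` / ``gen_trivariate``)
  with controllable directed couplings, coupling delays, per-link
  linear/quadratic nonlinearity and Gaussian innovation noise — the
  benchmark for every complexity/causality estimator;
* a constructed HP/SAP pair with a planted number of SAP ramps, a known
  fraction of which evoke baroreflex sequences of known slope
  (``gen_baroreflex_toy``);
* a cohort table of ages and index values around a planted linear trend
  (``gen_cohort``).

Defaults target the study conditions: windows of 256 beats, trivariate
HP/SAP/RESP-like systems, unit-variance Gaussian innovations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import SpecificationError
from .series import BeatSeries

_BURN_IN = 200


@dataclass(frozen=True)
class Coupling:
    """One directed link: ``gain * y_source(n - lag)`` (or its centered
    square when ``nonlinear``) entering the target's equation."""

    source: int
    target: int
    lag: int
    gain: float
    nonlinear: bool = False


@dataclass(frozen=True)
class CouplingSpec:
    """Specification of a coupled stochastic system.

    ``self_coeffs[i][k-1]`` is the AR coefficient of series i at lag k;
    ``noise_sd[i]`` the innovation SD.  The linear part (self terms plus
    linear couplings) must be stable — spectral radius of the companion
    matrix below 1 — and instantaneous (lag-0) links must form an
    acyclic graph.  Quadratic links are excluded from the linear
    stability check.
    """

    n: int = 256
    self_coeffs: tuple[tuple[float, ...], ...] = ((0.8,), (0.8,), (0.8,))
    couplings: tuple[Coupling, ...] = ()
    noise_sd: tuple[float, ...] = (1.0, 1.0, 1.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "self_coeffs",
                           tuple(tuple(float(c) for c in row) for row in self.self_coeffs))
        object.__setattr__(self, "couplings", tuple(self.couplings))
        object.__setattr__(self, "noise_sd", tuple(float(s) for s in self.noise_sd))
        if self.n < 64:
            raise SpecificationError("series length must be >= 64")
        if len(self.noise_sd) != self.n_series:
            raise SpecificationError("noise_sd length must match series count")
        for c in self.couplings:
            if not (0 <= c.source < self.n_series and 0 <= c.target < self.n_series):
                raise SpecificationError(f"coupling {c} references unknown series")
            if c.lag < 0 or (c.lag == 0 and c.source == c.target):
                raise SpecificationError(f"invalid lag in coupling {c}")

    @property
    def n_series(self) -> int:
        return len(self.self_coeffs)

    @property
    def max_lag(self) -> int:
        lags = [len(row) for row in self.self_coeffs]
        lags += [c.lag for c in self.couplings]
        return max(lags) if lags else 1

    def truth_matrix(self) -> np.ndarray:
        """Boolean (source, target) matrix of planted directed links."""
        truth = np.zeros((self.n_series, self.n_series), dtype=bool)
        for c in self.couplings:
            if c.gain != 0.0:
                truth[c.source, c.target] = True
        return truth


def _instantaneous_order(spec: CouplingSpec) -> list[int]:
    """Topological order of series w.r.t. lag-0 links (Kahn's algorithm)."""
    m = spec.n_series
    deps = {i: set() for i in range(m)}
    for c in spec.couplings:
        if c.lag == 0 and c.gain != 0.0:
            deps[c.target].add(c.source)
    order, ready = [], [i for i in range(m) if not deps[i]]
    while ready:
        i = ready.pop(0)
        order.append(i)
        for j in range(m):
            if i in deps[j]:
                deps[j].discard(i)
                if not deps[j] and j not in order and j not in ready:
                    ready.append(j)
    if len(order) != m:
        raise SpecificationError("instantaneous couplings form a cycle")
    return order


def spectral_radius(spec: CouplingSpec) -> float:
    """Spectral radius of the companion matrix of the linear part.

    Instantaneous linear links are folded in via the structural form
    ``y(n) = B0 y(n) + sum_k A_k y(n-k) + w``, i.e. the reduced-form lag
    matrices are ``(I - B0)^-1 A_k``.
    """
    m, p = spec.n_series, spec.max_lag
    if p == 0:
        return 0.0  # purely instantaneous/noise system: no lagged dynamics
    A = np.zeros((p, m, m))
    B0 = np.zeros((m, m))
    for i, row in enumerate(spec.self_coeffs):
        for k, coef in enumerate(row, start=1):
            A[k - 1, i, i] += coef
    for c in spec.couplings:
        if c.nonlinear:
            continue
        if c.lag == 0:
            B0[c.target, c.source] += c.gain
        else:
            A[c.lag - 1, c.target, c.source] += c.gain
    inv = np.linalg.inv(np.eye(m) - B0)
    comp = np.zeros((m * p, m * p))
    for k in range(p):
        comp[:m, k * m:(k + 1) * m] = inv @ A[k]
    if p > 1:
        comp[m:, :-m] = np.eye(m * (p - 1))
    return float(np.abs(np.linalg.eigvals(comp)).max())


def simulate_coupled(spec: CouplingSpec,
                     seed: int | np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the coupled system; returns ``(data (n, M), truth (M, M))``.

    A 200-beat burn-in is discarded.  Reproducible under a fixed seed
    (``seed`` overrides ``spec.seed``).
    """
    radius = spectral_radius(spec)
    if radius >= 1.0:
        raise SpecificationError(f"unstable linear part (spectral radius {radius:.3f})")
    if seed is None:
        seed = spec.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m, p = spec.n_series, spec.max_lag
    total = spec.n + _BURN_IN + p
    noise = rng.normal(size=(total, m)) * np.asarray(spec.noise_sd)
    y = np.zeros((total, m))
    order = _instantaneous_order(spec)
    by_target: dict[int, list[Coupling]] = {i: [] for i in range(m)}
    for c in spec.couplings:
        if c.gain != 0.0:
            by_target[c.target].append(c)
    for n in range(p, total):
        for i in order:
            val = noise[n, i]
            for k, coef in enumerate(spec.self_coeffs[i], start=1):
                val += coef * y[n - k, i]
            for c in by_target[i]:
                x = y[n - c.lag, c.source]
                val += c.gain * ((x * x - 1.0) if c.nonlinear else x)
            y[n, i] = val
    return y[p + _BURN_IN:], spec.truth_matrix()


_TRIVARIATE_LABELS = ("HP", "SAP", "RESP")
_TRIVARIATE_UNITS = ("ms", "mmHg", "a.u.")
_TRIVARIATE_OFFSET = (850.0, 120.0, 0.0)
_TRIVARIATE_SCALE = (25.0, 4.0, 1.0)


def gen_trivariate(spec: CouplingSpec | None = None,
                   seed: int | np.random.Generator | None = None,
                   physiological: bool = True) -> tuple[list[BeatSeries], np.ndarray]:
    """Trivariate HP/SAP/RESP-like system with known causal structure.

    ``physiological=True`` rescales the standardized dynamics onto
    plausible raw units (HP around 850 ms, SAP around 120 mmHg) so the
    output can also feed the baroreflex stage; the complexity pipeline
    normalizes regardless.
    """
    if spec is None:
        spec = cardio_like()
    if spec.n_series != 3:
        raise SpecificationError("gen_trivariate needs a 3-series spec")
    data, truth = simulate_coupled(spec, seed=seed)
    series = []
    for i in range(3):
        col = data[:, i]
        if physiological:
            sd = col.std()
            z = (col - col.mean()) / sd if sd > 0 else col - col.mean()
            col = _TRIVARIATE_OFFSET[i] + _TRIVARIATE_SCALE[i] * z
        series.append(BeatSeries(col, unit=_TRIVARIATE_UNITS[i],
                                 label=_TRIVARIATE_LABELS[i]))
    return series, truth


def cardio_like(n: int = 256, seed: int | None = None) -> CouplingSpec:
    """Default trivariate spec emulating the cardiovascular loop.

    Baroreflex arm SAP -> HP within the beat, respiratory sinus
    arrhythmia RESP -> HP within the beat, mechanical feed-forward
    HP -> SAP at one beat, respiration-to-pressure RESP -> SAP within
    the beat, and an oscillatory AR(2) respiration (period about 4-5
    beats).
    """
    return CouplingSpec(
        n=n,
        self_coeffs=((0.6,), (0.6,), (0.3, -0.81)),
        couplings=(
            Coupling(1, 0, 0, 0.5),   # SAP -> HP (baroreflex, instantaneous)
            Coupling(2, 0, 0, 0.4),   # RESP -> HP (RSA)
            Coupling(0, 1, 1, -0.3),  # HP -> SAP (mechanical, one beat)
            Coupling(2, 1, 0, 0.3),   # RESP -> SAP (intrathoracic pressure)
        ),
        noise_sd=(1.0, 1.0, 1.0),
        seed=seed,
    )


def unidirectional_linear(gain: float = 0.8, n: int = 4096,
                          seed: int | None = None) -> CouplingSpec:
    """White-noise driver x, effect y = gain * x(n-1) + w (two series)."""
    return CouplingSpec(
        n=n,
        self_coeffs=((), ()),
        couplings=(Coupling(0, 1, 1, gain),),
        noise_sd=(1.0, 1.0),
        seed=seed,
    )


def unidirectional_quadratic(gain: float = 0.8, n: int = 1024,
                             seed: int | None = None) -> CouplingSpec:
    """White-noise driver x, effect y = gain * (x(n-1)^2 - 1) + w.

    The coupling is invisible to linear regression (zero correlation
    with any lag of x) but recoverable by local prediction.
    """
    return CouplingSpec(
        n=n,
        self_coeffs=((), ()),
        couplings=(Coupling(0, 1, 1, gain, nonlinear=True),),
        noise_sd=(1.0, 1.0),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# baroreflex toy


def gen_baroreflex_toy(n_ramps: int, fraction_effective: float,
                       slopes: float | Sequence[float] = 8.0,
                       seed: int | None = None) -> tuple[BeatSeries, BeatSeries, dict]:
    """HP/SAP pair with a planted ramp/sequence structure.

    ``n_ramps`` SAP ramps are embedded in criterion-free filler beats
    (alternating small steps, so no spurious three-step monotone run);
    the first ``round(fraction_effective * n_ramps)`` ramps carry a
    concordant HP limb of exactly the requested slope, the rest a
    non-monotone HP limb.  Ground truth (counts, BRS, BEI) is returned
    alongside.
    """
    if n_ramps < 1:
        raise SpecificationError("need at least one ramp")
    if not 0.0 <= fraction_effective <= 1.0:
        raise SpecificationError("fraction_effective must lie in [0, 1]")
    n_eff = round(fraction_effective * n_ramps)
    if np.isscalar(slopes):
        slope_list = [float(slopes)] * n_eff
    else:
        slope_list = [float(s) for s in slopes]
        if len(slope_list) != n_eff:
            raise SpecificationError(
                f"{len(slope_list)} slopes for {n_eff} effective ramps"
            )
    if any(s <= 0 for s in slope_list):
        raise SpecificationError("slopes must be positive")

    rng = np.random.default_rng(seed)
    sap_base, hp_base = 120.0, 850.0
    sap: list[float] = []
    hp: list[float] = []

    def filler(n_beats: int = 6) -> None:
        # strict sign alternation starting downward: a filler segment can
        # never contribute three same-sign changes, and it ends on the
        # high side so the next ramp start (low side) breaks any run
        for b in range(n_beats):
            sgn = -1 if b % 2 == 0 else 1
            sap.append(sap_base + 0.3 * sgn)
            hp.append(hp_base + 2.0 * sgn)

    filler()
    for r in range(n_ramps):
        steps = np.array([1.0, 1.1, 1.2]) * (1.0 + 0.05 * rng.uniform(-1, 1, 3))
        sap_start = sap_base - 0.3  # below the filler high, so entry diff < 0
        sap_run = sap_start + np.concatenate([[0.0], np.cumsum(steps)])
        if r < n_eff:
            # HP exactly linear in SAP: sequence slope is exact
            hp_run = hp_base + slope_list[r] * (sap_run - sap_start)
        else:
            hp_run = hp_base + np.array([0.0, -2.0, 1.0, -1.5])  # non-monotone
        sap.extend(sap_run)
        hp.extend(hp_run)
        # the following filler starts low: one large negative step back,
        # then alternation — never a second consecutive same-sign change
        filler()

    hp_series = BeatSeries(np.array(hp), unit="ms", label="HP")
    sap_series = BeatSeries(np.array(sap), unit="mmHg", label="SAP")
    truth = {
        "n_ramps": n_ramps,
        "n_sequences": n_eff,
        "brs": float(np.mean(slope_list)) if n_eff else float("nan"),
        "bei": n_eff / n_ramps,
    }
    return hp_series, sap_series, truth


def gen_cohort(n_subjects: int = 100, slope: float = 0.0, noise_sd: float = 1.0,
               seed: int | None = None, index_name: str = "index") -> pd.DataFrame:
    """Cohort table: ages uniform on [21, 70], index = slope*age + noise."""
    if n_subjects < 10:
        raise SpecificationError("need at least 10 subjects")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(21.0, 70.0, n_subjects)
    values = slope * ages + rng.normal(scale=noise_sd, size=n_subjects)
    return pd.DataFrame({
        "subject": [f"S{i:03d}" for i in range(n_subjects)],
        "age": ages,
        "index_name": index_name,
        "value": values,
    })
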