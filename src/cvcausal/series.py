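"""Beat-to-beat series I/O and preprocessing.

Series are stored 0-based internally; the beat counter ``n = 1..N`` of the
physiological convention is used in log messages and reported window
starts.  A processing window is detrended first and then normalized to
zero mean and unit variance (population convention), producing the
universe of knowledge used by every estimator.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    InputError,
    InsufficientDataError,
)

logger = logging.getLogger(__name__)

#: units conventionally attached to the cardiovascular labels
CANONICAL_UNITS = {"HP": "ms", "SAP": "mmHg", "RESP": "a.u."}

_NORM_TOL = 1e-10


@dataclass(frozen=True)
class BeatSeries:
    """A scalar series indexed by the cardiac beat counter.

    Parameters
    ----------
    values : array-like
        One value per beat; must be finite.
    unit : str
        Physical unit, e.g. ``"ms"``, ``"mmHg"`` or ``"a.u."``.
    label : str
        Identifier such as ``"HP"``, ``"SAP"`` or ``"RESP"``.
    """

    values: np.ndarray
    unit: str = "a.u."
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise InputError(f"series {self.label!r} must be 1-D")
        if vals.size < 2:
            raise InputError(f"series {self.label!r} needs at least 2 beats")
        if not np.all(np.isfinite(vals)):
            raise InputError(f"series {self.label!r} contains non-finite values")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class Universe:
    """Ordered collection of equal-length series — the universe Ω.

    The complexity/causality estimators require a normalized universe
    (every member with zero mean and unit population variance).
    """

    series: tuple[BeatSeries, ...]
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        series = tuple(self.series)
        if not series:
            raise InputError("universe needs at least one series")
        lengths = {len(s) for s in series}
        if len(lengths) != 1:
            raise InputError(f"series lengths differ: {sorted(lengths)}")
        if self.normalized:
            for s in series:
                if abs(s.values.mean()) > _NORM_TOL or abs(s.values.var() - 1.0) > _NORM_TOL:
                    raise InputError(
                        f"universe flagged normalized but {s.label!r} is not"
                    )
        object.__setattr__(self, "series", series)

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def n_beats(self) -> int:
        return len(self.series[0])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.series)

    def matrix(self) -> np.ndarray:
        """Return the (N, M) data matrix, one column per series."""
        return np.column_stack([s.values for s in self.series])

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ConfigurationError(f"no series labeled {label!r}") from None


def read_beat_table(path, columns: Mapping[str, str | int] | None = None,
                    sep: str | None = None) -> list[BeatSeries]:
    """Read a delimited beat table (one row per beat, header line).

    Parameters
    ----------
    path : path-like
        CSV/TSV file with a header row.
    columns : mapping label -> column name or 0-based position, optional
        Which columns to load.  Default: every column, labels from the
        header.
    sep : str, optional
        Field separator; sniffed when omitted.

    Returns
    -------
    list of BeatSeries, all the same length.
    """
    try:
        frame = pd.read_csv(path, sep=sep, engine="python")
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty file") from None
    if frame.shape[0] == 0:
        raise InputError(f"{path}: header only, no data rows")

    if columns is None:
        columns = {str(c): str(c) for c in frame.columns}

    out: list[BeatSeries] = []
    for label, col in columns.items():
        if isinstance(col, int):
            if not 0 <= col < frame.shape[1]:
                raise ConfigurationError(f"{path}: no column index {col}")
            raw = frame.iloc[:, col]
        else:
            if col not in frame.columns:
                raise ConfigurationError(f"{path}: missing column {col!r}")
            raw = frame[col]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = np.nonzero(~np.isfinite(vals.to_numpy(dtype=float)))[0]
        if bad.size:
            # 1-based data-row numbering in the message
            raise InputError(
                f"{path}: non-numeric value in column {col!r} at data row {bad[0] + 1}"
            )
        out.append(BeatSeries(vals.to_numpy(dtype=float), unit=CANONICAL_UNITS.get(label, "a.u."), label=label))
    return out


def write_beat_table(path, series: Sequence[BeatSeries], sep: str = "\t") -> None:
    """Write series as a delimited table with one row per beat."""
    frame = pd.DataFrame({s.label or f"col{i}": s.values for i, s in enumerate(series)})
    frame.to_csv(path, sep=sep, index=False)


def normalize(series: BeatSeries) -> BeatSeries:
    """Scale a series to zero mean and unit population variance.

    Raises
    ------
    DegenerateInputError
        If the series is constant (zero variance).
    """
    vals = series.values
    sd = vals.std()  # population (ddof=0)
    if sd == 0.0:
        raise DegenerateInputError(f"series {series.label!r} is constant")
    return replace(series, values=(vals - vals.mean()) / sd, unit="a.u.")


def linear_detrend(series: BeatSeries) -> BeatSeries:
    """Remove the least-squares line over the beat counter."""
    n = np.arange(len(series), dtype=float)
    coeffs = np.polyfit(n, series.values, 1)
    return replace(series, values=series.values - np.polyval(coeffs, n))


def _stationarity_score(window: np.ndarray) -> float:
    """Heuristic nonstationarity score of a detrended multichannel window.

    The window is split in halves; per channel the score is the larger of
    |mean difference| / (0.5 * pooled SD) and (variance ratio) / 2, and the
    window score is the maximum over channels.  Scores <= 1 are admissible
    (no slow mean drift, no sudden variance change).
    """
    half = window.shape[0] // 2
    a, b = window[:half], window[half: 2 * half]
    score = 0.0
    for j in range(window.shape[1]):
        va, vb = a[:, j].var(), b[:, j].var()
        pooled = np.sqrt(0.5 * (va + vb))
        if pooled == 0.0:
            mean_part = 0.0 if a[:, j].mean() == b[:, j].mean() else np.inf
        else:
            mean_part = abs(a[:, j].mean() - b[:, j].mean()) / (0.5 * pooled)
        lo, hi = sorted((va, vb))
        var_part = np.inf if lo == 0.0 else (hi / lo) / 2.0
        score = max(score, mean_part, var_part)
    return float(score)


def select_window(series: Sequence[BeatSeries], length: int = 256,
                  seed: int | np.random.Generator | None = None,
                  max_tries: int = 100) -> int:
    """Pick a random start index for an analysis window of ``length`` beats.

    Candidate windows are linearly detrended and screened by a
    stationarity heuristic (split-half mean drift and variance-ratio
    checks); a failing window is re-drawn, up to ``max_tries``, after
    which the best-scoring candidate is returned with a warning.

    Returns the 0-based start index (logged 1-based).
    """
    n_beats = len(series[0])
    if any(len(s) != n_beats for s in series):
        raise InputError("series lengths differ")
    if n_beats < length:
        raise InsufficientDataError(f"need >= {length} beats, got {n_beats}")
    if n_beats == length:
        return 0

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    data = np.column_stack([s.values for s in series])
    best_start, best_score = 0, np.inf
    for _ in range(max_tries):
        start = int(rng.integers(0, n_beats - length + 1))
        window = data[start: start + length]
        detrended = np.column_stack(
            [linear_detrend(BeatSeries(window[:, j], label=str(j))).values
             for j in range(window.shape[1])]
        )
        score = _stationarity_score(detrended)
        if score <= 1.0:
            logger.debug("window start %d (1-based) accepted, score %.3f", start + 1, score)
            return start
        if score < best_score:
            best_start, best_score = start, score
    warnings.warn(
        f"no window passed the stationarity heuristic in {max_tries} tries; "
        f"returning best candidate (start {best_start + 1}, score {best_score:.2f})",
        stacklevel=2,
    )
    return best_start


def prepare_universe(series: Sequence[BeatSeries], length: int | None = 256,
                     seed: int | np.random.Generator | None = None,
                     max_tries: int = 100) -> tuple[Universe, dict]:
    """Window, detrend and normalize series into an analysis-ready universe.

    ``length=None`` uses the full series (no random selection).  Returns
    the normalized universe and a metadata dict (window start, length and
    stationarity score) suitable for a JSON sidecar.
    """
    if length is None:
        start, length_ = 0, len(series[0])
    else:
        start = select_window(series, length=length, seed=seed, max_tries=max_tries)
        length_ = length
    windowed = [replace(s, values=s.values[start: start + length_]) for s in series]
    detrended = [linear_detrend(s) for s in windowed]
    normalized = [normalize(s) for s in detrended]
    score = _stationarity_score(np.column_stack([s.values for s in detrended]))
    meta = {"window_start": start + 1, "window_length": length_,
            "stationarity_score": score}
    return Universe(tuple(normalized), normalized=True), meta


def write_window_sidecar(path, meta: dict) -> None:
    """Write the window-selection metadata next to an output file."""
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
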