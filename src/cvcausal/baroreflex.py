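"""Sequence-method baroreflex sensitivity (BRS) and effectiveness (BEI).

A SAP ramp is a run of four beats with three consecutive same-sign SAP
changes, a total excursion larger than 1 mmHg and a beat-index/SAP
correlation above 0.85.  A baroreflex sequence additionally requires a
concordant HP run with total excursion larger than 5 ms and a SAP/HP
correlation above 0.85; its slope is the least-squares line in the
[SAP, HP] plane (ms/mmHg).  BRS is the unweighted mean slope, BEI the
fraction of ramps that evoke a sequence.  All thresholds are strict
inequalities and apply to raw-unit series (ms, mmHg), before any
normalization.  Overlapping four-beat windows are counted individually.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InputError
from .series import BeatSeries

SEQ_BEATS = 4
SAP_THRESHOLD_MMHG = 1.0
HP_THRESHOLD_MS = 5.0
CORR_THRESHOLD = 0.85

#: sentinel for indexes undefined on the record (no qualifying events)
UNDEFINED = float("nan")


@dataclass(frozen=True)
class SapRamp:
    """Four-beat monotone SAP run qualifying as a ramp (0-based start)."""

    start: int
    direction: int
    total_change: float
    correlation: float


@dataclass(frozen=True)
class BaroreflexSequence:
    """Concordant SAP/HP four-beat run with its regression slope."""

    start: int
    direction: int
    slope: float
    correlation: float


def _run_direction(diffs: np.ndarray) -> int:
    """+1 / -1 for three strictly same-sign changes, else 0."""
    if np.all(diffs > 0):
        return 1
    if np.all(diffs < 0):
        return -1
    return 0


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def find_sap_ramps(sap: BeatSeries) -> list[SapRamp]:
    """All four-beat windows qualifying as SAP ramps (overlaps counted)."""
    vals = sap.values
    ramps: list[SapRamp] = []
    beat_idx = np.arange(SEQ_BEATS, dtype=float)
    for start in range(len(vals) - SEQ_BEATS + 1):
        window = vals[start: start + SEQ_BEATS]
        direction = _run_direction(np.diff(window))
        if direction == 0:
            continue
        total = window[-1] - window[0]
        if abs(total) <= SAP_THRESHOLD_MMHG:
            continue
        corr = abs(_corr(beat_idx, window))
        if corr <= CORR_THRESHOLD:
            continue
        ramps.append(SapRamp(start, direction, float(total), corr))
    return ramps


def find_baroreflex_sequences(hp: BeatSeries, sap: BeatSeries) -> list[BaroreflexSequence]:
    """All four-beat windows qualifying as baroreflex sequences (lag 0)."""
    if len(hp) != len(sap):
        raise InputError("HP and SAP series must have equal length")
    hp_v, sap_v = hp.values, sap.values
    sequences: list[BaroreflexSequence] = []
    for start in range(len(sap_v) - SEQ_BEATS + 1):
        sap_w = sap_v[start: start + SEQ_BEATS]
        hp_w = hp_v[start: start + SEQ_BEATS]
        d_sap = _run_direction(np.diff(sap_w))
        d_hp = _run_direction(np.diff(hp_w))
        if d_sap == 0 or d_hp != d_sap:
            continue
        if abs(sap_w[-1] - sap_w[0]) <= SAP_THRESHOLD_MMHG:
            continue
        if abs(hp_w[-1] - hp_w[0]) <= HP_THRESHOLD_MS:
            continue
        corr = _corr(sap_w, hp_w)
        if corr <= CORR_THRESHOLD:
            continue
        slope = float(np.polyfit(sap_w, hp_w, 1)[0])
        sequences.append(BaroreflexSequence(start, d_sap, slope, corr))
    return sequences


def brs(sequences: list[BaroreflexSequence]) -> float:
    """Mean sequence slope in ms/mmHg; NaN when no sequence occurred."""
    if not sequences:
        return UNDEFINED
    return float(np.mean([s.slope for s in sequences]))


def bei(sequences: list[BaroreflexSequence], ramps: list[SapRamp]) -> float:
    """Baroreflex effectiveness: sequences per qualifying SAP ramp."""
    if not ramps:
        return UNDEFINED
    return len(sequences) / len(ramps)


def baroreflex_summary(hp: BeatSeries, sap: BeatSeries) -> dict:
    """One-call BRS/BEI summary used by the pipeline and CLI."""
    ramps = find_sap_ramps(sap)
    sequences = find_baroreflex_sequences(hp, sap)
    brs_value = brs(sequences)
    return {
        "brs": None if math.isnan(brs_value) else brs_value,
        "bei": (None if not ramps else bei(sequences, ramps)),
        "n_sequences": len(sequences),
        "n_ramps": len(ramps),
    }
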