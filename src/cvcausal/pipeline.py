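"""Per-subject and cohort orchestration.

``run_subject`` reproduces the per-recording analysis: select a
256-beat window, detrend and normalize it, compute the normalized
complexity index of every series with the requested methods (MB, LP,
CE), the causality ratio of every directed pair, and the baroreflex
indexes on the raw HP/SAP window.  ``run_cohort`` repeats this over a
manifest of subjects and correlates every computed index with age
through the normality-gated association stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baroreflex import baroreflex_summary
from .ce import cr_ce, default_tolerance, forward_select_ce, nci_ce
from .cohort import associate
from .embedding import EmbeddingSpec
from .exceptions import ConfigurationError, CvCausalError, InputError
from .lp import cr_lp, forward_select_lp, nci_lp
from .mb import cr_mb, nci_mb
from .series import BeatSeries, Universe, linear_detrend, normalize, read_beat_table, select_window

logger = logging.getLogger(__name__)

METHODS = ("MB", "LP", "CE")

#: minimum delays of influence, (effect, source)-indexed by label.
#: The self delay is always 1; SAP and RESP may act on HP within the same
#: beat (fast vagal arm), RESP on SAP within the same beat (intrathoracic
#: pressure transfer); HP on SAP and both on RESP only from the next beat.
DEFAULT_DELAY_TABLE = {
    "HP": {"HP": 1, "SAP": 0, "RESP": 0},
    "SAP": {"HP": 1, "SAP": 1, "RESP": 0},
    "RESP": {"HP": 1, "SAP": 1, "RESP": 1},
}


def default_delays(labels: tuple[str, ...], effect: int) -> tuple[int, ...]:
    """Minimum-delay vector for one effect given the universe labels.

    Labels found in the cardiovascular delay table use its settings;
    unknown labels fall back to delay 1 for the effect itself and 0
    otherwise.
    """
    effect_label = labels[effect]
    row = DEFAULT_DELAY_TABLE.get(effect_label, {})
    return tuple(
        row.get(lab, 1 if j == effect else 0) for j, lab in enumerate(labels)
    )


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings; the defaults are the study preset.

    max_lag 8 (candidate lags per series and the upper end of the MB
    order scan), k = 30 neighbors, percentile tolerance rule for CE,
    Theiler half-width equal to the maximal lag, 256-beat windows.
    """

    methods: tuple[str, ...] = METHODS
    max_lag: int = 8
    orders: tuple[int, ...] = tuple(range(1, 9))
    k: int = 30
    exclusion: int | None = None  # None -> max_lag
    window_length: int | None = 256
    seed: int | None = None
    normalization: str = "fractional"

    def __post_init__(self) -> None:
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ConfigurationError(f"unknown methods: {sorted(bad)}")


def _effect_spec(universe: Universe, effect: int, config: RunConfig) -> EmbeddingSpec:
    delays = default_delays(universe.labels, effect)
    return EmbeddingSpec(effect, delays, config.max_lag)


def run_subject(config: RunConfig, source, subject_id: str = "") -> dict:
    """Full per-subject analysis.

    ``source`` is a beat-table path or a list of :class:`BeatSeries`.
    Returns a JSON-ready dict with window metadata, per-method NCI and
    CR records, selection traces, and the baroreflex summary when HP and
    SAP are both present.
    """
    if isinstance(source, (list, tuple)):
        series = list(source)
    else:
        series = read_beat_table(source)
    labels = [s.label for s in series]

    if config.window_length is None:
        start, length = 0, len(series[0])
    else:
        start = select_window(series, length=config.window_length, seed=config.seed)
        length = config.window_length
    windowed = [replace(s, values=s.values[start: start + length]) for s in series]

    result: dict = {
        "subject": subject_id,
        "window": {"start": start + 1, "length": length},
        "nci": [],
        "cr": [],
    }

    if "HP" in labels and "SAP" in labels:
        result["baroreflex"] = baroreflex_summary(
            windowed[labels.index("HP")], windowed[labels.index("SAP")]
        )

    universe = Universe(
        tuple(normalize(linear_detrend(s)) for s in windowed), normalized=True
    )
    exclusion = config.max_lag if config.exclusion is None else config.exclusion

    for effect in range(universe.n_series):
        spec = _effect_spec(universe, effect, config)
        label = universe.labels[effect]
        others = [j for j in range(universe.n_series) if j != effect]
        t0 = time.perf_counter()
        if "MB" in config.methods:
            result["nci"].append(nci_mb(universe, spec, config.orders).to_dict())
            for cause in others:
                result["cr"].append(
                    cr_mb(universe, spec, cause, config.orders,
                          normalization=config.normalization).to_dict()
                )
        if "LP" in config.methods:
            trace = forward_select_lp(universe, spec, k=config.k, exclusion=exclusion)
            result["nci"].append(nci_lp(trace, effect, label).to_dict())
            for cause in others:
                result["cr"].append(
                    cr_lp(universe, spec, cause, k=config.k, exclusion=exclusion,
                          trace=trace, normalization=config.normalization).to_dict()
                )
        if "CE" in config.methods:
            eps = default_tolerance(universe.series[effect].values)
            trace = forward_select_ce(universe, spec, k=config.k,
                                      exclusion=exclusion, eps=eps)
            result["nci"].append(nci_ce(trace, effect=effect, label=label).to_dict())
            for cause in others:
                result["cr"].append(
                    cr_ce(universe, spec, cause, k=config.k, exclusion=exclusion,
                          eps=eps, trace=trace,
                          normalization=config.normalization).to_dict()
                )
        logger.debug("subject %s effect %s: %.2f s", subject_id, label,
                     time.perf_counter() - t0)
    return result


def _index_records(bundle: dict) -> dict[str, float]:
    """Flatten a subject bundle into {index name: value}."""
    out: dict[str, float] = {}
    for rec in bundle["nci"]:
        out[f"NCI_{rec['effect']}_{rec['method']}"] = rec["nci"]
    for rec in bundle["cr"]:
        out[f"CR_{rec['cause']}->{rec['effect']}_{rec['method']}"] = rec["cr"]
    baro = bundle.get("baroreflex")
    if baro:
        if baro["brs"] is not None:
            out["BRS"] = baro["brs"]
        if baro["bei"] is not None:
            out["BEI"] = baro["bei"]
    return out


def run_cohort(config: RunConfig, manifest: pd.DataFrame | str) -> pd.DataFrame:
    """Index-on-age association tables over a cohort manifest.

    ``manifest`` needs columns ``subject``, ``age``, ``path`` (beat-table
    file per subject) and optionally ``condition``.  Unreadable subjects
    are logged and excluded; fewer than 8 usable subjects is an error.
    Returns a table with one row per (condition, index): correlation
    coefficient, chosen method and significance flag.
    """
    if isinstance(manifest, (str,)) or hasattr(manifest, "__fspath__"):
        manifest = pd.read_csv(manifest)
    required = {"subject", "age", "path"}
    if not required.issubset(manifest.columns):
        raise ConfigurationError(f"manifest needs columns {sorted(required)}")
    if "condition" not in manifest.columns:
        manifest = manifest.assign(condition="ALL")

    rows = []
    n_failed = 0
    for rec in manifest.itertuples(index=False):
        try:
            bundle = run_subject(config, rec.path, subject_id=str(rec.subject))
        except (CvCausalError, OSError) as exc:
            logger.warning("subject %s skipped: %s", rec.subject, exc)
            n_failed += 1
            continue
        for name, value in _index_records(bundle).items():
            rows.append({"subject": rec.subject, "age": rec.age,
                         "condition": rec.condition, "index": name, "value": value})
    if n_failed:
        logger.warning("%d subject(s) excluded", n_failed)
    long = pd.DataFrame(rows)
    if long.empty:
        raise InputError("no usable subjects in manifest")

    tables = []
    for (condition, index), grp in long.groupby(["condition", "index"]):
        if grp.shape[0] < 8:
            raise InputError(
                f"only {grp.shape[0]} subjects for {index} in {condition}; need >= 8"
            )
        res = associate(grp["value"].to_numpy(), grp["age"].to_numpy(), index)
        tables.append({"condition": condition, **res.to_dict()})
    return pd.DataFrame(tables)


def bundle_to_json(bundle: dict) -> str:
    """Deterministic JSON serialization of a subject bundle."""
    return json.dumps(bundle, indent=2, sort_keys=True, allow_nan=True)
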