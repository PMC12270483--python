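"""Shared domain types and CSV input/output for the LH pulsatility pipeline.

Everything downstream (pulse detection, phenotyping metrics, qPCR
quantification, benchmarking) operates on the validated containers defined
here.  CSV is the sole external format; column names are fixed but matched
case-insensitively, and every reader validates the stated invariants rather
than silently dropping offending rows.

Times are always minutes from the first sample of each animal.  The
"canonical" serial-bleed design is one sample every 10 min over 180 min
(19 samples per animal); series matching that grid are flagged so that
downstream code can assert the full sampling contract where it matters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("lhpulse")

__all__ = [
    "FormatError",
    "ValidationError",
    "ParameterError",
    "STAGES",
    "normalize_stage",
    "LHSeries",
    "PulseCalls",
    "PulseSummary",
    "CycleLog",
    "PubertyRecord",
    "SurgeRecord",
    "QpcrRecord",
    "read_lh_csv",
    "write_lh_csv",
    "read_summary_csv",
    "write_summary_csv",
    "read_cycle_log_csv",
    "read_surge_csv",
    "read_puberty_csv",
    "read_qpcr_csv",
]


class FormatError(ValueError):
    """A file does not conform to the expected CSV schema."""


class ValidationError(ValueError):
    """Data violates a domain-type invariant (bad value, not bad schema)."""


class ParameterError(ValueError):
    """An argument to an operation is outside its admissible range."""


# ---------------------------------------------------------------------------
# Estrous stage vocabulary
# ---------------------------------------------------------------------------

STAGES = ("proestrus", "estrus", "metestrus", "diestrus")

_STAGE_ALIASES = {
    "p": "proestrus",
    "pro": "proestrus",
    "proestrus": "proestrus",
    "e": "estrus",
    "est": "estrus",
    "estrus": "estrus",
    "m": "metestrus",
    "met": "metestrus",
    "metestrus": "metestrus",
    "d": "diestrus",
    "di": "diestrus",
    "diestrus": "diestrus",
}


def normalize_stage(label: str) -> str:
    """Map an estrous-stage label (or accepted abbreviation) to its canonical
    lower-case name; raise :class:`ValidationError` for anything else."""
    key = str(label).strip().lower()
    try:
        return _STAGE_ALIASES[key]
    except KeyError:
        raise ValidationError(
            f"unknown estrous stage label {label!r}; expected one of {STAGES} "
            "or abbreviations p/e/met/di"
        ) from None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def _as_float_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class LHSeries:
    """One animal's serial LH concentrations on a time grid.

    Parameters
    ----------
    animal_id, group
        Opaque labels carried through to every output table.
    times
        Minutes from the first sample; strictly increasing, finite.
    values
        LH concentration in ng/ml; finite and non-negative.
    stage
        Optional estrous stage at sampling (normalized if given).
    canonical
        True when the series matches the canonical 10-min x 180-min grid
        (19 samples).  Set by :func:`read_lh_csv` / the simulator.
    """

    animal_id: str
    group: str
    times: np.ndarray
    values: np.ndarray
    stage: Optional[str] = None
    canonical: bool = False

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.values = _as_float_array(self.values, "values")
        if len(self.times) != len(self.values) or len(self.times) < 1:
            raise ValidationError(
                f"animal {self.animal_id!r}: times and values must have equal "
                f"length >= 1 (got {len(self.times)} and {len(self.values)})"
            )
        if not np.all(np.isfinite(self.times)):
            raise ValidationError(f"animal {self.animal_id!r}: non-finite time")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"animal {self.animal_id!r}: times must be strictly increasing"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"animal {self.animal_id!r}: non-finite LH value")
        if np.any(self.values < 0):
            raise ValidationError(f"animal {self.animal_id!r}: negative LH value")
        if self.stage is not None:
            self.stage = normalize_stage(self.stage)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PulseCalls:
    """Pulse peaks called on one :class:`LHSeries` by the rule detector.

    Indices lie in [1, n-2]: the first sample has no preceding values and
    the last no following one.  ``last_callable`` relaxes the upper bound to
    n-1, for calls produced by a detector configured to waive the
    (unevaluable) fall condition at the final sample.
    """

    series: LHSeries
    pulse_indices: np.ndarray
    pulse_times: np.ndarray
    pulse_heights: np.ndarray
    last_callable: bool = False

    def __post_init__(self) -> None:
        self.pulse_indices = np.asarray(self.pulse_indices, dtype=int)
        self.pulse_times = _as_float_array(self.pulse_times, "pulse_times")
        self.pulse_heights = _as_float_array(self.pulse_heights, "pulse_heights")
        n = len(self.series)
        idx = self.pulse_indices
        if len(idx) != len(self.pulse_times) or len(idx) != len(self.pulse_heights):
            raise ValidationError("pulse call arrays must have equal length")
        if len(idx) > 0:
            upper = n - 1 if self.last_callable else n - 2
            if idx.min() < 1 or idx.max() > upper:
                raise ValidationError(
                    f"pulse indices must lie in [1, {upper}]; the first "
                    "sample is never callable and the last only when the "
                    "fall condition is explicitly waived"
                )
            if np.any(np.diff(idx) <= 0):
                raise ValidationError("pulse indices must be strictly increasing")
            if not np.array_equal(self.pulse_heights, self.series.values[idx]):
                raise ValidationError("pulse heights must equal series values")

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_indices)


@dataclass
class PulseSummary:
    """The four pulsatility statistics for one animal's sampling window:
    total secretory mass (trapezoidal AUC), pulse amplitude (mean of the 4
    highest samples), basal LH (mean of the 4 lowest samples), and the number
    of detected pulses."""

    animal_id: str
    group: str
    auc: float  # ng*min/ml
    amplitude: float  # ng/ml
    basal: float  # ng/ml
    n_pulses: int
    window_minutes: float

    def __post_init__(self) -> None:
        if not (self.basal <= self.amplitude):
            raise ValidationError(
                f"animal {self.animal_id!r}: basal ({self.basal}) exceeds "
                f"amplitude ({self.amplitude})"
            )
        if self.n_pulses < 0:
            raise ValidationError("n_pulses must be non-negative")


@dataclass
class CycleLog:
    """Daily estrous-stage calls for one animal over consecutive days."""

    animal_id: str
    days: np.ndarray
    stages: tuple

    MAX_DAYS: int = field(default=366, repr=False)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.stages = tuple(normalize_stage(s) for s in self.stages)
        if len(self.days) != len(self.stages) or len(self.days) < 1:
            raise ValidationError(
                f"animal {self.animal_id!r}: need one stage per day, >= 1 day"
            )
        if len(self.days) > self.MAX_DAYS:
            raise ValidationError(
                f"animal {self.animal_id!r}: log longer than {self.MAX_DAYS} days"
            )
        if len(self.days) > 1 and not np.all(np.diff(self.days) == 1):
            raise ValidationError(
                f"animal {self.animal_id!r}: days must be consecutive integers"
            )

    def __len__(self) -> int:
        return len(self.days)


@dataclass
class PubertyRecord:
    """Puberty-onset milestones for one animal: age at vaginal opening (VO)
    and at first estrus (FE), in days, with optional body weight at VO."""

    animal_id: str
    group: str
    age_vo: Optional[float] = None
    age_fe: Optional[float] = None
    bw_at_vo: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("age_vo", "age_fe", "bw_at_vo"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v)):
                setattr(self, name, None)
        if self.age_vo is not None and self.age_vo <= 0:
            raise ValidationError(f"animal {self.animal_id!r}: age_vo must be > 0")
        if self.age_fe is not None and self.age_fe <= 0:
            raise ValidationError(f"animal {self.animal_id!r}: age_fe must be > 0")
        if self.age_vo is not None and self.age_fe is not None:
            if self.age_fe < self.age_vo:
                raise ValidationError(
                    f"animal {self.animal_id!r}: first estrus ({self.age_fe}) "
                    f"precedes vaginal opening ({self.age_vo})"
                )


@dataclass
class SurgeRecord:
    """Paired AM (8 a.m.) / PM (7 p.m.) LH samples from the surge-induction
    protocol, in ng/ml."""

    animal_id: str
    group: str
    lh_am: float
    lh_pm: float

    def __post_init__(self) -> None:
        for name in ("lh_am", "lh_pm"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"animal {self.animal_id!r}: {name} must be finite and >= 0"
                )


@dataclass
class QpcrRecord:
    """Replicate qPCR cycle-threshold values for one (sample, gene) pair."""

    sample_id: str
    group: str
    gene: str
    ct_replicates: tuple
    is_housekeeping: bool = False

    def __post_init__(self) -> None:
        self.ct_replicates = tuple(float(c) for c in self.ct_replicates)
        if len(self.ct_replicates) < 1:
            raise ValidationError(
                f"sample {self.sample_id!r} gene {self.gene!r}: need >= 1 Ct"
            )
        for c in self.ct_replicates:
            if not (0 < c <= 45) or not math.isfinite(c):
                raise ValidationError(
                    f"sample {self.sample_id!r} gene {self.gene!r}: Ct {c} "
                    "outside (0, 45]"
                )

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_replicates))


# ---------------------------------------------------------------------------
# CSV helpers
# ---------------------------------------------------------------------------


def _load_table(path, required: Sequence[str], optional: Sequence[str] = ()) -> pd.DataFrame:
    """Read a CSV and return it with lower-cased column names, checking that
    the required schema columns are present."""
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def _format_floats(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    """Render float columns with Python's shortest round-trippable repr, so
    a write -> read cycle reproduces the values bit-equal."""
    df = df.copy()
    for c in cols:
        df[c] = [repr(float(v)) for v in df[c]]
    return df


def read_lh_csv(
    path,
    expected_interval: float = 10.0,
    expected_duration: float = 180.0,
    interpolate_single_missing: bool = False,
) -> list[LHSeries]:
    """Read serial LH series, one :class:`LHSeries` per animal.

    The file must have columns ``animal_id, group, time_min, lh_ng_ml``
    (case-insensitive; an optional ``stage`` column is carried through).  Row
    order is irrelevant: rows are grouped by animal and sorted by time, and
    times are re-based to minutes from each animal's first sample.  A series
    whose re-based grid equals ``0, expected_interval, ..., expected_duration``
    is flagged canonical.

    Missing LH values (empty cells / NaN) reject the series unless
    ``interpolate_single_missing`` is set, in which case a single missing
    *interior* sample is filled by linear interpolation (and logged).
    """
    df = _load_table(path, ["animal_id", "group", "time_min", "lh_ng_ml"])
    grid = np.arange(0.0, expected_duration + expected_interval / 2, expected_interval)
    out: list[LHSeries] = []
    for animal, sub in df.groupby("animal_id", sort=False):
        sub = sub.sort_values("time_min", kind="stable")
        times = sub["time_min"].to_numpy(dtype=float)
        values = sub["lh_ng_ml"].to_numpy(dtype=float)
        if np.any(~np.isfinite(times)):
            raise ValidationError(f"animal {animal!r}: missing/invalid time_min")
        dup = np.flatnonzero(np.diff(times) == 0)
        if dup.size:
            raise ValidationError(
                f"animal {animal!r}: duplicated time {times[dup[0]]} min "
                f"(rows {sub.index[dup[0]]} and {sub.index[dup[0] + 1]})"
            )
        missing = np.flatnonzero(~np.isfinite(values))
        if missing.size:
            interior = (missing > 0) & (missing < len(values) - 1)
            if interpolate_single_missing and missing.size == 1 and interior.all():
                i = int(missing[0])
                t0, t1, t2 = times[i - 1], times[i], times[i + 1]
                values[i] = values[i - 1] + (values[i + 1] - values[i - 1]) * (
                    (t1 - t0) / (t2 - t0)
                )
                log.warning(
                    "animal %r: interpolated missing LH at t=%g min", animal, t1
                )
            else:
                raise ValidationError(
                    f"animal {animal!r}: {missing.size} missing LH value(s) at "
                    f"row(s) {list(sub.index[missing])}"
                )
        bad = np.flatnonzero(values < 0)
        if bad.size:
            raise ValidationError(
                f"animal {animal!r}: negative LH at row {sub.index[bad[0]]}"
            )
        times = times - times[0]
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValidationError(f"animal {animal!r}: inconsistent group labels")
        stage = None
        if "stage" in sub.columns:
            st = sub["stage"].dropna().unique()
            if len(st) == 1:
                stage = str(st[0])
        canonical = len(times) == len(grid) and np.allclose(times, grid)
        out.append(
            LHSeries(
                animal_id=str(animal),
                group=str(groups[0]),
                times=times,
                values=values,
                stage=stage,
                canonical=canonical,
            )
        )
    if not out:
        raise ValidationError(f"{path}: no data rows")
    return out


def write_lh_csv(series: Iterable[LHSeries], path) -> None:
    """Write LH series in the same schema :func:`read_lh_csv` accepts."""
    rows = []
    for s in series:
        for t, v in zip(s.times, s.values):
            rows.append(
                {"animal_id": s.animal_id, "group": s.group, "time_min": t, "lh_ng_ml": v}
            )
    if not rows:
        raise ValidationError("no series to write")
    df = _format_floats(pd.DataFrame(rows), ["time_min", "lh_ng_ml"])
    df.to_csv(path, index=False)


_SUMMARY_COLS = ["animal_id", "group", "auc", "amplitude", "basal", "n_pulses", "window_minutes"]


def write_summary_csv(summaries: Iterable[PulseSummary], path) -> None:
    """Write one row per animal with the four pulsatility statistics.

    Floats are written with pandas' shortest round-trippable representation,
    so re-reading reproduces the values bit-equal.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValidationError("no summaries to write")
    df = pd.DataFrame(
        [{c: getattr(s, c) for c in _SUMMARY_COLS} for s in summaries],
        columns=_SUMMARY_COLS,
    )
    df = _format_floats(df, ["auc", "amplitude", "basal", "window_minutes"])
    df.to_csv(path, index=False)


def read_summary_csv(path) -> list[PulseSummary]:
    df = _load_table(path, _SUMMARY_COLS)
    return [
        PulseSummary(
            animal_id=str(r.animal_id),
            group=str(r.group),
            auc=float(r.auc),
            amplitude=float(r.amplitude),
            basal=float(r.basal),
            n_pulses=int(r.n_pulses),
            window_minutes=float(r.window_minutes),
        )
        for r in df.itertuples(index=False)
    ]


def read_cycle_log_csv(path) -> list[CycleLog]:
    """Read daily estrous-stage logs (columns ``animal_id, day, stage``)."""
    df = _load_table(path, ["animal_id", "day", "stage"])
    out = []
    for animal, sub in df.groupby("animal_id", sort=False):
        sub = sub.sort_values("day", kind="stable")
        out.append(
            CycleLog(
                animal_id=str(animal),
                days=sub["day"].to_numpy(dtype=int),
                stages=tuple(sub["stage"]),
            )
        )
    if not out:
        raise ValidationError(f"{path}: no data rows")
    return out


def read_surge_csv(path) -> list[SurgeRecord]:
    """Read AM/PM surge samples (columns ``animal_id, group, lh_am, lh_pm``)."""
    df = _load_table(path, ["animal_id", "group", "lh_am", "lh_pm"])
    return [
        SurgeRecord(str(r.animal_id), str(r.group), float(r.lh_am), float(r.lh_pm))
        for r in df.itertuples(index=False)
    ]


def read_puberty_csv(path) -> list[PubertyRecord]:
    """Read puberty milestones (columns ``animal_id, group, age_vo, age_fe``
    and optionally ``bw_at_vo``)."""
    df = _load_table(path, ["animal_id", "group", "age_vo", "age_fe"])

    def _opt(v):
        v = float(v)
        return v if math.isfinite(v) else None

    return [
        PubertyRecord(
            animal_id=str(r.animal_id),
            group=str(r.group),
            age_vo=_opt(r.age_vo),
            age_fe=_opt(r.age_fe),
            bw_at_vo=_opt(getattr(r, "bw_at_vo", float("nan"))),
        )
        for r in df.itertuples(index=False)
    ]


def read_qpcr_csv(path, housekeeping: str = "Hprt") -> list[QpcrRecord]:
    """Read a long-format Ct table (columns ``sample_id, group, gene, ct``;
    one row per replicate).  Replicates are collected per (sample, gene) and
    the housekeeping flag is set by case-insensitive gene-name match."""
    df = _load_table(path, ["sample_id", "group", "gene", "ct"])
    out = []
    for (sample, gene), sub in df.groupby(["sample_id", "gene"], sort=False):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValidationError(f"sample {sample!r}: inconsistent group labels")
        out.append(
            QpcrRecord(
                sample_id=str(sample),
                group=str(groups[0]),
                gene=str(gene),
                ct_replicates=tuple(sub["ct"].astype(float)),
                is_housekeeping=str(gene).lower() == housekeeping.lower(),
            )
        )
    if not out:
        raise ValidationError(f"{path}: no data rows")
    return out
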