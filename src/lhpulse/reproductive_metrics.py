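"""Estrous-cyclicity, puberty-onset and LH-surge descriptors.

Stage proportions summarize a daily vaginal-cytology log as the percent of
logged days spent in each stage; by default metestrus days are folded into
diestrus, matching the common three-stage (diestrus/proestrus/estrus)
reporting.  Puberty onset is described by the cumulative percent of animals
having reached the milestone (vaginal opening or first estrus) by each age,
plus mean +/- SEM age per group.  The estradiol-induced LH surge is described
per animal by the PM - AM difference and PM/AM ratio — no binary "surge
present" threshold is imposed; group-level inference is left to group_stats.

SEM throughout is the sample standard deviation (ddof=1) divided by sqrt(n),
undefined (NaN) for groups of one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .timeseries_io import (
    CycleLog,
    ParameterError,
    PubertyRecord,
    STAGES,
    SurgeRecord,
    ValidationError,
)

__all__ = [
    "CycleSummary",
    "SurgeResponse",
    "stage_proportions",
    "puberty_cumulative",
    "surge_response",
    "sem",
]


def sem(x: Sequence[float]) -> float:
    """Standard error of the mean: sd(ddof=1)/sqrt(n); NaN for n < 2."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / math.sqrt(len(x)))


@dataclass
class CycleSummary:
    """Percent of logged days per estrous stage for one animal."""

    animal_id: str
    percent_by_stage: dict
    n_days: int

    def __post_init__(self) -> None:
        total = sum(self.percent_by_stage.values())
        if abs(total - 100.0) > 1e-9:
            raise ValidationError(
                f"animal {self.animal_id!r}: stage percents sum to {total}, not 100"
            )
        if any(p < 0 for p in self.percent_by_stage.values()):
            raise ValidationError(f"animal {self.animal_id!r}: negative stage percent")


def stage_proportions(log: CycleLog, collapse_metestrus: bool = True) -> CycleSummary:
    """Per-stage day counts / total days x 100.

    With ``collapse_metestrus`` (default), metestrus days are counted as
    diestrus and the summary reports three stages; proestrus and estrus
    percents are unaffected by the collapse.
    """
    n = len(log)
    if n == 0:
        raise ValidationError(f"animal {log.animal_id!r}: empty cycle log")
    stages = list(STAGES)
    counts = {s: 0 for s in stages}
    for s in log.stages:
        counts[s] += 1
    if collapse_metestrus:
        counts["diestrus"] += counts.pop("metestrus")
    percents = {s: 100.0 * c / n for s, c in counts.items()}
    return CycleSummary(animal_id=log.animal_id, percent_by_stage=percents, n_days=n)


def puberty_cumulative(
    records: Iterable[PubertyRecord], event: str = "vo"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cumulative puberty-onset curves and per-group mean +/- SEM ages.

    Parameters
    ----------
    records
        Puberty milestones; animals without the requested event recorded are
        excluded from that event's curve.
    event
        ``"vo"`` (vaginal opening) or ``"fe"`` (first estrus).

    Returns
    -------
    curve : DataFrame with columns ``group, age, cumulative_percent`` — for
        each integer age from the earliest to the latest event age, the
        percent of the group's animals with event age <= that age.  Each
        group's curve is non-decreasing and ends at exactly 100.
    stats : DataFrame with columns ``group, n, mean_age, sem_age``.
    """
    if event not in ("vo", "fe"):
        raise ParameterError(f"event must be 'vo' or 'fe', got {event!r}")
    attr = f"age_{event}"
    ages_by_group: dict[str, list[float]] = {}
    for r in records:
        age = getattr(r, attr)
        if age is not None:
            ages_by_group.setdefault(r.group, []).append(age)
    if not ages_by_group:
        raise ValidationError(f"no animal has event {event!r} recorded")

    all_ages = np.concatenate([np.asarray(v) for v in ages_by_group.values()])
    age_grid = np.arange(int(np.floor(all_ages.min())), int(np.ceil(all_ages.max())) + 1)
    curve_rows = []
    stat_rows = []
    for g, ages in ages_by_group.items():
        ages_arr = np.asarray(ages, dtype=float)
        for a in age_grid:
            pct = 100.0 * np.mean(ages_arr <= a)
            curve_rows.append({"group": g, "age": int(a), "cumulative_percent": pct})
        stat_rows.append(
            {"group": g, "n": len(ages_arr), "mean_age": float(np.mean(ages_arr)),
             "sem_age": sem(ages_arr)}
        )
    return pd.DataFrame(curve_rows), pd.DataFrame(stat_rows)


@dataclass
class SurgeResponse:
    """Per-animal surge descriptors: delta = PM - AM (ng/ml) and the PM/AM
    ratio (NaN when AM = 0, where the ratio is undefined)."""

    animal_id: str
    group: str
    delta: float
    ratio: float


def surge_response(
    records: Iterable[SurgeRecord],
) -> tuple[list[SurgeResponse], pd.DataFrame]:
    """Per-animal surge descriptors plus per-group mean +/- SEM of AM, PM,
    delta and ratio.  Groups of a single animal have NaN SEMs (flagged by the
    ``sem_defined`` column)."""
    records = list(records)
    if not records:
        raise ValidationError("no surge records")
    responses = []
    for r in records:
        ratio = r.lh_pm / r.lh_am if r.lh_am > 0 else float("nan")
        responses.append(SurgeResponse(r.animal_id, r.group, r.lh_pm - r.lh_am, ratio))

    rows = []
    groups = {}
    for r, resp in zip(records, responses):
        groups.setdefault(r.group, []).append((r.lh_am, r.lh_pm, resp.delta, resp.ratio))
    for g, vals in groups.items():
        am, pm, delta, ratio = (np.asarray(col, dtype=float) for col in zip(*vals))
        finite_ratio = ratio[np.isfinite(ratio)]
        rows.append(
            {
                "group": g,
                "n": len(am),
                "am_mean": float(np.mean(am)),
                "am_sem": sem(am),
                "pm_mean": float(np.mean(pm)),
                "pm_sem": sem(pm),
                "delta_mean": float(np.mean(delta)),
                "delta_sem": sem(delta),
                "ratio_mean": float(np.mean(finite_ratio)) if len(finite_ratio) else float("nan"),
                "sem_defined": len(am) >= 2,
            }
        )
    return responses, pd.DataFrame(rows)
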