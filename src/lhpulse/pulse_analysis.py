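"""Rule-based LH pulse detection and the four pulsatility statistics.

The detector reproduces the threshold rules used to score serial-bleed LH
profiles in mice: a sample is a pulse peak iff its height is

  * more than ``rise_factor`` (default 1.20, i.e. 20% greater) times *each*
    of the two previous samples, and
  * more than ``fall_factor`` (default 1.10, i.e. 10% greater) times the
    following sample;
  * at the second sample of the series, where only one previous value
    exists, the rise test compares against that single value with
    ``second_point_factor`` (default 1.20).

All inequalities are strict, every index is evaluated independently (no
refractory period, no smoothing), and the first and last samples are never
callable — the first has no preceding values and the last no following one.
The rules are purely multiplicative, so calls are invariant to rescaling
the series.

Pulsatility is summarized per animal by: total secretory mass (trapezoidal
AUC of ng/ml over minutes), pulse amplitude (mean of the 4 highest samples),
basal LH (mean of the 4 lowest samples), and the number of called pulses in
the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .timeseries_io import LHSeries, ParameterError, PulseCalls, PulseSummary

__all__ = [
    "PulseRuleParams",
    "SeriesTooShortError",
    "detect_pulses",
    "auc",
    "pulse_amplitude",
    "basal_lh",
    "summarize_pulsatility",
]


class SeriesTooShortError(ValueError):
    """The series has too few samples for the requested operation."""


@dataclass(frozen=True)
class PulseRuleParams:
    """Thresholds of the rule detector.

    ``rise_compare`` selects how the two previous values enter the rise test:
    ``"each"`` (default) requires the peak to exceed the threshold against
    both values individually; ``"mean"`` compares against their mean.
    ``allow_last`` waives the (unevaluable) fall condition at the final
    sample; off by default because no look-ahead datum exists there.
    """

    rise_factor: float = 1.20
    fall_factor: float = 1.10
    second_point_factor: float = 1.20
    rise_compare: str = "each"
    allow_last: bool = False

    def __post_init__(self) -> None:
        for name in ("rise_factor", "fall_factor", "second_point_factor"):
            if not getattr(self, name) > 1:
                raise ParameterError(f"{name} must be > 1")
        if self.rise_compare not in ("each", "mean"):
            raise ParameterError("rise_compare must be 'each' or 'mean'")


def detect_pulses(series: LHSeries, params: Optional[PulseRuleParams] = None) -> PulseCalls:
    """Apply the three threshold rules at every index of a series.

    Raises :class:`SeriesTooShortError` for series with fewer than 3 samples,
    where no index has both a preceding and a following neighbour.
    """
    if params is None:
        params = PulseRuleParams()
    v = series.values
    n = len(v)
    if n < 3:
        raise SeriesTooShortError(
            f"animal {series.animal_id!r}: need >= 3 samples to call pulses, got {n}"
        )
    last_callable = n - 1 if params.allow_last else n - 2
    idx = []
    for i in range(1, last_callable + 1):
        if i == 1:
            rise = v[1] > params.second_point_factor * v[0]
        elif params.rise_compare == "each":
            rise = (v[i] > params.rise_factor * v[i - 1]) and (
                v[i] > params.rise_factor * v[i - 2]
            )
        else:
            rise = v[i] > params.rise_factor * 0.5 * (v[i - 1] + v[i - 2])
        if not rise:
            continue
        fall = True if i == n - 1 else v[i] > params.fall_factor * v[i + 1]
        if fall:
            idx.append(i)
    idx = np.asarray(idx, dtype=int)
    return PulseCalls(
        series=series,
        pulse_indices=idx,
        pulse_times=series.times[idx],
        pulse_heights=series.values[idx],
        last_callable=params.allow_last,
    )


def auc(series: LHSeries) -> float:
    """Total secretory mass: trapezoidal integral of LH (ng/ml) over the
    sampling window (minutes), in ng*min/ml."""
    if len(series) < 2:
        raise SeriesTooShortError(
            f"animal {series.animal_id!r}: AUC undefined for fewer than 2 samples"
        )
    return float(np.trapezoid(series.values, series.times))


def _k_extreme_mean(series: LHSeries, k: int, largest: bool) -> float:
    if k < 1:
        raise ParameterError("k must be >= 1")
    n = len(series)
    if n < k:
        raise SeriesTooShortError(
            f"animal {series.animal_id!r}: need >= {k} samples, got {n}"
        )
    v = np.sort(series.values)
    chosen = v[-k:] if largest else v[:k]
    return float(np.mean(chosen))


def pulse_amplitude(series: LHSeries, k: int = 4) -> float:
    """Mean of the k (default 4) highest LH values in the window, ng/ml."""
    return _k_extreme_mean(series, k, largest=True)


def basal_lh(series: LHSeries, k: int = 4) -> float:
    """Mean of the k (default 4) lowest LH values in the window, ng/ml."""
    return _k_extreme_mean(series, k, largest=False)


def summarize_pulsatility(
    series: LHSeries, params: Optional[PulseRuleParams] = None, k: int = 4
) -> PulseSummary:
    """Bundle AUC, amplitude, basal and pulse count for one series."""
    if len(series) < max(k, 3):
        raise SeriesTooShortError(
            f"animal {series.animal_id!r}: need >= {max(k, 3)} samples to summarize"
        )
    calls = detect_pulses(series, params)
    return PulseSummary(
        animal_id=series.animal_id,
        group=series.group,
        auc=auc(series),
        amplitude=pulse_amplitude(series, k),
        basal=basal_lh(series, k),
        n_pulses=calls.n_pulses,
        window_minutes=float(series.times[-1] - series.times[0]),
    )
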