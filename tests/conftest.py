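"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from lhpulse import LHSeries


def brute_force_pulse_indices(values, rise=1.2, fall=1.1, second=1.2):
    """Independent, literal re-evaluation of the three pulse rules at every
    index.  Deliberately written as plain transcription of the rule text,
    separate from the library implementation, to serve as the oracle.

    A peak at index i (0-based) is a pulse iff:
      rule 1 (i >= 2): height > rise x previous value AND > rise x the value
                       before that;
      rule 2 (any callable i): height > fall x following value — hence the
                       final sample, with no following value, is never a pulse;
      rule 3 (i == 1): height > second x the single preceding value,
                       replacing rule 1.
    """
    v = list(values)
    n = len(v)
    out = []
    for i in range(n):
        if i == 0 or i == n - 1:
            continue
        if i == 1:
            rise_ok = v[1] > second * v[0]
        else:
            rise_ok = v[i] > rise * v[i - 1] and v[i] > rise * v[i - 2]
        fall_ok = v[i] > fall * v[i + 1]
        if rise_ok and fall_ok:
            out.append(i)
    return out


def make_series(values, interval=10.0, animal_id="a1", group="g"):
    values = np.asarray(values, dtype=float)
    times = np.arange(len(values)) * interval
    return LHSeries(animal_id=animal_id, group=group, times=times, values=values)


@pytest.fixture
def constant_series():
    """The canonical 19-sample series at a constant 0.4 ng/ml."""
    return make_series([0.4] * 19)


@pytest.fixture
def single_pulse_series():
    """One clear pulse at t=30 on an otherwise flat 0.30 ng/ml series."""
    return make_series([0.30, 0.30, 0.30, 0.50, 0.30, 0.30])
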