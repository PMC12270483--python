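"""Generative models for every input the analysis pipeline consumes.

The study this pipeline targets deposits its serial-bleed LH measurements
only as figure points, so testable inputs have to be simulated.  The LH
generator uses the standard minimal model of episodic secretion: pulses are
instantaneous concentration increments that decay by first-order clearance,

    C(t) = baseline + sum_i  a_i * 2^(-(t - t_i)/half_life)   for t >= t_i,

sampled on a regular grid (canonically every 10 min over 180 min), with
additive Gaussian assay noise and the ELISA functional-sensitivity floor
(0.0039 ng/ml) applied as left-censoring.  Pulse onsets follow a gamma
renewal process started at a uniform phase; per-pulse increments are
log-normal.  Every generator is bit-reproducible given its seed, and each
returns the ground truth needed for detector benchmarking.

Also here: semi-Markov estrous-cycle logs, AM/PM surge cohorts, and
comparative-Ct qPCR tables with known fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .timeseries_io import (
    CycleLog,
    LHSeries,
    ParameterError,
    QpcrRecord,
    STAGES,
    SurgeRecord,
)

__all__ = [
    "SimParams",
    "GroundTruth",
    "paper_like_params",
    "isolated_pulse_params",
    "simulate_lh_series",
    "simulate_cohort",
    "simulate_cycle_log",
    "simulate_surge_cohort",
    "simulate_qpcr",
]


@dataclass(frozen=True)
class SimParams:
    """Full parameterization of the pulsatile-LH generative model.

    Parameters
    ----------
    baseline : ng/ml
        Tonic inter-pulse concentration.
    mean_ipi : minutes
        Mean inter-pulse interval of the renewal process; ``inf`` disables
        pulses entirely.
    ipi_shape
        Gamma shape of the inter-pulse intervals; larger = more regular.
    amp_mean, amp_sd : ng/ml
        Mean and SD of the log-normal per-pulse concentration increments.
    half_life : minutes
        First-order clearance half-life.
    noise_sd : ng/ml
        Additive Gaussian assay noise.
    lod : ng/ml
        Assay detection floor; observed values are clipped from below.
    interval, duration : minutes
        Sampling step and total window; duration must be a multiple of the
        interval (the canonical design is 10 and 180 -> 19 samples).
    onset_times, amplitudes
        Optional forced pulse trains; when given they replace the renewal
        draw exactly (used for closed-form oracles and benchmarking).
    """

    baseline: float = 0.35
    mean_ipi: float = 60.0
    ipi_shape: float = 4.0
    amp_mean: float = 0.3
    amp_sd: float = 0.15
    half_life: float = 20.0
    noise_sd: float = 0.02
    lod: float = 0.0039
    interval: float = 10.0
    duration: float = 180.0
    seed: int = 0
    onset_times: Optional[tuple] = None
    amplitudes: Optional[tuple] = None

    def __post_init__(self) -> None:
        for name in ("baseline", "ipi_shape", "amp_mean", "half_life", "interval", "duration"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not self.mean_ipi > 0:
            raise ParameterError("mean_ipi must be > 0 (inf allowed)")
        if self.amp_sd < 0 or self.noise_sd < 0 or self.lod < 0:
            raise ParameterError("amp_sd, noise_sd and lod must be >= 0")
        n_steps = self.duration / self.interval
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ParameterError("duration must be a multiple of interval")
        if (self.onset_times is None) != (self.amplitudes is None):
            raise ParameterError("onset_times and amplitudes must be given together")
        if self.onset_times is not None:
            object.__setattr__(self, "onset_times", tuple(float(t) for t in self.onset_times))
            object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))
            if len(self.onset_times) != len(self.amplitudes):
                raise ParameterError("onset_times and amplitudes lengths differ")
            if any(a <= 0 for a in self.amplitudes):
                raise ParameterError("forced amplitudes must be > 0")
            if any(t < 0 or t >= self.duration for t in self.onset_times):
                raise ParameterError("forced onsets must lie in [0, duration)")

    @property
    def grid(self) -> np.ndarray:
        """The sampling grid 0, interval, ..., duration."""
        n = int(round(self.duration / self.interval)) + 1
        return np.arange(n) * self.interval


def paper_like_params(**overrides) -> SimParams:
    """The default calibration preset: baseline 0.35 ng/ml, amp_mean 0.3,
    half-life 20 min, mean IPI 60 min, noise SD 0.02, canonical 10x180 grid.

    These values place simulated basal, amplitude and pulse counts in the
    ranges reported for control animals; they are calibration choices of this
    package, not measured secretion parameters.
    """
    return SimParams(**overrides)


def isolated_pulse_params(seed: int, noise_sd: float = 0.0, **overrides) -> SimParams:
    """Noise-free, well-separated tall-pulse study conditions for parameter
    recovery: first onset uniform in [35, 50] min so the four pre-pulse grid
    samples sit exactly at baseline, subsequent gaps uniform in [50, 70] min,
    amplitudes uniform in [0.4, 0.6] ng/ml, onsets confined to [35, 160].

    On the noiseless 10-min grid these pulses provably satisfy the detector's
    rule predicate (rise >20% over both previous samples, fall >10% over the
    next), so detection sensitivity should be exactly 1 and the basal
    estimate should equal the configured baseline.
    """
    rng = np.random.default_rng(seed)
    onsets = [rng.uniform(35.0, 50.0)]
    while True:
        t = onsets[-1] + rng.uniform(50.0, 70.0)
        if t > 160.0:
            break
        onsets.append(t)
    amps = rng.uniform(0.4, 0.6, len(onsets))
    return SimParams(
        noise_sd=noise_sd,
        seed=seed,
        onset_times=tuple(onsets),
        amplitudes=tuple(amps),
        **overrides,
    )


@dataclass
class GroundTruth:
    """True pulse train and noiseless sampled curve behind a simulated series."""

    onset_times: np.ndarray
    amplitudes: np.ndarray
    noiseless_values: np.ndarray

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.noiseless_values = np.asarray(self.noiseless_values, dtype=float)
        if len(self.onset_times) != len(self.amplitudes):
            raise ParameterError("onset/amplitude lengths differ")


def _lognormal_mean_sd(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Draw log-normals with the requested arithmetic mean and SD."""
    if sd == 0:
        return np.full(size, mean)
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _draw_pulse_train(params: SimParams, rng: np.random.Generator):
    if params.onset_times is not None:
        return (
            np.asarray(params.onset_times, dtype=float),
            np.asarray(params.amplitudes, dtype=float),
        )
    if math.isinf(params.mean_ipi):
        return np.empty(0), np.empty(0)
    # Renewal process started at a uniform phase: first onset ~ U(0, mean_ipi),
    # subsequent gaps gamma(shape, mean_ipi/shape).
    onsets = []
    t = rng.uniform(0.0, params.mean_ipi)
    scale = params.mean_ipi / params.ipi_shape
    while t < params.duration:
        onsets.append(t)
        t += rng.gamma(params.ipi_shape, scale)
    onsets = np.asarray(onsets)
    amps = _lognormal_mean_sd(rng, params.amp_mean, params.amp_sd, len(onsets))
    return onsets, amps


def noiseless_curve(params: SimParams, onsets: np.ndarray, amps: np.ndarray,
                    times: Optional[np.ndarray] = None) -> np.ndarray:
    """Evaluate C(t) = baseline + sum a_i 2^(-(t-t_i)/half_life) on a grid."""
    t = params.grid if times is None else np.asarray(times, dtype=float)
    c = np.full(t.shape, params.baseline)
    for t0, a in zip(onsets, amps):
        dt = t - t0
        mask = dt >= 0
        c[mask] += a * np.exp2(-dt[mask] / params.half_life)
    return c


def simulate_lh_series(params: SimParams, animal_id: Optional[str] = None,
                       group: str = "sim") -> tuple[LHSeries, GroundTruth]:
    """Simulate one serial-bleed LH series plus its ground truth.

    Observed value = max(C(t) + eps, lod) with eps ~ N(0, noise_sd^2); the
    draw is fully determined by ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    onsets, amps = _draw_pulse_train(params, rng)
    clean = noiseless_curve(params, onsets, amps)
    if params.noise_sd > 0:
        observed = clean + rng.normal(0.0, params.noise_sd, clean.shape)
    else:
        observed = clean.copy()
    observed = np.maximum(observed, params.lod)
    series = LHSeries(
        animal_id=animal_id if animal_id is not None else f"sim{params.seed}",
        group=group,
        times=params.grid,
        values=observed,
        canonical=(params.interval == 10.0 and params.duration == 180.0),
    )
    return series, GroundTruth(onsets, amps, clean)


def simulate_cohort(params: SimParams, n_animals: int, group: str = "sim"
                    ) -> tuple[list[LHSeries], list[GroundTruth]]:
    """Simulate ``n_animals`` independent series; animal k uses a child seed
    derived from ``params.seed`` so the cohort is reproducible as a whole."""
    if n_animals < 1:
        raise ParameterError("n_animals must be >= 1")
    seeds = np.random.SeedSequence(params.seed).generate_state(n_animals)
    series, truths = [], []
    for k, s in enumerate(seeds):
        p = replace(params, seed=int(s) % (2**31))
        ser, gt = simulate_lh_series(p, animal_id=f"{group}{k + 1}", group=group)
        series.append(ser)
        truths.append(gt)
    return series, truths


# ---------------------------------------------------------------------------
# Estrous cycles
# ---------------------------------------------------------------------------

_CYCLE_ORDER = ("proestrus", "estrus", "metestrus", "diestrus")

# Mean dwell (days) per stage.  "regular" yields ~4.7-day cycles; "irregular"
# inflates the diestrus dwell, reproducing the longer-diestrus/shorter-estrus
# phenotype of the disrupted genotypes.
_REGULAR_DWELL = {"proestrus": 1.0, "estrus": 1.2, "metestrus": 1.0, "diestrus": 1.5}
_IRREGULAR_DIESTRUS_DWELL = 6.0


def simulate_cycle_log(
    n_days: int,
    regularity: str = "regular",
    seed: int = 0,
    animal_id: str = "sim1",
    diestrus_dwell_mean: Optional[float] = None,
) -> CycleLog:
    """Generate a daily estrous-stage log as a semi-Markov chain
    P -> E -> M -> D -> P with stage dwell times 1 + Poisson(mean - 1).

    ``diestrus_dwell_mean`` overrides the preset diestrus dwell; ``inf``
    produces an all-diestrus log (the degenerate acyclic limit).
    """
    if n_days < 4:
        raise ParameterError("n_days must be >= 4")
    if regularity not in ("regular", "irregular"):
        raise ParameterError(f"unknown regularity {regularity!r}")
    dwell = dict(_REGULAR_DWELL)
    if regularity == "irregular":
        dwell["diestrus"] = _IRREGULAR_DIESTRUS_DWELL
    if diestrus_dwell_mean is not None:
        if not diestrus_dwell_mean >= 1:
            raise ParameterError("diestrus_dwell_mean must be >= 1")
        dwell["diestrus"] = diestrus_dwell_mean

    rng = np.random.default_rng(seed)
    if math.isinf(dwell["diestrus"]):
        stages = ("diestrus",) * n_days
        return CycleLog(animal_id=animal_id, days=np.arange(1, n_days + 1), stages=stages)

    # Start in a stage drawn with probability proportional to its mean dwell
    # (the stationary occupancy of the semi-Markov chain).
    weights = np.array([dwell[s] for s in _CYCLE_ORDER])
    state = int(rng.choice(len(_CYCLE_ORDER), p=weights / weights.sum()))
    stages: list[str] = []
    while len(stages) < n_days:
        stage = _CYCLE_ORDER[state]
        d = 1 + rng.poisson(dwell[stage] - 1.0)
        stages.extend([stage] * d)
        state = (state + 1) % len(_CYCLE_ORDER)
    stages = stages[:n_days]
    return CycleLog(animal_id=animal_id, days=np.arange(1, n_days + 1), stages=tuple(stages))


# ---------------------------------------------------------------------------
# Surge cohorts
# ---------------------------------------------------------------------------


def simulate_surge_cohort(
    n_per_group: int,
    am_mean: float,
    surge_factor_by_group: Mapping[str, float],
    cv: float = 0.3,
    seed: int = 0,
) -> list[SurgeRecord]:
    """Simulate paired AM/PM LH samples for several groups.

    AM is log-normal with mean ``am_mean`` and coefficient of variation
    ``cv``; PM = AM x group surge factor x an independent log-normal
    multiplier with mean 1 and the same CV.  A factor near 1 emulates a
    blunted surge; a large factor the control evening rise.
    """
    if n_per_group < 1:
        raise ParameterError("n_per_group must be >= 1")
    if am_mean <= 0:
        raise ParameterError("am_mean must be > 0")
    if cv < 0:
        raise ParameterError("cv must be >= 0")
    for g, f in surge_factor_by_group.items():
        if f <= 0:
            raise ParameterError(f"surge factor for group {g!r} must be > 0")
    rng = np.random.default_rng(seed)
    out: list[SurgeRecord] = []
    for g, factor in surge_factor_by_group.items():
        am = _lognormal_mean_sd(rng, am_mean, cv * am_mean, n_per_group)
        mult = _lognormal_mean_sd(rng, 1.0, cv, n_per_group)
        pm = am * factor * mult
        for k in range(n_per_group):
            out.append(SurgeRecord(f"{g}{k + 1}", g, float(am[k]), float(pm[k])))
    return out


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------


def simulate_qpcr(
    true_fold_by_group: Mapping[str, float],
    base_ct: float = 26.0,
    ct_noise_sd: float = 0.25,
    n_per_group: int = 6,
    seed: int = 0,
    gene: str = "Pdyn",
    housekeeping_gene: str = "Hprt",
    housekeeping_ct: float = 20.0,
    n_replicates: int = 2,
) -> list[QpcrRecord]:
    """Simulate replicate Ct tables with known relative expression.

    A group whose true fold is f amplifies log2(f) cycles earlier, so its
    target Ct is ``base_ct - log2(f)`` plus noise; housekeeping Ct is a shared
    constant plus noise.  Replicates are drawn independently, emulating the
    run-in-duplicate design.
    """
    if n_per_group < 1:
        raise ParameterError("n_per_group must be >= 1")
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    if ct_noise_sd < 0:
        raise ParameterError("ct_noise_sd must be >= 0")
    for g, f in true_fold_by_group.items():
        if f <= 0:
            raise ParameterError(f"fold for group {g!r} must be > 0")
    rng = np.random.default_rng(seed)
    out: list[QpcrRecord] = []
    for g, fold in true_fold_by_group.items():
        target_mean = base_ct - math.log2(fold)
        for k in range(n_per_group):
            sample = f"{g}{k + 1}"
            t_reps = target_mean + rng.normal(0.0, ct_noise_sd, n_replicates) if ct_noise_sd > 0 \
                else np.full(n_replicates, target_mean)
            h_reps = housekeeping_ct + rng.normal(0.0, ct_noise_sd, n_replicates) if ct_noise_sd > 0 \
                else np.full(n_replicates, housekeeping_ct)
            out.append(QpcrRecord(sample, g, gene, tuple(t_reps), is_housekeeping=False))
            out.append(QpcrRecord(sample, g, housekeeping_gene, tuple(h_reps), is_housekeeping=True))
    return out
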