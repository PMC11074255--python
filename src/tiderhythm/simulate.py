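"""Synthetic activity and expression data with ground-truth rhythm labels.

The generators emulate the sampling design of a dual-zeitgeber chronobiology
experiment on a freshwater snail: time-course TPM expression sampled every
3.1 h for 49.6 h (17 timepoints) per population x entrainment group, and
hourly locomotor distance series recorded under constant darkness for
96 h (control) or 84 h (tidal-entrainment treatment).

Rhythmic genes follow

    TPM_g(t) = baseline_g * (1 + a * cos(2*pi*(t - phi_g)/T)) * noise,

with ``a`` chosen so the noiseless peak/trough ratio equals the configured
value (a = (r-1)/(r+1)), and multiplicative lognormal noise with a configured
coefficient of variation.  Pooled-sample sequencing in the emulated design
provides no replicate variance, so the noise CV has no in-data calibration
target; it is an explicit parameter.

All randomness is driven by explicit integer seeds through
``numpy.random.SeedSequence``.  Baselines, phases and noise use separate
child streams, so two configs that share a seed and gene count draw the same
baselines and noise — convenient for paired control/treatment simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ActivityTrace, ExpressionMatrix

__all__ = [
    "ConfigurationError",
    "ExpressionSimConfig",
    "ActivitySimConfig",
    "TideSchedule",
    "BEHAVIOUR_TIDE_SCHEDULE",
    "TRANSCRIPTOME_TIDE_SCHEDULE",
    "generate_expression_dataset",
    "generate_activity_dataset",
    "tide_level",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def peak_trough_to_relamp(ratio: float) -> float:
    """Relative cosine amplitude a with (1+a)/(1-a) = ratio."""
    if ratio < 1:
        raise ConfigurationError("peak/trough ratio must be >= 1")
    return (ratio - 1.0) / (ratio + 1.0)


@dataclass
class ExpressionSimConfig:
    """Configuration of the expression-matrix simulator.

    Defaults mirror the emulated design: 17 timepoints at 3.1 h spacing
    (49.6 h span), a 12.4 h circatidal and a 24.8 h circadian period.
    """

    n_genes: int
    seed: int
    n_timepoints: int = 17
    dt_hours: float = 3.1
    frac_circatidal: float = 0.0
    frac_circadian: float = 0.0
    period_circatidal_hours: float = 12.4
    period_circadian_hours: float = 24.8
    peak_trough_ratio: float = 2.0
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.0
    noise_cv: float = 0.1
    phase_distribution: str | float = "uniform"

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_timepoints < 2:
            raise ConfigurationError("n_timepoints must be >= 2")
        if self.dt_hours <= 0:
            raise ConfigurationError("dt_hours must be positive")
        if self.frac_circatidal < 0 or self.frac_circadian < 0:
            raise ConfigurationError("fractions must be nonnegative")
        if self.frac_circatidal + self.frac_circadian > 1 + 1e-12:
            raise ConfigurationError("frac_circatidal + frac_circadian must be <= 1")
        if self.peak_trough_ratio < 1:
            raise ConfigurationError("peak_trough_ratio must be >= 1")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be nonnegative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dt_hours


@dataclass
class ActivitySimConfig:
    """Configuration of the hourly locomotor-distance simulator.

    ``components`` lists (period_hours, relative_amplitude, phase_hours)
    cosine components superposed on a mean level; ``decay_rate`` applies an
    exponential envelope exp(-decay_rate * t) emulating the gradual decline
    in activity seen after tidal entrainment.
    """

    n_individuals: int
    seed: int
    duration_hours: int = 96
    components: tuple = ((24.0, 0.3, 0.0),)
    decay_rate: float = 0.0
    noise_sd: float = 0.0
    mean_distance: float = 10.0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if self.duration_hours < 72:
            raise ConfigurationError(
                "duration_hours must be >= 72 (the downstream periodogram window)"
            )
        if self.decay_rate < 0 or self.noise_sd < 0:
            raise ConfigurationError("decay_rate and noise_sd must be nonnegative")
        if self.mean_distance <= 0:
            raise ConfigurationError("mean_distance must be positive")
        for comp in self.components:
            if len(comp) != 3 or comp[0] <= 0:
                raise ConfigurationError(
                    "components must be (period_hours>0, relative_amplitude, phase_hours)"
                )


@dataclass(frozen=True)
class TideSchedule:
    """Timer-driven simulated tide: clock times (h) of drain and supply starts.

    The water level switches instantaneously at each timer event; the
    schedule is a phase reference, not a hydrodynamic model.
    """

    drain_start_times: tuple = (3.0, 15.0)
    supply_start_times: tuple = (9.0, 21.0)
    high_level_cm: float = 39.0
    low_level_cm: float = 24.0

    def __post_init__(self):
        events = self._events()
        kinds = [k for _, k in events]
        if len(set(t for t, _ in events)) != len(events):
            raise ConfigurationError("overlapping tide timer events")
        if any(a == b for a, b in zip(kinds, kinds[1:] + kinds[:1])):
            raise ConfigurationError("drain and supply events must alternate")

    def _events(self):
        events = [(t % 24.0, "drain") for t in self.drain_start_times]
        events += [(t % 24.0, "supply") for t in self.supply_start_times]
        return sorted(events)


#: schedule used for the behavioural entrainment simulation
BEHAVIOUR_TIDE_SCHEDULE = TideSchedule((3.0, 15.0), (9.0, 21.0))
#: schedule used for the transcriptome entrainment simulation
TRANSCRIPTOME_TIDE_SCHEDULE = TideSchedule((5.0, 17.0), (11.0, 23.0))


def tide_level(schedule: TideSchedule, t: float) -> str:
    """Water level ("high"/"low") at clock time ``t`` hours.

    High between a supply start and the next drain start, low otherwise;
    an event takes effect at its start time.
    """
    tc = t % 24.0
    events = schedule._events()
    last_kind = None
    for time, kind in events:
        if time <= tc:
            last_kind = kind
    if last_kind is None:  # before the first event of the day: wrap around
        last_kind = events[-1][1]
    return "high" if last_kind == "supply" else "low"


def _gene_ids(n: int) -> np.ndarray:
    width = max(5, len(str(n)))
    return np.array([f"g{i:0{width}d}" for i in range(n)])


def generate_expression_dataset(config: ExpressionSimConfig,
                                population: str = "", group: str = ""):
    """Simulate a TPM matrix plus an aligned ground-truth table.

    Genes are laid out circatidal first, then circadian, then arrhythmic.
    A configured peak/trough ratio of exactly 1 yields zero amplitude, and
    such genes are labelled arrhythmic in the truth table.

    Returns
    -------
    (ExpressionMatrix, pandas.DataFrame)
        Truth columns: unit_id, rhythm_class, true_period_hours,
        true_phase_hours, true_peak_trough_ratio.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_base, rng_phase, rng_noise = (np.random.default_rng(c) for c in ss.spawn(3))

    n = cfg.n_genes
    n_tid = int(round(cfg.frac_circatidal * n))
    n_cir = int(round(cfg.frac_circadian * n))
    if n_tid + n_cir > n:
        raise ConfigurationError("rounded rhythmic gene counts exceed n_genes")
    ids = _gene_ids(n)
    t = cfg.times

    baseline = rng_base.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n)
    periods = np.full(n, np.nan)
    periods[:n_tid] = cfg.period_circatidal_hours
    periods[n_tid:n_tid + n_cir] = cfg.period_circadian_hours
    if cfg.phase_distribution == "uniform":
        phases = rng_phase.uniform(0.0, 1.0, size=n) * np.where(
            np.isnan(periods), 1.0, periods)
    else:
        phases = np.full(n, float(cfg.phase_distribution))

    a = peak_trough_to_relamp(cfg.peak_trough_ratio)
    signal = np.ones((n, len(t)))
    rhythmic = ~np.isnan(periods) if a > 0 else np.zeros(n, dtype=bool)
    if rhythmic.any():
        ph = phases[rhythmic, None]
        T = periods[rhythmic, None]
        signal[rhythmic] = 1.0 + a * np.cos(2.0 * np.pi * (t[None, :] - ph) / T)

    if cfg.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + cfg.noise_cv**2))
        noise = rng_noise.lognormal(-0.5 * sigma**2, sigma, size=(n, len(t)))
    else:
        noise = np.ones((n, len(t)))

    tpm = baseline[:, None] * signal * noise
    matrix = ExpressionMatrix(
        pd.DataFrame(tpm, index=pd.Index(ids, name="gene_id"), columns=t),
        population=population, group=group,
    )
    classes = np.where(
        rhythmic & (periods == cfg.period_circatidal_hours), "circatidal",
        np.where(rhythmic & (periods == cfg.period_circadian_hours),
                 "circadian", "arrhythmic"),
    )
    truth = pd.DataFrame({
        "unit_id": ids,
        "rhythm_class": classes,
        "true_period_hours": np.where(rhythmic, periods, np.nan),
        "true_phase_hours": np.where(rhythmic, phases, np.nan),
        "true_peak_trough_ratio": np.where(rhythmic, cfg.peak_trough_ratio, np.nan),
    })
    return matrix, truth


def generate_activity_dataset(config: ActivitySimConfig,
                              population: str = "", group: str = ""):
    """Simulate hourly locomotor-distance traces plus a truth table.

    Each trace is mean_distance * (1 + sum of cosine components) *
    exp(-decay_rate * t) plus additive Gaussian noise, clipped at zero.
    An individual's truth class follows its largest-amplitude component:
    period in [20, 28] h -> circadian, in [10.4, 14.4] h -> circatidal,
    otherwise (or no components) arrhythmic.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    t = np.arange(cfg.duration_hours, dtype=float)
    base = np.ones_like(t)
    for period, amp, phase in cfg.components:
        base = base + amp * np.cos(2.0 * np.pi * (t - phase) / period)
    base = cfg.mean_distance * base * np.exp(-cfg.decay_rate * t)

    if cfg.components:
        period, amp, phase = max(cfg.components, key=lambda c: abs(c[1]))
        if 20.0 <= period <= 28.0 and amp != 0:
            klass, true_period, true_phase = "circadian", period, phase
        elif 10.4 <= period <= 14.4 and amp != 0:
            klass, true_period, true_phase = "circatidal", period, phase
        else:
            klass, true_period, true_phase = "arrhythmic", np.nan, np.nan
    else:
        klass, true_period, true_phase = "arrhythmic", np.nan, np.nan

    traces, rows = [], []
    for i in range(cfg.n_individuals):
        noise = rng.normal(0.0, cfg.noise_sd, size=len(t)) if cfg.noise_sd > 0 else 0.0
        dist = np.clip(base + noise, 0.0, None)
        ind = f"ind{i:03d}"
        traces.append(ActivityTrace(ind, dist, population=population, group=group))
        rows.append({
            "unit_id": ind,
            "rhythm_class": klass,
            "true_period_hours": true_period,
            "true_phase_hours": true_phase,
            "true_peak_trough_ratio": np.nan,
        })
    return traces, pd.DataFrame(rows)
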