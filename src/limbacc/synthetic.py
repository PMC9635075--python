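"""Synthetic multi-night accelerometer cohorts with known impairment.

The generator emulates the statistical structure the analysis assumes for a
chronic spinal-cord-injury cohort wearing ankle + wrist accelerometers during
sleep. Each participant receives a ground-truth phenotype — lower-extremity
motor score (LEMS, 0-50), lower-limb light-touch score (0-20) and a
spasticity category — drawn from mixtures shaped like the study population
(a motor-complete subgroup with LEMS 0, an incomplete subgroup centred near
LEMS 27). The phenotype maps monotonically onto generative parameters:

* ``movement_rate`` (events/h), ``amplitude_scale`` (g) and
  ``rotation_speed_scale`` (deg/s) increase with strength — stronger
  participants reposition more often, harder and faster;
* ``timing_cv`` (coefficient of variation of inter-movement intervals)
  decreases with light-touch sensation — intact sensation cues regularly
  timed repositioning;
* ``spasm_rate`` is 0 / 4 / 12 bursts per hour for none / mild / moderate
  spasticity, and spasms are short sinusoidal packets in the clonus band;
* ``plm_propensity`` governs how many periodic-limb-movement trains occur.

A night is a unit-gravity baseline at a random orientation plus white sensor
noise plus inserted events: band-limited repositioning bursts, smooth
gravity-vector rolls, PLM trains (>= 4 short bursts 5-90 s apart) and spasm
bursts. The wrist mirrors ankle event times with independent amplitude and
40% random omission. Every night returns its ground-truth event log.

All randomness derives from a single master seed through counter-based
``numpy.random.SeedSequence`` splitting, so outputs are reproducible
independent of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import ConfigurationError
from .ingest import NightMeta
from .outcomes import ImpairmentOutcomes
from .types import ANKLES, PLACEMENTS, AccelTrace, NightRecord

SPASTICITY_CATEGORIES = ("none", "mild", "moderate")


@dataclass(frozen=True)
class PhenotypeMaps:
    """Coefficients of the phenotype -> generative-parameter mappings."""

    rate_base: float = 6.0  # events/h at LEMS 0
    rate_slope: float = 0.30  # events/h per LEMS point
    amp_base: float = 0.12  # g
    amp_slope: float = 0.010  # g per LEMS point
    rot_base: float = 20.0  # deg/s
    rot_slope: float = 1.6  # deg/s per LEMS point
    cv_base: float = 1.1
    cv_slope: float = 0.04  # per light-touch point
    cv_floor: float = 0.25
    plm_base: float = 0.12
    plm_slope: float = 0.006  # per LEMS point
    spasm_rates: tuple = (0.0, 4.0, 12.0)  # events/h for none/mild/moderate
    spasm_freq_hz: float = 6.0  # clonus band 5-8 Hz


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-generation configuration; the seed fully determines the output."""

    n_participants: int = 200
    nights_per_participant: int = 3
    sampling_rate_hz: float = 30.0
    #: simulated consolidated-sleep window per night; real nights are longer,
    #: but every rate-like quantity is per-hour so the window length only
    #: sets how much evidence each night contributes
    night_duration_s: float = 7200.0
    #: uniform fractional jitter of the night duration (makes time asleep vary)
    night_duration_jitter: float = 0.15
    noise_sd_g: float = 0.008
    seed: int = 0
    complete_fraction: float = 0.25
    typical_fraction: float = 1.0
    n_covariates: int = 24
    maps: PhenotypeMaps = field(default_factory=PhenotypeMaps)
    # study-population mixture shapes (motor incomplete / complete)
    lems_mean: float = 26.9
    lems_sd: float = 15.0
    lems_range: tuple = (2, 49)
    lt_complete_mean: float = 3.8
    lt_sd: float = 5.0
    lt_slope: float = 0.26  # light-touch drift per LEMS point
    spasticity_probs: tuple = (0.395, 0.368, 0.237)

    def validate(self):
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        if not 1 <= self.nights_per_participant <= 5:
            raise ConfigurationError("nights_per_participant must be in 1-5")
        if self.sampling_rate_hz <= 2 * self.maps.spasm_freq_hz:
            raise ConfigurationError(
                "sampling rate must exceed twice the highest simulated spasm frequency"
            )
        if self.night_duration_s <= 0 or self.noise_sd_g < 0:
            raise ConfigurationError("night duration and noise must be positive")
        if not 0 <= self.complete_fraction <= 1:
            raise ConfigurationError("complete_fraction must be in [0, 1]")


@dataclass
class SyntheticPhenotype:
    """Ground-truth impairment and the derived generative parameters."""

    participant_id: str
    participant_index: int
    lems_true: int
    light_touch_true: int
    spasticity_true: str
    movement_rate: float = 0.0
    amplitude_scale: float = 0.0
    rotation_speed_scale: float = 0.0
    timing_cv: float = 0.0
    plm_propensity: float = 0.0
    spasm_rate: float = 0.0
    spasm_freq_hz: float = 6.0


@dataclass
class SimEvent:
    """One inserted ground-truth event."""

    kind: str  # reposition | roll | plm | spasm
    onset_s: float
    duration_s: float
    limbs: tuple  # ankle placements involved
    amplitude_g: float
    freq_hz: float | None = None
    roll_angle_deg: float = 0.0
    train_id: int = -1


def _derive_parameters(lems: int, lt: int, spasticity: str, maps: PhenotypeMaps):
    idx = SPASTICITY_CATEGORIES.index(spasticity)
    return {
        "movement_rate": maps.rate_base + maps.rate_slope * lems,
        "amplitude_scale": maps.amp_base + maps.amp_slope * lems,
        "rotation_speed_scale": maps.rot_base + maps.rot_slope * lems,
        "timing_cv": max(maps.cv_floor, maps.cv_base - maps.cv_slope * lt),
        "plm_propensity": maps.plm_base + maps.plm_slope * lems,
        "spasm_rate": maps.spasm_rates[idx],
        "spasm_freq_hz": maps.spasm_freq_hz,
    }


def expected_lems_mean(config: CohortConfig) -> float:
    """Mean of the configured LEMS mixture (motor complete mass at 0)."""
    lo, hi = config.lems_range
    a = (lo - config.lems_mean) / config.lems_sd
    b = (hi - config.lems_mean) / config.lems_sd
    incomplete_mean = stats.truncnorm.mean(a, b, loc=config.lems_mean, scale=config.lems_sd)
    return (1.0 - config.complete_fraction) * float(incomplete_mean)


def _participant_rng(config: CohortConfig, index: int, *stream) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([config.seed, index, *stream]))
    )


def sample_phenotype(config: CohortConfig, participant_index: int) -> SyntheticPhenotype:
    """Draw one participant's ground-truth phenotype (deterministic in seed+index)."""
    config.validate()
    if participant_index >= config.n_participants:
        raise ConfigurationError("participant_index out of range")
    rng = _participant_rng(config, participant_index, 0)
    complete = rng.random() < config.complete_fraction
    if complete:
        lems = 0
    else:
        lo, hi = config.lems_range
        a = (lo - config.lems_mean) / config.lems_sd
        b = (hi - config.lems_mean) / config.lems_sd
        lems = int(round(stats.truncnorm.rvs(
            a, b, loc=config.lems_mean, scale=config.lems_sd, random_state=rng
        )))
    lt_mean = config.lt_complete_mean + config.lt_slope * lems
    a = (0 - lt_mean) / config.lt_sd
    b = (20 - lt_mean) / config.lt_sd
    lt = int(round(stats.truncnorm.rvs(a, b, loc=lt_mean, scale=config.lt_sd, random_state=rng)))
    spasticity = SPASTICITY_CATEGORIES[
        rng.choice(3, p=np.asarray(config.spasticity_probs) / sum(config.spasticity_probs))
    ]
    params = _derive_parameters(lems, lt, spasticity, config.maps)
    return SyntheticPhenotype(
        participant_id=f"P{participant_index:04d}",
        participant_index=participant_index,
        lems_true=lems,
        light_touch_true=lt,
        spasticity_true=spasticity,
        **params,
    )


# ---------------------------------------------------------------------------
# event scheduling (cheap; no signal synthesis)
# ---------------------------------------------------------------------------

def night_duration(
    phenotype: SyntheticPhenotype, night_index: int, config: CohortConfig
) -> float:
    """This night's actual duration (base duration with uniform jitter)."""
    rng = _participant_rng(config, phenotype.participant_index, 6, night_index)
    j = config.night_duration_jitter
    return config.night_duration_s * (1.0 + j * (2.0 * rng.random() - 1.0))


def schedule_events(
    phenotype: SyntheticPhenotype,
    night_index: int,
    config: CohortConfig,
    duration_s: float | None = None,
) -> list[SimEvent]:
    """Draw the ground-truth event schedule for one night, sorted by onset."""
    rng = _participant_rng(config, phenotype.participant_index, 1, night_index)
    dur = duration_s if duration_s is not None else night_duration(phenotype, night_index, config)
    hours = dur / 3600.0
    events: list[SimEvent] = []
    margin = 30.0

    # repositioning / roll events: gamma-renewal onsets with the phenotype's CV
    mean_gap = 3600.0 / max(phenotype.movement_rate, 1e-9)
    cv = phenotype.timing_cv
    k, theta = 1.0 / cv**2, mean_gap * cv**2
    t = float(rng.gamma(k, theta))
    while phenotype.movement_rate > 0 and t < dur - margin:
        duration = float(rng.uniform(1.0, 8.0))
        amp = phenotype.amplitude_scale * float(rng.lognormal(0.0, 0.3))
        is_roll = rng.random() < 0.25
        if is_roll:
            speed = phenotype.rotation_speed_scale * float(rng.lognormal(0.0, 0.2))
            angle = min(speed * duration, 150.0)
            events.append(
                SimEvent("roll", t, duration, ANKLES, amp * 0.5, roll_angle_deg=angle)
            )
        else:
            u = rng.random()
            limbs = ANKLES if u < 0.4 else (("left_ankle",) if u < 0.7 else ("right_ankle",))
            events.append(SimEvent("reposition", t, duration, limbs, amp))
        t += float(rng.gamma(k, theta))

    # periodic-limb-movement trains
    n_trains = int(rng.poisson(1.2 * phenotype.plm_propensity * hours))
    for train in range(n_trains):
        n_bursts = 4 + int(rng.poisson(4))
        onset = float(rng.uniform(margin, max(margin + 1, dur - margin - n_bursts * 45.0)))
        limb = ("left_ankle",) if rng.random() < 0.5 else ("right_ankle",)
        for _ in range(n_bursts):
            if onset >= dur - margin:
                break
            duration = float(rng.uniform(0.5, 3.0))
            amp = max(0.08, 0.5 * phenotype.amplitude_scale) * float(rng.lognormal(0.0, 0.2))
            events.append(SimEvent("plm", onset, duration, limb, amp, train_id=train))
            onset += float(rng.uniform(10.0, 40.0))

    # spasm bursts: short sinusoidal packets in the clonus band
    n_spasms = int(rng.poisson(phenotype.spasm_rate * hours))
    for _ in range(n_spasms):
        onset = float(rng.uniform(margin, dur - margin))
        duration = float(rng.uniform(0.5, 2.0))
        amp = float(rng.uniform(0.10, 0.25))
        limb = ("left_ankle",) if rng.random() < 0.5 else ("right_ankle",)
        events.append(
            SimEvent("spasm", onset, duration, limb, amp, freq_hz=phenotype.spasm_freq_hz)
        )

    events.sort(key=lambda e: e.onset_s)
    return events


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def bandlimited_burst(n: int, fs: float, rng: np.random.Generator, band=(0.5, 3.0)) -> np.ndarray:
    """Hann-windowed band-limited noise burst, peak vector magnitude 1."""
    pad = max(int(fs), n)
    noise = rng.normal(size=(n + 2 * pad, 3))
    hi = min(band[1], 0.45 * fs)
    sos = signal.butter(2, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    shaped = signal.sosfiltfilt(sos, noise, axis=0)[pad : pad + n]
    shaped *= signal.windows.hann(n)[:, None]
    peak = np.max(np.linalg.norm(shaped, axis=1))
    return shaped / peak if peak > 0 else shaped


def sinusoid_burst(n: int, fs: float, freq_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Hann-windowed sinusoidal packet along a random direction, peak vm 1."""
    t = np.arange(n) / fs
    carrier = np.sin(2 * np.pi * freq_hz * t + rng.uniform(0, 2 * np.pi))
    burst = np.outer(carrier * signal.windows.hann(n), random_unit_vector(rng))
    peak = np.max(np.linalg.norm(burst, axis=1))
    return burst / peak if peak > 0 else burst


def _slerp(g0: np.ndarray, g1: np.ndarray, u: np.ndarray) -> np.ndarray:
    dot = float(np.clip(np.dot(g0, g1), -1.0, 1.0))
    theta = math.acos(dot)
    if theta < 1e-9:
        return np.outer(np.ones_like(u), g0)
    return (
        np.outer(np.sin((1 - u) * theta), g0) + np.outer(np.sin(u * theta), g1)
    ) / math.sin(theta)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (
        v * math.cos(angle_rad)
        + np.cross(axis, v) * math.sin(angle_rad)
        + axis * np.dot(axis, v) * (1 - math.cos(angle_rad))
    )


def _synthesize_trace(
    placement: str,
    events: list[SimEvent],
    config: CohortConfig,
    rng: np.random.Generator,
    start_time: pd.Timestamp,
    duration_s: float,
) -> AccelTrace:
    fs = config.sampling_rate_hz
    n = int(round(duration_s * fs))
    data = rng.normal(0.0, config.noise_sd_g, size=(n, 3))

    # piecewise gravity baseline: constant orientation, rotated smoothly by rolls
    g = random_unit_vector(rng)
    cursor = 0
    for ev in events:
        i0 = int(ev.onset_s * fs)
        i1 = min(n, i0 + max(2, int(ev.duration_s * fs)))
        if ev.kind == "roll" and i0 > cursor:
            axis = random_unit_vector(rng)
            g_new = _rotate_about(g, axis, math.radians(ev.roll_angle_deg))
            g_new /= np.linalg.norm(g_new)
            data[cursor:i0] += g
            data[i0:i1] += _slerp(g, g_new, np.linspace(0.0, 1.0, i1 - i0))
            g = g_new
            cursor = i1
    data[cursor:] += g

    # additive movement bursts
    for ev in events:
        i0 = int(ev.onset_s * fs)
        i1 = min(n, i0 + max(4, int(ev.duration_s * fs)))
        m = i1 - i0
        if m <= 0:
            continue
        if ev.kind == "spasm":
            burst = sinusoid_burst(m, fs, ev.freq_hz, rng)
        else:
            burst = bandlimited_burst(m, fs, rng)
        data[i0:i1] += ev.amplitude_g * burst

    return AccelTrace(placement=placement, sampling_rate_hz=fs, start_time=start_time, data=data)


def _wrist_events(events: list[SimEvent], rng: np.random.Generator) -> list[SimEvent]:
    """Wrist mirrors ankle event times; independent amplitude, 40% omission."""
    mirrored = []
    for ev in events:
        if rng.random() < 0.4:
            continue
        mirrored.append(
            replace(
                ev,
                limbs=("wrist",),
                amplitude_g=max(0.06, ev.amplitude_g * float(rng.lognormal(-0.5, 0.3))),
                roll_angle_deg=ev.roll_angle_deg,
            )
        )
    return mirrored


def generate_night(
    phenotype: SyntheticPhenotype, night_index: int, config: CohortConfig
):
    """Synthesize one night: traces per placement, metadata, ground-truth events."""
    config.validate()
    dur = night_duration(phenotype, night_index, config)
    events = schedule_events(phenotype, night_index, config, duration_s=dur)
    start_time = pd.Timestamp("2024-01-01 23:00:00") + pd.Timedelta(days=night_index)
    traces = {}
    for k, placement in enumerate(PLACEMENTS):
        rng = _participant_rng(config, phenotype.participant_index, 2, night_index, k)
        if placement == "wrist":
            placement_events = _wrist_events(events, rng)
        else:
            placement_events = [e for e in events if placement in e.limbs]
        traces[placement] = _synthesize_trace(
            placement, placement_events, config, rng, start_time, dur
        )

    rng_meta = _participant_rng(config, phenotype.participant_index, 3, night_index)
    typical = bool(rng_meta.random() < config.typical_fraction)
    meta = NightMeta(
        participant_id=phenotype.participant_id,
        night_index=night_index,
        typical=typical,
        sleep_window=(start_time, traces["left_ankle"].end_time),
        covariates={},
    )
    return traces, meta, events


def make_outcomes(phenotype: SyntheticPhenotype, rng: np.random.Generator) -> ImpairmentOutcomes:
    """Clinical outcome record consistent with the ground-truth phenotype."""
    cat = phenotype.spasticity_true
    if cat == "none":
        mas = ["0", "0", "0", "0"]
    elif cat == "mild":
        mas = [str(rng.choice(["1", "1+"])) for _ in range(rng.integers(1, 5))]
        mas += ["0"] * (4 - len(mas))
    else:
        n_mod = int(rng.integers(1, 3))
        mas = [str(rng.choice(["2", "3"])) for _ in range(n_mod)]
        mas += [str(rng.choice(["0", "1", "1+"])) for _ in range(4 - n_mod)]
    rng.shuffle(mas)
    return ImpairmentOutcomes(
        participant_id=phenotype.participant_id,
        lems=phenotype.lems_true,
        light_touch=phenotype.light_touch_true,
        mas_scores=tuple(mas),
    )


def make_covariates(phenotype: SyntheticPhenotype, config: CohortConfig) -> dict:
    """Generic questionnaire covariates: demographics plus mostly-noise scales.

    A few columns carry weak outcome information (as pain and sleep-quality
    scales plausibly would); the rest are independent noise.
    """
    rng = _participant_rng(config, phenotype.participant_index, 4)
    cov = {
        "cov_age": float(np.clip(rng.normal(54, 11), 20, 80)),
        "cov_bmi": float(np.clip(rng.normal(27, 5), 17, 45)),
        "cov_years_since_injury": float(np.clip(rng.normal(18, 12), 1, 50)),
        "cov_sleep_quality": float(
            np.clip(rng.normal(10 + 0.05 * phenotype.lems_true, 3), 0, 21)
        ),
        "cov_pain": float(np.clip(rng.normal(5 - 0.03 * phenotype.lems_true, 2), 0, 10)),
    }
    for i in range(len(cov), config.n_covariates):
        cov[f"cov_q{i + 1:02d}"] = float(rng.normal())
    return cov


@dataclass
class CohortBundle:
    """A fully materialized synthetic cohort (small-n use; nights in memory)."""

    config: CohortConfig
    phenotypes: list
    outcomes: list
    nights: list  # NightRecord
    metas: list  # NightMeta
    event_logs: dict  # (participant_id, night_index) -> list[SimEvent]


def iter_participants(config: CohortConfig):
    """Stream participants: yields (phenotype, outcomes, covariates, night iterator).

    The night iterator lazily yields ``(NightRecord, NightMeta, events)`` so
    large cohorts never hold more than one night in memory.
    """
    config.validate()
    for idx in range(config.n_participants):
        phen = sample_phenotype(config, idx)
        rng_out = _participant_rng(config, idx, 5)
        outcome = make_outcomes(phen, rng_out)
        cov = make_covariates(phen, config)

        def nights(phen=phen, cov=cov):
            for night_index in range(config.nights_per_participant):
                traces, meta, events = generate_night(phen, night_index, config)
                meta.covariates = dict(cov)
                record = NightRecord(
                    participant_id=phen.participant_id,
                    night_index=night_index,
                    traces=traces,
                    typical=meta.typical,
                    reported_sleep_window=meta.sleep_window,
                    covariates=dict(cov),
                )
                yield record, meta, events

        yield phen, outcome, cov, nights()


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Materialize the whole cohort (use :func:`iter_participants` for large n)."""
    phenotypes, outcomes, nights, metas = [], [], [], []
    event_logs = {}
    for phen, outcome, cov, night_iter in iter_participants(config):
        phenotypes.append(phen)
        outcomes.append(outcome)
        for record, meta, events in night_iter:
            nights.append(record)
            metas.append(meta)
            event_logs[(phen.participant_id, record.night_index)] = events
    return CohortBundle(
        config=config,
        phenotypes=phenotypes,
        outcomes=outcomes,
        nights=nights,
        metas=metas,
        event_logs=event_logs,
    )
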