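"""Synthetic two-cohort behavioural dataset generator.

The study's raw movement recordings are not publicly deposited, so every
downstream stage is exercised on synthetic cohorts that emulate the recording
conventions and the session structure: per participant, three mirror-game
sessions of [Solo, 3 x Leader-Follower, Solo] one-minute games (session 1 is
a familiarisation block, generated but excluded from analysis) plus six TMT
click logs (parts A and B, three repetitions each).  Sensor quirks are
emulated: variable sampling rate (90-140 Hz Solo, 40-70 Hz leader-follower,
with +/-10% inter-sample jitter), and position saturation at the +/-0.5 rails.

Cohort differences are configurable per group:

* Solo motion is a narrowband stochastic oscillation -- an amplitude- and
  frequency-wandering sinusoid around a participant-specific characteristic
  frequency (the study gives no distributional account of real solo motion;
  this is a stand-in, not a claim about the population).
* The follower trace is the leader delayed by a participant-specific lag plus
  low-passed (2 Hz) tracking noise, occasionally overshooting into the rails.
* TMT inter-on-target-click times are log-normal around a participant-specific
  median, with off-target clicks inserted at a configurable rate.

Within the clinical cohort, a CAARMS subdivision applies a multiplier to the
*mirror-game* effect parameters only (0.5 for CAARMS = 0, 1.0 for CAARMS > 0)
while TMT parameters are shared, emulating the study's observed pattern of
graded movement effects but flat TMT effects across CAARMS strata.

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import InvalidArgumentError
from .records import (
    CohortDataset,
    MGTrial,
    ParticipantRecord,
    POSITION_BOUND,
    SampledSeries,
    TMTClickLog,
)

GAME_DURATION_S = 60.0
DENSE_RATE_HZ = 200.0  # internal rate before sensor-rate resampling
N_SESSIONS = 3
LF_PER_SESSION = 3
N_TMT_REPETITIONS = 3


# --------------------------------------------------------------------------
# Parameter containers


@dataclass(frozen=True)
class LeaderPatternParams:
    """Computer-generated leader trajectory: a sum of random sinusoids."""

    n_components: int = 6
    band_hz: tuple[float, float] = (0.1, 0.75)
    amplitude: float = 0.45


@dataclass(frozen=True)
class SoloParams:
    """Free horizontal motion model for one group."""

    characteristic_freq_hz: float = 0.7
    freq_jitter_hz: float = 0.15  # between-participant sd of the characteristic freq
    amplitude: float = 0.40  # mean peak amplitude, arbitrary units
    amplitude_sd: float = 0.06  # between-participant sd (draws > 0.5 saturate)
    freq_wander_hz: float = 0.06  # within-trial instantaneous-frequency wander sd
    noise_sd: float = 0.004  # sensor measurement noise


@dataclass(frozen=True)
class FollowerParams:
    """Leader-tracking model for one group."""

    lag_s: float = 0.12
    lag_sd_s: float = 0.04  # between-participant sd
    noise_sd: float = 0.015  # tracking noise sd (position units)
    noise_sd_sd: float = 0.006  # between-participant sd
    noise_cutoff_hz: float = 2.0  # tracking noise respects human-motion bandwidth
    overshoot_prob: float = 0.15  # per-trial chance of gain overshoot into the rails
    overshoot_gain: float = 1.12


@dataclass(frozen=True)
class TMTParams:
    """Click-timing model for one group."""

    median_ict_ms: float = 900.0
    dispersion: float = 0.30  # within-participant log-sd of intervals
    between_sd: float = 0.25  # between-participant log-sd of the median
    error_rate: float = 0.04  # off-target click insertion prob per interval


@dataclass(frozen=True)
class GroupParams:
    solo: SoloParams = field(default_factory=SoloParams)
    follower: FollowerParams = field(default_factory=FollowerParams)
    tmt: TMTParams = field(default_factory=TMTParams)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full recipe for a two-cohort dataset; a pure function of itself + seed."""

    n_per_cohort: int = 32
    seed: int = 0
    leader: LeaderPatternParams = field(default_factory=LeaderPatternParams)
    cc: GroupParams = field(default_factory=GroupParams)
    su: GroupParams = field(default_factory=GroupParams)
    solo_rate_range_hz: tuple[float, float] = (90.0, 140.0)
    lf_rate_range_hz: tuple[float, float] = (40.0, 70.0)
    rate_jitter: float = 0.10
    caarms_positive_fraction: float = 0.5
    caarms_zero_multiplier: float = 0.5
    duration_s: float = GAME_DURATION_S

    def __post_init__(self) -> None:
        if self.n_per_cohort <= 0:
            raise InvalidArgumentError("n_per_cohort must be positive")
        if not 0 <= self.caarms_positive_fraction <= 1:
            raise InvalidArgumentError("caarms fraction must be in [0, 1]")
        if self.duration_s <= 0:
            raise InvalidArgumentError("duration must be positive")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def study_config(n_per_cohort: int = 32, seed: int = 0) -> SyntheticConfig:
    """Default study conditions: clinical cohort slower on TMT, tracking with
    longer lag and more noise, solo motion at a shifted characteristic
    frequency -- magnitudes chosen to land the measured Cliff's deltas in the
    large-for-TMT / moderate-for-MG regime the study reports."""
    su = GroupParams(
        solo=SoloParams(characteristic_freq_hz=0.95, amplitude=0.44),
        follower=FollowerParams(lag_s=0.26, lag_sd_s=0.06, noise_sd=0.045,
                                noise_sd_sd=0.012, overshoot_prob=0.25),
        tmt=TMTParams(median_ict_ms=1400.0, error_rate=0.10),
    )
    return SyntheticConfig(n_per_cohort=n_per_cohort, seed=seed, su=su)


def null_config(n_per_cohort: int = 32, seed: int = 0) -> SyntheticConfig:
    """Both cohorts drawn from identical distributions (no true effect)."""
    return SyntheticConfig(n_per_cohort=n_per_cohort, seed=seed)


# --------------------------------------------------------------------------
# Elementary generators


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_leader_pattern(
    duration_s: float, params: LeaderPatternParams, seed
) -> SampledSeries:
    """Smooth bounded leader trajectory: sum of ``n_components`` sinusoids
    with random frequencies in the configured band and random phases,
    amplitude-normalised to ``params.amplitude``."""
    if duration_s <= 0:
        raise InvalidArgumentError("duration must be positive")
    rng = _rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / DENSE_RATE_HZ)
    freqs = rng.uniform(*params.band_hz, size=params.n_components)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=params.n_components)
    amps = rng.uniform(0.5, 1.0, size=params.n_components)
    x = (amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None])).sum(0)
    x *= params.amplitude / np.max(np.abs(x))
    return SampledSeries(t, x, DENSE_RATE_HZ)


def _ou_process(rng: np.random.Generator, n: int, dt: float, tau_s: float, sd: float
                ) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path (mean 0, sd ``sd``, timescale ``tau_s``)."""
    a = np.exp(-dt / tau_s)
    b = sd * np.sqrt(1.0 - a * a)
    drive = np.empty(n)
    drive[0] = rng.normal(0.0, sd)
    drive[1:] = b * rng.normal(0.0, 1.0, size=n - 1)
    # x[i] = a * x[i-1] + drive[i] as an IIR filter
    return sps.lfilter([1.0], [1.0, -a], drive)


def _sensor_timestamps(
    rng: np.random.Generator, duration_s: float, rate_range: tuple[float, float],
    jitter: float,
) -> np.ndarray:
    """Variable-rate sensor timestamps: per-trial mean rate uniform in the
    band, inter-sample intervals jittered by +/-``jitter``."""
    rate = rng.uniform(*rate_range)
    n_guess = int(duration_s * rate * 1.2) + 8
    dts = (1.0 / rate) * (1.0 + rng.uniform(-jitter, jitter, size=n_guess))
    t = np.concatenate([[0.0], np.cumsum(dts)])
    return t[t <= duration_s]


def generate_solo(params: SoloParams, duration_s: float, seed,
                  rate_range: tuple[float, float] = (90.0, 140.0),
                  rate_jitter: float = 0.10) -> SampledSeries:
    """One Solo game: narrowband stochastic oscillation at the participant's
    characteristic frequency, observed through the variable-rate sensor."""
    if not 0.0 < params.characteristic_freq_hz < 5.0:
        raise InvalidArgumentError("characteristic frequency must be in (0, 5) Hz")
    if duration_s <= 0:
        raise InvalidArgumentError("duration must be positive")
    rng = _rng(seed)
    dt = 1.0 / DENSE_RATE_HZ
    t_dense = np.arange(0.0, duration_s + dt, dt)
    n = len(t_dense)
    f_inst = np.maximum(
        params.characteristic_freq_hz + _ou_process(rng, n, dt, 8.0, params.freq_wander_hz),
        0.02,
    )
    phase = 2.0 * np.pi * np.cumsum(f_inst) * dt + rng.uniform(0.0, 2.0 * np.pi)
    amp = params.amplitude * (1.0 + 0.15 * _ou_process(rng, n, dt, 12.0, 1.0))
    x_dense = np.clip(amp * np.sin(phase), -POSITION_BOUND, POSITION_BOUND)
    t = _sensor_timestamps(rng, duration_s, rate_range, rate_jitter)
    x = np.interp(t, t_dense, x_dense)
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, size=len(x))
    x = np.clip(x, -POSITION_BOUND, POSITION_BOUND)
    return SampledSeries(t, x, np.mean(rate_range))


def generate_follower(leader: SampledSeries, params: FollowerParams, seed,
                      rate_range: tuple[float, float] = (40.0, 70.0),
                      rate_jitter: float = 0.10) -> tuple[SampledSeries, SampledSeries]:
    """One Leader-Follower game.

    Returns ``(leader_obs, follower_obs)`` on a shared variable-rate
    timestamp grid (as logged by the game loop): the follower is the leader
    delayed by ``lag_s`` plus tracking noise low-passed at
    ``noise_cutoff_hz``, clipped to the sensor rails.
    """
    if params.lag_s < 0:
        raise InvalidArgumentError("lag must be non-negative")
    if params.lag_s >= leader.duration:
        raise InvalidArgumentError("lag must be smaller than the leader duration")
    rng = _rng(seed)
    t = _sensor_timestamps(rng, leader.duration, rate_range, rate_jitter)
    t = t + leader.timestamps[0]
    leader_obs = np.interp(t, leader.timestamps, leader.values)
    t_delayed = np.maximum(t - params.lag_s, leader.timestamps[0])
    follower = np.interp(t_delayed, leader.timestamps, leader.values)
    if rng.uniform() < params.overshoot_prob:
        follower = follower * params.overshoot_gain
    if params.noise_sd > 0:
        white = rng.normal(0.0, 1.0, size=len(t))
        b, a = sps.butter(2, params.noise_cutoff_hz, fs=np.mean(rate_range))
        noise = sps.filtfilt(b, a, white)
        rms = np.sqrt(np.mean(noise**2))
        if rms > 0:
            follower = follower + noise * (params.noise_sd / rms)
    follower = np.clip(follower, -POSITION_BOUND, POSITION_BOUND)
    rate = np.mean(rate_range)
    return (
        SampledSeries(t, np.clip(leader_obs, -POSITION_BOUND, POSITION_BOUND), rate),
        SampledSeries(t, follower, rate),
    )


def generate_tmt_log(params: TMTParams, part: str, repetition: int, seed,
                     participant_id: str = "anon", n_targets: int = 25) -> TMTClickLog:
    """One TMT run: log-normal on-target intervals with the configured median
    and log-scale dispersion; off-target clicks inserted between correct
    clicks at the configured rate."""
    if params.error_rate < 0:
        raise InvalidArgumentError("error rate must be non-negative")
    if params.median_ict_ms <= 0:
        raise InvalidArgumentError("median ICT must be positive")
    rng = _rng(seed)
    mu = np.log(params.median_ict_ms)
    intervals = rng.lognormal(mu, params.dispersion, size=n_targets)
    on_times = np.cumsum(intervals)
    times = list(on_times)
    flags = [True] * n_targets
    for i in range(1, n_targets):
        if rng.uniform() < params.error_rate:
            lo, hi = on_times[i - 1], on_times[i]
            times.append(rng.uniform(lo + 1e-3, hi - 1e-3))
            flags.append(False)
    order = np.argsort(times)
    return TMTClickLog(
        participant_id=participant_id,
        part=part,
        repetition=repetition,
        click_times_ms=np.asarray(times)[order],
        on_target=np.asarray(flags)[order],
        n_targets=n_targets,
    )


# --------------------------------------------------------------------------
# Cohort assembly


def _graded(cc: GroupParams, su: GroupParams, multiplier: float) -> GroupParams:
    """Interpolate the *mirror-game* effect parameters between CC and SU by
    ``multiplier`` (TMT parameters stay at the SU values)."""

    def lerp(a: float, b: float) -> float:
        return a + multiplier * (b - a)

    solo = replace(
        su.solo,
        characteristic_freq_hz=lerp(cc.solo.characteristic_freq_hz,
                                    su.solo.characteristic_freq_hz),
        amplitude=lerp(cc.solo.amplitude, su.solo.amplitude),
    )
    follower = replace(
        su.follower,
        lag_s=lerp(cc.follower.lag_s, su.follower.lag_s),
        noise_sd=lerp(cc.follower.noise_sd, su.follower.noise_sd),
        overshoot_prob=lerp(cc.follower.overshoot_prob, su.follower.overshoot_prob),
    )
    return GroupParams(solo=solo, follower=follower, tmt=su.tmt)


def _individualize(group: GroupParams, rng: np.random.Generator) -> GroupParams:
    """Draw participant-level parameters around the group-level ones."""
    solo = replace(
        group.solo,
        characteristic_freq_hz=float(np.clip(
            rng.normal(group.solo.characteristic_freq_hz, group.solo.freq_jitter_hz),
            0.1, 4.5)),
        amplitude=float(np.clip(
            rng.normal(group.solo.amplitude, group.solo.amplitude_sd), 0.08, 0.55)),
    )
    follower = replace(
        group.follower,
        lag_s=float(np.clip(
            rng.normal(group.follower.lag_s, group.follower.lag_sd_s), 0.01, 1.5)),
        noise_sd=float(abs(rng.normal(group.follower.noise_sd,
                                      group.follower.noise_sd_sd))),
    )
    tmt = replace(
        group.tmt,
        median_ict_ms=float(rng.lognormal(
            np.log(group.tmt.median_ict_ms), group.tmt.between_sd)),
    )
    return GroupParams(solo=solo, follower=follower, tmt=tmt)


def _make_participant(
    pid: str, cohort: str, caarms: Optional[int], params: GroupParams,
    leaders: list[SampledSeries], config: SyntheticConfig,
    rng: np.random.Generator, sex: str,
) -> ParticipantRecord:
    age = float(np.clip(18.0 + rng.exponential(8.0), 18.0, 58.0))
    mg_trials: list[MGTrial] = []
    for session in range(1, N_SESSIONS + 1):
        rep = 1
        solo = generate_solo(params.solo, config.duration_s, rng,
                             config.solo_rate_range_hz, config.rate_jitter)
        mg_trials.append(MGTrial(pid, "solo", session, rep, solo))
        for j in range(LF_PER_SESSION):
            leader = leaders[(session - 1) * LF_PER_SESSION + j]
            lead_obs, foll_obs = generate_follower(
                leader, params.follower, rng, config.lf_rate_range_hz,
                config.rate_jitter)
            mg_trials.append(
                MGTrial(pid, "leader_follower", session, j + 1, foll_obs, lead_obs))
        solo2 = generate_solo(params.solo, config.duration_s, rng,
                              config.solo_rate_range_hz, config.rate_jitter)
        mg_trials.append(MGTrial(pid, "solo", session, rep + 1, solo2))
    tmt_logs = [
        generate_tmt_log(params.tmt, part, rep, rng, participant_id=pid)
        for rep in range(1, N_TMT_REPETITIONS + 1)
        for part in ("A", "B")
    ]
    return ParticipantRecord(id=pid, cohort=cohort, caarms=caarms, age=age, sex=sex,
                             mg_trials=mg_trials, tmt_logs=tmt_logs)


def generate_cohort_dataset(config: SyntheticConfig) -> CohortDataset:
    """Generate the full two-cohort dataset described by ``config``.

    Deterministic in ``config`` (including its seed).  The nine leader
    patterns are shared by every participant, as in the study.  Within SU,
    the first ``caarms_positive_fraction`` (rounded) participants get
    CAARMS > 0 (scores 4 and 2 in a 3:1 ratio) and full-strength mirror-game
    effect parameters; the rest get CAARMS = 0 and effects scaled by
    ``caarms_zero_multiplier``.
    """
    root = np.random.SeedSequence(config.seed)
    leader_ss, participants_ss = root.spawn(2)
    leader_rng = np.random.default_rng(leader_ss)
    leaders = [
        generate_leader_pattern(config.duration_s, config.leader, leader_rng)
        for _ in range(N_SESSIONS * LF_PER_SESSION)
    ]
    participants: list[ParticipantRecord] = []
    n = config.n_per_cohort
    n_pos = int(round(config.caarms_positive_fraction * n))
    streams = participants_ss.spawn(2 * n)
    # Sex split loosely mirrors the study demographics (SU 16/16, CC 12/20).
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        sex = "male" if i < int(round(n * 12 / 32)) else "female"
        params = _individualize(config.cc, rng)
        participants.append(_make_participant(
            f"CC{i + 1:03d}", "CC", None, params, leaders, config, rng, sex))
    for i in range(n):
        rng = np.random.default_rng(streams[n + i])
        sex = "male" if i % 2 == 0 else "female"
        if i < n_pos:
            caarms = 4 if (i % 4) != 3 else 2
            group = _graded(config.cc, config.su, 1.0)
        else:
            caarms = 0
            group = _graded(config.cc, config.su, config.caarms_zero_multiplier)
        params = _individualize(group, rng)
        participants.append(_make_participant(
            f"SU{i + 1:03d}", "SU", caarms, params, leaders, config, rng, sex))
    return CohortDataset(
        participants=participants,
        provenance={"synthetic_config_hash": config.hash(), "seed": config.seed},
    )
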