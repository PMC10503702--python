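"""Mirror-game kinematic preprocessing.

The chain, applied in this fixed order to every trial:

1. resample to a uniform 100 Hz grid with linear interpolation (the sensor's
   native rate varies, 90-140 Hz in Solo and 40-70 Hz in leader-follower);
2. zero-phase low-pass filtering at 5 Hz (second-order Butterworth design run
   forward-backward, so the effective magnitude response is fourth-order and
   the phase response is identically zero);
3. trimming the first and last 5 s of the recording;
4. velocity estimation with a fourth-order central finite-difference stencil.

Sensor-edge saturation (positions pinned at +/-0.5) is *not* repaired here;
`excise_saturation` computes a validity mask from the raw positions and the
feature stage excludes masked samples when averaging or concatenating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .errors import DegenerateInputError, InvalidArgumentError
from .records import MGTrial, POSITION_BOUND, SampledSeries

TARGET_RATE_HZ = 100.0
LOWPASS_CUTOFF_HZ = 5.0
LOWPASS_ORDER = 2
MARGIN_S = 5.0
SATURATION_TOL = 1e-6

#: Samples dropped at each end by the 5-point velocity stencil.
STENCIL_MARGIN = 2


@dataclass
class PreparedTrial:
    """A preprocessed trial on a uniform 100 Hz grid.

    Position and velocity share one time grid (the two stencil-margin samples
    are cropped from every field so lengths agree); leader traces, when
    present, live on the same grid.  ``valid_mask`` is False where the raw
    follower position had saturated at the sensor edge.
    """

    participant_id: str
    game_kind: str
    session_index: int
    repetition_index: int
    position: SampledSeries
    velocity: SampledSeries
    valid_mask: np.ndarray
    leader_position: Optional[SampledSeries] = None
    leader_velocity: Optional[SampledSeries] = None
    stage_log: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.position)
        if len(self.velocity) != n or len(self.valid_mask) != n:
            raise InvalidArgumentError("position/velocity/mask lengths differ")
        if self.leader_position is not None and len(self.leader_position) != n:
            raise InvalidArgumentError("leader and follower grids differ")


def resample_uniform(series: SampledSeries, rate_hz: float = TARGET_RATE_HZ) -> SampledSeries:
    """Linear-interpolation resampling onto a uniform grid.

    The grid runs from the first to the last original timestamp at ``rate_hz``;
    no extrapolation beyond the recorded span.
    """
    if len(series) < 2:
        raise DegenerateInputError("need at least 2 samples to resample")
    if rate_hz <= 0:
        raise InvalidArgumentError("rate must be positive")
    t0, t1 = series.timestamps[0], series.timestamps[-1]
    n = int(np.floor((t1 - t0) * rate_hz)) + 1
    grid = t0 + np.arange(n) / rate_hz
    values = np.interp(grid, series.timestamps, series.values)
    return SampledSeries(grid, values, rate_hz)


def lowpass_filter(
    series: SampledSeries,
    cutoff_hz: float = LOWPASS_CUTOFF_HZ,
    order: int = LOWPASS_ORDER,
) -> SampledSeries:
    """Zero-phase (forward-backward) Butterworth low-pass on a uniform grid."""
    _require_uniform(series)
    nyquist = series.nominal_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise InvalidArgumentError(f"cutoff {cutoff_hz} Hz outside (0, Nyquist={nyquist})")
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=series.nominal_rate)
    filtered = signal.filtfilt(b, a, series.values)
    return SampledSeries(series.timestamps.copy(), filtered, series.nominal_rate)


def trim_margins(series: SampledSeries, margin_s: float = MARGIN_S) -> SampledSeries:
    """Drop samples within ``margin_s`` of either end of the recording."""
    if margin_s < 0:
        raise InvalidArgumentError("margin must be non-negative")
    if margin_s == 0:
        return series.copy()
    if series.duration <= 2 * margin_s:
        raise DegenerateInputError(
            f"duration {series.duration:.2f}s too short for {margin_s}s margins"
        )
    t0, t1 = series.timestamps[0], series.timestamps[-1]
    keep = (series.timestamps >= t0 + margin_s) & (series.timestamps <= t1 - margin_s)
    return SampledSeries(series.timestamps[keep], series.values[keep], series.nominal_rate)


def differentiate(series: SampledSeries) -> SampledSeries:
    """Velocity via the fourth-order central stencil.

    Interior estimate ``(-x[i+2] + 8x[i+1] - 8x[i-1] + x[i-2]) / (12h)``; the
    two samples at each end, where the stencil does not fit, are dropped
    rather than approximated one-sidedly (the 5 s margins have already been
    trimmed, so the loss is negligible and the scheme stays uniformly
    fourth-order accurate).
    """
    _require_uniform(series)
    x = series.values
    if len(x) < 5:
        raise DegenerateInputError("need at least 5 samples for the 5-point stencil")
    h = 1.0 / series.nominal_rate
    v = (-x[4:] + 8.0 * x[3:-1] - 8.0 * x[1:-3] + x[:-4]) / (12.0 * h)
    return SampledSeries(series.timestamps[2:-2], v, series.nominal_rate)


def excise_saturation(
    series: SampledSeries,
    bound: float = POSITION_BOUND,
    tol: float = SATURATION_TOL,
) -> np.ndarray:
    """Validity mask over a raw position trace: False where the sensor pinned.

    A sample counts as saturated when ``|value| >= bound - tol``; the small
    tolerance absorbs floating-point representation of the +/-0.5 rails.
    """
    return np.abs(series.values) < (bound - tol)


def preprocess_mg_trial(
    trial: MGTrial,
    rate_hz: float = TARGET_RATE_HZ,
    cutoff_hz: float = LOWPASS_CUTOFF_HZ,
    margin_s: float = MARGIN_S,
) -> PreparedTrial:
    """Run the full chain on one trial (both traces for leader-follower).

    The follower and leader are interpolated onto one shared uniform grid
    covering the intersection of their recorded spans (anchored at the later
    of the two start times, i.e. the follower grid wins whenever, as in the
    synthetic data, both traces share timestamps).  The validity mask comes
    from the *raw* follower positions, carried through resampling by linear
    interpolation of the saturation indicator: a grid point is invalid if
    either raw neighbour was saturated.
    """
    stages: list[str] = []
    try:
        follower = trial.follower_series
        leader = trial.leader_series
        t_start = follower.timestamps[0]
        t_end = follower.timestamps[-1]
        if leader is not None:
            t_start = max(t_start, leader.timestamps[0])
            t_end = min(t_end, leader.timestamps[-1])
        n = int(np.floor((t_end - t_start) * rate_hz)) + 1
        grid = t_start + np.arange(n) / rate_hz

        def _on_grid(s: SampledSeries) -> SampledSeries:
            return SampledSeries(grid, np.interp(grid, s.timestamps, s.values), rate_hz)

        pos = _on_grid(follower)
        stages.append("resample")
        pos = lowpass_filter(pos, cutoff_hz=cutoff_hz)
        stages.append("lowpass")
        pos = trim_margins(pos, margin_s=margin_s)
        stages.append("trim")
        vel = differentiate(pos)
        stages.append("differentiate")

        # Saturation indicator from raw positions, interpolated onto the grid:
        # any contribution from a saturated raw sample marks the grid point.
        sat = (~excise_saturation(follower)).astype(float)
        sat_grid = np.interp(grid, follower.timestamps, sat) > 0
        mask_full = SampledSeries(grid, (~sat_grid).astype(float), rate_hz)
        mask_trimmed = trim_margins(mask_full, margin_s=margin_s)
        mask = mask_trimmed.values[STENCIL_MARGIN:-STENCIL_MARGIN] > 0.5

        crop = slice(STENCIL_MARGIN, -STENCIL_MARGIN)
        pos_c = SampledSeries(pos.timestamps[crop], pos.values[crop], rate_hz)

        leader_pos = leader_vel = None
        if leader is not None:
            lp = _on_grid(leader)
            lp = lowpass_filter(lp, cutoff_hz=cutoff_hz)
            lp = trim_margins(lp, margin_s=margin_s)
            leader_vel = differentiate(lp)
            leader_pos = SampledSeries(lp.timestamps[crop], lp.values[crop], rate_hz)

        return PreparedTrial(
            participant_id=trial.participant_id,
            game_kind=trial.game_kind,
            session_index=trial.session_index,
            repetition_index=trial.repetition_index,
            position=pos_c,
            velocity=vel,
            valid_mask=mask,
            leader_position=leader_pos,
            leader_velocity=leader_vel,
            stage_log=tuple(stages),
        )
    except (InvalidArgumentError, DegenerateInputError) as exc:
        raise type(exc)(
            f"participant {trial.participant_id}, {trial.game_kind} trial "
            f"(session {trial.session_index}, rep {trial.repetition_index}): {exc}"
        ) from exc


def _require_uniform(series: SampledSeries, rtol: float = 1e-6) -> None:
    dt = np.diff(series.timestamps)
    if len(dt) == 0:
        raise DegenerateInputError("series too short")
    if not np.allclose(dt, dt[0], rtol=rtol, atol=1e-9):
        raise InvalidArgumentError("series must be uniformly sampled")
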