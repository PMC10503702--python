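"""The 12 mirror-game features: Solo/LF global-spectrum summaries and
leader-follower relative phase.

Solo features (position ``p`` and velocity ``v``): peak frequency ``pf`` and
mean frequency of the global wavelet spectrum over [0.25, 5] Hz.

Leader-follower features: mean GWS frequency and GWS density at 5 Hz of the
follower's position and velocity; plus four relative-phase (RP) features from
the wavelet cross-spectrum over [1/15, 2] Hz:

* ``LF RP frequency`` -- scanning the circular-mean-over-time phase profile
  from low to high frequency, the first grid frequency at which the phase
  drops below -pi/4 (a follower lagging by tau crosses at 1/(8*tau); if the
  profile never crosses, the band ceiling of 2 Hz is returned, censored);
* mean / standard deviation / median over time of the circular-mean-over-
  frequency phase series, pooled across trials by concatenation.

Trial inclusion follows the study protocol: the entire first session is a
familiarisation block and is excluded; features pool the remaining trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError
from .preprocess import PreparedTrial
from .records import SampledSeries
from .wavelets import (
    GWS_BAND,
    RP_BAND,
    WCSField,
    compute_gws,
    compute_wcs,
    gws_summaries,
    log_frequency_grid,
)

logger = logging.getLogger(__name__)

PHASE_THRESHOLD = -np.pi / 4.0

MG_FEATURE_NAMES = (
    "S GWS p pf",
    "S GWS p mean",
    "S GWS v pf",
    "S GWS v mean",
    "LF GWS pos. mean",
    "LF GWS pos. 5HZ",
    "LF GWS vel. mean",
    "LF GWS vel. 5HZ",
    "LF RP frequency",
    "LF RP time mean",
    "LF RP time std",
    "LF RP time median",
)


@dataclass
class PhaseProfile:
    """Circular-mean-over-time relative phase per frequency, wrapped to (-pi, pi]."""

    frequencies: np.ndarray
    phase: np.ndarray


@dataclass
class PhaseSeries:
    """Circular-mean-over-frequency relative phase per time, wrapped to (-pi, pi]."""

    times: np.ndarray
    phase: np.ndarray


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to the interval (-pi, pi]."""
    out = np.mod(-np.asarray(phi) + np.pi, 2.0 * np.pi)
    return np.pi - out


def phase_by_frequency(fields: WCSField | Sequence[WCSField]) -> PhaseProfile:
    """Per-frequency circular mean over valid times of the cross-spectrum phase.

    Accepts one field or several (trials pooled by summing unit phasors over
    all valid time cells, i.e. an unweighted circular mean of cell phases).
    """
    if isinstance(fields, WCSField):
        fields = [fields]
    if not fields:
        raise DegenerateInputError("no cross-spectra")
    freqs = fields[0].frequencies
    phasor_sum = np.zeros(len(freqs), dtype=complex)
    counts = np.zeros(len(freqs))
    for fld in fields:
        if len(fld.frequencies) != len(freqs) or not np.allclose(fld.frequencies, freqs):
            raise InvalidArgumentError("cross-spectra use different frequency grids")
        cells = fld.values[:, fld.valid_mask]
        mag = np.abs(cells)
        ok = mag > 0
        unit = np.where(ok, cells / np.where(ok, mag, 1.0), 0.0)
        phasor_sum += unit.sum(axis=1)
        counts += ok.sum(axis=1)
    if np.any(counts == 0):
        raise DegenerateInputError("all-masked frequency row in cross-spectrum")
    return PhaseProfile(freqs, wrap_phase(np.angle(phasor_sum)))


def rp_crossing_frequency(
    profile: PhaseProfile, threshold: float = PHASE_THRESHOLD
) -> tuple[float, bool]:
    """Lowest grid frequency at which the phase drops below ``threshold``.

    Returns ``(frequency, censored)``; if the profile never crosses, the band
    ceiling (the top grid frequency) is returned with ``censored=True``.
    """
    below = profile.phase < threshold
    if np.any(below):
        return float(profile.frequencies[int(np.argmax(below))]), False
    return float(profile.frequencies[-1]), True


def phase_by_time(fields: WCSField | Sequence[WCSField]) -> PhaseSeries:
    """Per-time circular mean over band frequencies, trials concatenated."""
    if isinstance(fields, WCSField):
        fields = [fields]
    if not fields:
        raise DegenerateInputError("no cross-spectra")
    times_all: list[np.ndarray] = []
    phases_all: list[np.ndarray] = []
    offset = 0.0
    for fld in fields:
        cells = fld.values[:, fld.valid_mask]
        if cells.shape[1] == 0:
            continue
        mag = np.abs(cells)
        ok = mag > 0
        unit = np.where(ok, cells / np.where(ok, mag, 1.0), 0.0)
        mean_phasor = unit.sum(axis=0) / np.maximum(ok.sum(axis=0), 1)
        t = fld.times[fld.valid_mask]
        # Concatenation across trials: shift each trial after the first so the
        # pooled time axis stays ascending (the statistics ignore it anyway).
        t_shifted = t - t[0] + offset
        offset = t_shifted[-1] + (1.0 / max(len(t), 1))
        times_all.append(t_shifted)
        phases_all.append(wrap_phase(np.angle(mean_phasor)))
    if not times_all:
        raise DegenerateInputError("no valid samples for phase series")
    return PhaseSeries(np.concatenate(times_all), np.concatenate(phases_all))


def phase_by_time_stats(fields: WCSField | Sequence[WCSField]) -> dict[str, float]:
    """Linear mean/std/median of the wrapped per-time phase values.

    Linear (not circular) statistics on the wrapped values: relative phase in
    a tracking task concentrates near zero, far from the wrap point.
    """
    series = phase_by_time(fields)
    if len(series.phase) == 0:
        raise DegenerateInputError("empty phase series")
    return {
        "mean": float(np.mean(series.phase)),
        "std": float(np.std(series.phase, ddof=1)) if len(series.phase) > 1 else 0.0,
        "median": float(np.median(series.phase)),
    }


def extract_mg_features(
    trials: Sequence[PreparedTrial],
    include_first_session: bool = False,
    gws_band: tuple[float, float] = GWS_BAND,
    rp_band: tuple[float, float] = RP_BAND,
) -> dict[str, float]:
    """The 12 mirror-game features for one participant.

    ``trials`` are that participant's prepared trials; the first session is
    excluded unless ``include_first_session``.  Missing trial classes or
    degenerate traces yield NaN features with a logged reason (the
    classification stage drops such participants).
    """
    included = [t for t in trials if include_first_session or t.session_index > 1]
    solo = [t for t in included if t.game_kind == "solo"]
    lf = [t for t in included if t.game_kind == "leader_follower"]
    out: dict[str, float] = {name: np.nan for name in MG_FEATURE_NAMES}

    # --- Solo block: position & velocity GWS pooled over solo trials.
    if not solo:
        logger.warning("no included solo trials; solo features flagged missing")
    else:
        try:
            spec_p = compute_gws(
                [t.position for t in solo], [t.valid_mask for t in solo], band=gws_band
            )
            s = gws_summaries(spec_p)
            out["S GWS p pf"] = s["peak_frequency"]
            out["S GWS p mean"] = s["mean_frequency"]
            spec_v = compute_gws(
                [t.velocity for t in solo], [t.valid_mask for t in solo], band=gws_band
            )
            s = gws_summaries(spec_v)
            out["S GWS v pf"] = s["peak_frequency"]
            out["S GWS v mean"] = s["mean_frequency"]
        except DegenerateInputError as exc:
            logger.warning("solo GWS degenerate: %s", exc)

    # --- LF block: follower GWS + cross-spectrum relative phase.
    if not lf:
        logger.warning("no included leader-follower trials; LF features flagged missing")
        return out
    try:
        spec_p = compute_gws(
            [t.position for t in lf], [t.valid_mask for t in lf], band=gws_band
        )
        s = gws_summaries(spec_p)
        out["LF GWS pos. mean"] = s["mean_frequency"]
        out["LF GWS pos. 5HZ"] = s["power_at_5hz"]
        spec_v = compute_gws(
            [t.velocity for t in lf], [t.valid_mask for t in lf], band=gws_band
        )
        s = gws_summaries(spec_v)
        out["LF GWS vel. mean"] = s["mean_frequency"]
        out["LF GWS vel. 5HZ"] = s["power_at_5hz"]
    except DegenerateInputError as exc:
        logger.warning("LF GWS degenerate: %s", exc)

    try:
        fields = [
            compute_wcs(t.leader_position, t.position, t.valid_mask, band=rp_band)
            for t in lf
            if t.leader_position is not None
        ]
        if fields:
            profile = phase_by_frequency(fields)
            out["LF RP frequency"], _ = rp_crossing_frequency(profile)
            stats = phase_by_time_stats(fields)
            out["LF RP time mean"] = stats["mean"]
            out["LF RP time std"] = stats["std"]
            out["LF RP time median"] = stats["median"]
        else:
            logger.warning("LF trials lack leader traces; RP features flagged missing")
    except DegenerateInputError as exc:
        logger.warning("LF relative phase degenerate: %s", exc)
    return out
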