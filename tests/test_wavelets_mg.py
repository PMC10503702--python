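"""Wavelet spectra, cross-spectra and the mirror-game features."""

import numpy as np
import pytest

from mirrortrail.errors import DegenerateInputError, InvalidArgumentError
from mirrortrail.mg import (
    PhaseProfile,
    extract_mg_features,
    phase_by_frequency,
    phase_by_time_stats,
    rp_crossing_frequency,
    wrap_phase,
)
from mirrortrail.preprocess import preprocess_mg_trial
from mirrortrail.records import MGTrial, SampledSeries
from mirrortrail.wavelets import (
    GWS_BAND,
    RP_BAND,
    compute_gws,
    compute_wcs,
    cwt_morlet,
    grid_step_ratio,
    gws_summaries,
    log_frequency_grid,
)

from conftest import uniform_series

STEP = grid_step_ratio()


def within_one_grid_step(f: float, target: float) -> bool:
    return abs(np.log2(f / target)) <= np.log2(STEP) + 1e-9


class TestGrids:
    def test_gws_grid_spans_band_and_tops_at_5hz(self):
        g = log_frequency_grid(GWS_BAND)
        assert g[-1] == pytest.approx(5.0)
        assert g[0] >= GWS_BAND[0]
        assert g[0] / STEP < GWS_BAND[0]  # one more step would leave the band
        assert np.all(np.diff(g) > 0)

    def test_rp_grid_tops_at_2hz(self):
        g = log_frequency_grid(RP_BAND)
        assert g[-1] == pytest.approx(2.0)
        assert g[0] >= RP_BAND[0]


class TestCWT:
    def test_tone_ridge_at_tone_frequency(self):
        s = uniform_series(50.0, 100.0, lambda t: np.sin(2 * np.pi * 1.0 * t))
        freqs = log_frequency_grid(GWS_BAND)
        power = np.abs(cwt_morlet(s.values, 100.0, freqs)) ** 2
        ridge = freqs[int(np.argmax(power[:, 2000:3000].mean(axis=1)))]
        assert within_one_grid_step(ridge, 1.0)

    def test_constant_offset_invisible(self):
        # the analytic wavelet has exactly zero mean: offsets change nothing
        s = uniform_series(50.0, 100.0, lambda t: np.sin(2 * np.pi * 0.7 * t))
        freqs = log_frequency_grid(GWS_BAND)
        a = cwt_morlet(s.values, 100.0, freqs)
        b = cwt_morlet(s.values + 17.0, 100.0, freqs)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_agrees_with_pywavelets_route(self):
        # independent CWT route: PyWavelets' complex Morlet with matching
        # bandwidth/centre parameters (B=2, C=omega0/2pi).  Normalisation and
        # scale->frequency conventions differ slightly between the two
        # routes, so compare convention-free statements: each route's
        # time-averaged power peaks at the tone (within one grid step under
        # its own frequency mapping), and both phase ramps run at the tone
        # frequency.
        pywt = pytest.importorskip("pywt")
        rate, tone = 100.0, 1.3
        s = uniform_series(60.0, rate, lambda t: np.sin(2 * np.pi * tone * t))
        freqs = log_frequency_grid(GWS_BAND)
        wavelet = "cmor2.0-0.9549296585513721"
        scales = pywt.frequency2scale(wavelet, freqs / rate)
        coeffs, ref_freqs = pywt.cwt(s.values, scales, wavelet, sampling_period=1 / rate)
        ref_power = (np.abs(coeffs) ** 2)[:, 500:-500].mean(axis=1)
        ref_peak = ref_freqs[int(np.argmax(ref_power))]
        assert abs(np.log2(ref_peak / tone)) <= np.log2(STEP) + 1e-9
        spec = compute_gws([s])
        our_peak = spec.frequencies[int(np.argmax(spec.density))]
        assert abs(np.log2(our_peak / tone)) <= np.log2(STEP) + 1e-9
        # phase velocity at the tone row equals 2*pi*tone for both routes
        row = int(np.argmin(np.abs(freqs - tone)))
        ours = cwt_morlet(s.values, rate, freqs)[row, 1000:2000]
        theirs = coeffs[row, 1000:2000]
        for w in (ours, theirs):
            dphi = np.angle(w[1:] * np.conj(w[:-1]))
            # |.|: the two routes differ in analytic-phase sign convention
            assert abs(np.mean(dphi)) * rate == pytest.approx(2 * np.pi * tone, rel=0.02)


class TestGWS:
    def test_single_tone_peak(self):
        s = uniform_series(50.0, 100.0, lambda t: np.sin(2 * np.pi * 1.0 * t))
        spec = compute_gws([s])
        assert within_one_grid_step(gws_summaries(spec)["peak_frequency"], 1.0)

    def test_unit_band_integral(self):
        rng = np.random.default_rng(0)
        s = uniform_series(30.0, 100.0, lambda t: rng.normal(size=len(t)))
        spec = compute_gws([s])
        assert spec.band_integral == pytest.approx(1.0, abs=1e-9)

    def test_two_tone_ordering(self):
        s = uniform_series(
            60.0, 100.0,
            lambda t: 2.0 * np.sin(2 * np.pi * 0.5 * t) + 0.5 * np.sin(2 * np.pi * 3.0 * t),
        )
        spec = compute_gws([s])
        d_at = lambda f: spec.density[int(np.argmin(np.abs(spec.frequencies - f)))]
        assert d_at(0.5) > d_at(3.0)

    def test_mask_excludes_contaminated_segment(self):
        t = np.arange(0.0, 50.0, 0.01)
        x = np.sin(2 * np.pi * 1.0 * t)
        burst = slice(2000, 2500)
        x2 = x.copy()
        x2[burst] += 5.0 * np.sin(2 * np.pi * 4.0 * t[burst])
        # mask the burst plus a guard for the wavelet support either side
        mask = np.ones(len(t), bool)
        mask[1700:2800] = False
        clean = compute_gws([SampledSeries(t, x, 100.0)])
        masked = compute_gws([SampledSeries(t, x2, 100.0)], [mask])
        np.testing.assert_allclose(masked.density, clean.density, atol=0.05)

    def test_constant_trace_degenerate(self):
        s = uniform_series(50.0, 100.0, lambda t: np.zeros_like(t))
        with pytest.raises(DegenerateInputError):
            compute_gws([s])

    def test_insufficient_duration_degenerate(self):
        s = uniform_series(10.0, 100.0, np.sin)
        with pytest.raises(DegenerateInputError):
            compute_gws([s])


class TestGWSSummaries:
    def test_tone_mean_near_tone(self):
        s = uniform_series(50.0, 100.0, lambda t: np.sin(2 * np.pi * 2.0 * t))
        summ = gws_summaries(compute_gws([s]))
        assert within_one_grid_step(summ["peak_frequency"], 2.0)
        assert abs(summ["mean_frequency"] - 2.0) < 2.0 * (STEP - 1) * 2

    def test_uniform_density_mean_is_band_midpoint(self):
        freqs = log_frequency_grid(GWS_BAND)
        density = np.full(len(freqs), 1.0 / np.trapezoid(np.ones(len(freqs)), freqs))
        from mirrortrail.wavelets import GWSpectrum

        summ = gws_summaries(GWSpectrum(freqs, density))
        midpoint = (freqs[0] + freqs[-1]) / 2.0
        assert summ["mean_frequency"] == pytest.approx(midpoint, rel=1e-9)

    def test_summaries_inside_band(self):
        rng = np.random.default_rng(5)
        s = uniform_series(30.0, 100.0, lambda t: rng.normal(size=len(t)))
        summ = gws_summaries(compute_gws([s]))
        assert GWS_BAND[0] <= summ["peak_frequency"] <= GWS_BAND[1]
        assert GWS_BAND[0] <= summ["mean_frequency"] <= GWS_BAND[1]


def _delayed_pair(tau: float, duration: float = 120.0, rate: float = 100.0):
    rng = np.random.default_rng(7)
    freqs = np.geomspace(0.04, 2.6, 80)
    phases = rng.uniform(0, 2 * np.pi, 80)

    def sig(t):
        return np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None]).sum(0) / 16

    t = np.arange(0.0, duration, 1.0 / rate)
    leader = SampledSeries(t, sig(t), rate)
    follower = SampledSeries(t, sig(t - tau), rate)
    return leader, follower


class TestWCS:
    def test_identical_signals_zero_phase(self):
        leader, _ = _delayed_pair(0.0)
        fld = compute_wcs(leader, leader)
        assert np.max(np.abs(np.angle(fld.values))) < 1e-9

    def test_swapping_arguments_conjugates(self):
        leader, follower = _delayed_pair(0.15)
        a = compute_wcs(leader, follower)
        b = compute_wcs(follower, leader)
        np.testing.assert_allclose(a.values, np.conj(b.values), rtol=1e-9, atol=1e-12)

    def test_mismatched_grids_rejected(self):
        leader, _ = _delayed_pair(0.0)
        other = SampledSeries(leader.timestamps + 0.003, leader.values, 100.0)
        with pytest.raises(InvalidArgumentError):
            compute_wcs(leader, other)

    def test_delay_phase_law(self):
        tau = 0.2
        leader, follower = _delayed_pair(tau)
        fld = compute_wcs(leader, follower)
        prof = phase_by_frequency(fld)
        expected = -2 * np.pi * prof.frequencies * tau
        band = np.abs(expected) < 0.8 * np.pi
        assert np.max(np.abs(prof.phase[band] - expected[band])) < 0.15


class TestPhaseOps:
    def test_wrap_phase_range_and_values(self):
        phi = np.array([0.0, np.pi, -np.pi, 3 * np.pi / 2, -3.6 * np.pi])
        w = wrap_phase(phi)
        assert np.all((w > -np.pi) & (w <= np.pi))
        assert w[1] == pytest.approx(np.pi)
        assert w[2] == pytest.approx(np.pi)  # -pi wraps to +pi
        assert w[3] == pytest.approx(-np.pi / 2)

    def test_circular_mean_wraparound(self):
        # phases straddling the wrap point average to pi, not 0
        from mirrortrail.wavelets import WCSField

        phases = np.array([[np.pi - 0.1, -np.pi + 0.1]])
        fld = WCSField(np.array([1.0]), np.array([0.0, 0.01]),
                       np.exp(1j * phases), np.array([True, True]))
        prof = phase_by_frequency(fld)
        assert abs(prof.phase[0]) == pytest.approx(np.pi, abs=1e-9)

    def test_crossing_closed_form(self):
        for tau in (0.1, 0.2):
            leader, follower = _delayed_pair(tau)
            prof = phase_by_frequency(compute_wcs(leader, follower))
            fc, censored = rp_crossing_frequency(prof)
            assert not censored
            assert abs(np.log2(fc * 8 * tau)) <= 2 * np.log2(STEP) + 1e-9

    def test_zero_lag_censored_at_band_top(self):
        leader, _ = _delayed_pair(0.0)
        prof = phase_by_frequency(compute_wcs(leader, leader))
        fc, censored = rp_crossing_frequency(prof)
        assert censored and fc == pytest.approx(2.0)

    def test_time_stats_identical_signals(self):
        leader, _ = _delayed_pair(0.0)
        stats = phase_by_time_stats(compute_wcs(leader, leader))
        assert abs(stats["mean"]) < 1e-6
        assert stats["std"] < 1e-6
        assert abs(stats["median"]) < 1e-6

    def test_time_stats_delay_negative_mean(self):
        leader, follower = _delayed_pair(0.25)
        stats = phase_by_time_stats(compute_wcs(leader, follower))
        assert stats["mean"] < 0
        assert stats["std"] < 0.6
        assert -np.pi < stats["median"] <= np.pi


@pytest.fixture(scope="module")
def solo_trial():
    from mirrortrail.synthetic import SoloParams, generate_solo

    params = SoloParams(characteristic_freq_hz=0.6, freq_jitter_hz=0.0,
                        freq_wander_hz=0.02, noise_sd=0.0)
    series = generate_solo(params, 60.0, 3)
    return MGTrial("p", "solo", 2, 1, series)


@pytest.fixture(scope="module")
def lf_trial():
    from mirrortrail.synthetic import (
        FollowerParams,
        LeaderPatternParams,
        generate_follower,
        generate_leader_pattern,
    )

    leader = generate_leader_pattern(60.0, LeaderPatternParams(), 11)
    params = FollowerParams(lag_s=0.2, lag_sd_s=0.0, noise_sd=0.0,
                            noise_sd_sd=0.0, overshoot_prob=0.0)
    lead_obs, foll_obs = generate_follower(leader, params, 12)
    return MGTrial("p", "leader_follower", 2, 1, foll_obs, lead_obs)


class TestExtractMG:
    def test_solo_frequency_round_trip(self, solo_trial, lf_trial):
        feats = extract_mg_features(
            [preprocess_mg_trial(solo_trial), preprocess_mg_trial(lf_trial)])
        assert within_one_grid_step(feats["S GWS p pf"], 0.6)

    def test_lag_participant_crossing_frequency(self, solo_trial, lf_trial):
        feats = extract_mg_features(
            [preprocess_mg_trial(solo_trial), preprocess_mg_trial(lf_trial)])
        assert abs(np.log2(feats["LF RP frequency"] / 0.625)) <= 2 * np.log2(STEP) + 1e-9
        assert feats["LF RP time mean"] < 0

    def test_identical_trials_identical_features(self, solo_trial, lf_trial):
        prepared = [preprocess_mg_trial(solo_trial), preprocess_mg_trial(lf_trial)]
        a = extract_mg_features(prepared)
        b = extract_mg_features(prepared)
        assert a == b

    def test_first_session_excluded(self, solo_trial, lf_trial):
        session1 = [
            MGTrial("p", "solo", 1, 1, solo_trial.follower_series),
            MGTrial("p", "leader_follower", 1, 1, lf_trial.follower_series,
                    lf_trial.leader_series),
        ]
        feats = extract_mg_features([preprocess_mg_trial(t) for t in session1])
        assert all(np.isnan(v) for v in feats.values())

    def test_offset_invariance_of_gws_features(self, solo_trial):
        # zero-mean wavelets: a constant position offset changes nothing
        prep = preprocess_mg_trial(solo_trial)
        base = gws_summaries(compute_gws([prep.position], [prep.valid_mask]))
        shifted_series = SampledSeries(prep.position.timestamps,
                                       prep.position.values + 0.05, 100.0)
        shifted = gws_summaries(compute_gws([shifted_series], [prep.valid_mask]))
        for key in base:
            assert shifted[key] == pytest.approx(base[key], abs=1e-6)
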