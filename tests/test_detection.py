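"""Detector behaviour: envelope thresholding, spectral validation of events,
ripple/fast-ripple pairing and rate computation."""

import numpy as np
import pandas as pd
import pytest

from hfoarea.config import AnalysisConfig
from hfoarea.containers import BandEvent
from hfoarea.detection import (
    compute_rates,
    detect_band_events,
    detect_hfos_in_epoch,
    pair_cooccurrence,
    validate_event_spectrum,
)
from hfoarea.preprocessing import bandpass, bandpass_array
from hfoarea.synthetic import RecordingSpec, _burst, pink_noise, simulate_recording
from hfoarea.preprocessing import segment_epochs

from conftest import make_epoch

FS = 2000.0


def _noise_epoch(dur=10.0, seed=0, sd=10.0):
    rng = np.random.default_rng(seed)
    return pink_noise(int(dur * FS), 1.0, sd, rng)


def _band_sd(x, low, high):
    bg = bandpass_array(x, low, high, FS)
    return 1.4826 * np.median(np.abs(bg - np.median(bg)))


def _be(ch, band, t0, t1, freq):
    return BandEvent(ch, band, t0, t1, peak_envelope=1.0, peak_freq=freq)


class TestDetectBandEvents:
    def test_zero_signal_yields_no_events(self):
        ep = make_epoch(np.zeros((1, 20000)))
        assert detect_band_events(ep, "ripple") == []

    def test_single_ripple_recovered_with_accurate_onset(self):
        x = _noise_epoch(seed=3)
        amp = 5.0 * _band_sd(x, 80, 240)
        wave = _burst(FS, 0.06, 140.0, 0.0, amp)
        t0 = 4.0
        i0 = int(t0 * FS) - len(wave) // 2
        x[i0 : i0 + len(wave)] += wave
        raw = make_epoch(x)
        filt = bandpass(raw, 80, 240)
        events = detect_band_events(filt, "ripple", raw_epoch=raw)
        assert len(events) == 1
        assert abs(events[0].t_start - (t0 - 0.03)) < 0.010

    def test_spike_artifact_rejected_by_validation(self):
        x = _noise_epoch(seed=4)
        t = np.arange(int(0.04 * FS)) / FS
        i0 = int(5.0 * FS)
        x[i0 : i0 + len(t)] += 100.0 * np.exp(-t / 0.004)
        raw = make_epoch(x)
        filt = bandpass(raw, 80, 240)
        assert detect_band_events(filt, "ripple", raw_epoch=raw) == []

    def test_event_overlapping_masked_time_discarded(self):
        x = _noise_epoch(seed=5)
        amp = 6.0 * _band_sd(x, 80, 240)
        wave = _burst(FS, 0.06, 140.0, 0.0, amp)
        i0 = int(4.0 * FS)
        x[i0 : i0 + len(wave)] += wave
        ep = make_epoch(x)
        ep.artifact_intervals[0] = [(3.9, 4.2)]
        filt = bandpass(ep, 80, 240)
        assert detect_band_events(filt, "ripple") == []

    def test_invalid_min_duration_rejected(self):
        cfg = AnalysisConfig()
        cfg.min_duration_ms["ripple"] = 0.0
        ep = make_epoch(_noise_epoch())
        with pytest.raises(ValueError, match="min_duration"):
            detect_band_events(bandpass(ep, 80, 240), "ripple", cfg)

    def test_raising_threshold_never_increases_event_count(self):
        for seed in range(4):
            x = _noise_epoch(seed=seed, dur=20.0)
            amp = 5.0 * _band_sd(x, 80, 240)
            for tc in (3.0, 8.0, 14.0):
                wave = _burst(FS, 0.06, 150.0, 0.5, amp)
                i0 = int(tc * FS)
                x[i0 : i0 + len(wave)] += wave
            ep = make_epoch(x)
            filt = bandpass(ep, 80, 240)
            counts = []
            for k in (2.0, 3.0, 4.0, 6.0):
                cfg = AnalysisConfig(threshold_k=k)
                counts.append(len(detect_band_events(filt, "ripple", cfg)))
            assert counts == sorted(counts, reverse=True)


class TestValidateEventSpectrum:
    def test_pure_in_band_burst_accepted(self):
        x = np.zeros(int(2.0 * FS))
        wave = _burst(FS, 0.06, 150.0, 0.0, 10.0)
        x[2000 : 2000 + len(wave)] += wave
        raw = make_epoch(x)
        ev = _be("S01", "ripple", 0.97, 1.09, 150.0)
        assert validate_event_spectrum(ev, raw)

    def test_step_transient_rejected(self):
        x = np.zeros(int(2.0 * FS))
        x[2060:] = 50.0  # discontinuity: 1/f-like spectrum, no isolated peak
        raw = make_epoch(x)
        ev = _be("S01", "ripple", 1.0, 1.06, 150.0)
        assert not validate_event_spectrum(ev, raw)

    def test_burst_outside_band_rejected(self):
        x = np.zeros(int(2.0 * FS))
        wave = _burst(FS, 0.04, 250.0, 0.0, 10.0)
        x[2000 : 2000 + len(wave)] += wave
        raw = make_epoch(x)
        ev = _be("S01", "ripple", 0.99, 1.05, 230.0)
        assert not validate_event_spectrum(ev, raw)


class TestPairCooccurrence:
    def test_union_extent(self):
        r = _be("S01", "ripple", 1.00, 1.06, 120.0)
        f = _be("S01", "fast_ripple", 1.02, 1.04, 300.0)
        hfos = pair_cooccurrence([r], [f])
        assert len(hfos) == 1
        assert (hfos[0].t_start, hfos[0].t_end) == (1.00, 1.06)

    def test_ripple_without_fast_ripple_is_not_an_hfo(self):
        r = _be("S01", "ripple", 1.0, 1.05, 120.0)
        assert pair_cooccurrence([r], []) == []

    def test_disjoint_events_not_paired(self):
        r = _be("S01", "ripple", 1.00, 1.05, 120.0)
        f = _be("S01", "fast_ripple", 2.00, 2.02, 300.0)
        assert pair_cooccurrence([r], [f]) == []

    def test_multiple_nested_fast_ripples_count_once(self):
        r = _be("S01", "ripple", 1.00, 1.10, 120.0)
        f1 = _be("S01", "fast_ripple", 1.01, 1.03, 300.0)
        f2 = _be("S01", "fast_ripple", 1.05, 1.07, 350.0)
        assert len(pair_cooccurrence([r], [f1, f2])) == 1

    def test_cross_channel_pairing_rejected(self):
        r = _be("S01", "ripple", 1.0, 1.05, 120.0)
        f = _be("S02", "fast_ripple", 1.01, 1.03, 300.0)
        with pytest.raises(ValueError, match="cross-channel"):
            pair_cooccurrence([r], [f])


class TestComputeRates:
    def _frames(self, count, minutes):
        c = pd.DataFrame({0: [count]}, index=["S01"])
        m = pd.DataFrame({0: [minutes]}, index=["S01"])
        return c, m

    @pytest.mark.parametrize("count,minutes,expected", [(15, 5.0, 3.0), (0, 5.0, 0.0), (8, 4.0, 2.0)])
    def test_rate_arithmetic(self, count, minutes, expected):
        rm = compute_rates(*self._frames(count, minutes))
        assert rm.rates.loc["S01", 0] == pytest.approx(expected)

    def test_zero_minutes_marked_missing(self):
        rm = compute_rates(*self._frames(3, 0.0))
        assert np.isnan(rm.rates.loc["S01", 0])


@pytest.fixture(scope="module")
def detected_epoch():
    spec = RecordingSpec(n_channels=1, duration_s=300, event_rates={"S01": 4.0}, seed=21)
    rec, truth = simulate_recording(spec)
    ep = segment_epochs(rec)[0]
    return ep, detect_hfos_in_epoch(ep)["S01"], [t for t in truth if t.kind == "hfo"]


def test_detected_hfos_match_injected_events(detected_epoch):
    ep, detected, truth = detected_epoch
    hits = sum(
        any(d.t_start < g.t_end and g.t_start < d.t_end for d in detected) for g in truth
    )
    assert hits / len(truth) >= 0.9
    extra = sum(
        not any(d.t_start < g.t_end and g.t_start < d.t_end for g in truth) for d in detected
    )
    assert extra <= 1


def test_every_hfo_component_passes_spectral_validation(detected_epoch):
    ep, detected, _ = detected_epoch
    assert detected
    for h in detected:
        assert validate_event_spectrum(h.ripple, ep)
        assert validate_event_spectrum(h.fast_ripple, ep)
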