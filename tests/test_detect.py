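import numpy as np
import pytest

from sleepspike.core import NREM, OscEvent
from sleepspike.detect import (CRIPPLE_PARAMS, DetectorParams, PowerTrace,
                               band_rms_z, concatenate_overlapping,
                               detect_spindles, detect_swr,
                               detect_threshold_events, event_summary,
                               morlet_power)
from conftest import make_hypnogram
from sleepspike.core import WAKE, REM


FS = 1250.0


def _trace(z, fs=FS):
    return PowerTrace(z=np.asarray(z, dtype=float), fs=fs, band=(90, 180),
                      window_ms=20.0)


class TestBandRmsZ:
    def test_baseline_mean_zero_sd_one(self, rng):
        x = rng.standard_normal(int(60 * FS))
        pw = band_rms_z(x, FS, (100, 250), 13.3, [(0.0, 60.0)])
        assert np.mean(pw.z) == pytest.approx(0.0, abs=1e-9)
        assert np.std(pw.z) == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(int(30 * FS))
        z1 = band_rms_z(x, FS, (100, 250), 13.3, [(0.0, 30.0)]).z
        z2 = band_rms_z(1234.5 * x, FS, (100, 250), 13.3, [(0.0, 30.0)]).z
        np.testing.assert_allclose(z1, z2, rtol=1e-6, atol=1e-7)

    def test_sinusoid_plateau_matches_analytic_rms(self, rng):
        """A 150 Hz sinusoid segment raises band RMS to ~A/sqrt(2)."""
        n = int(60 * FS)
        t = np.arange(n) / FS
        x = 0.1 * rng.standard_normal(n)
        a = 5.0
        seg = (t >= 30) & (t < 31)
        x[seg] += a * np.sin(2 * np.pi * 150 * t[seg])
        filt_rms_expected = a / np.sqrt(2)
        pw = band_rms_z(x, FS, (100, 250), 13.3, [(0.0, 30.0)])
        # invert the z-scoring on the plateau and compare to A/sqrt(2)
        base = band_rms_z(x, FS, (100, 250), 13.3, [(0.0, 30.0)])
        mid = pw.z[int(30.3 * FS):int(30.7 * FS)]
        # reconstruct rms on the plateau: z = (rms - mu)/sd
        from sleepspike.detect import bandpass
        from scipy.ndimage import uniform_filter1d
        filt = bandpass(x, FS, (100, 250))
        rms = np.sqrt(uniform_filter1d(filt**2, size=round(0.0133 * FS),
                                       mode="nearest"))
        plateau = rms[int(30.3 * FS):int(30.7 * FS)].mean()
        assert plateau == pytest.approx(filt_rms_expected, rel=0.02)
        assert mid.mean() > 10  # z plateau far above baseline

    def test_empty_baseline_fails(self, rng):
        with pytest.raises(ValueError):
            band_rms_z(rng.standard_normal(1000), FS, (100, 250), 13.3, [])


class TestThresholdEngine:
    def test_rectangular_pulse_detected(self):
        z = np.zeros(int(FS))
        z[int(0.4 * FS):int(0.5 * FS)] = 6.0
        params = DetectorParams((90, 180), 20, 2.0, 4.0, 30, 20)
        evs = detect_threshold_events(_trace(z), params)
        assert len(evs) == 1
        assert evs[0].start == pytest.approx(0.4, abs=2 / FS)
        assert evs[0].end == pytest.approx(0.5, abs=2 / FS)
        assert evs[0].peak_z == 6.0

    def test_close_pulses_are_merged(self):
        z = np.zeros(int(FS))
        z[int(0.40 * FS):int(0.45 * FS)] = 6.0
        z[int(0.465 * FS):int(0.50 * FS)] = 6.0  # 15 ms gap < 20 ms
        params = DetectorParams((90, 180), 20, 2.0, 4.0, 30, 20)
        evs = detect_threshold_events(_trace(z), params)
        assert len(evs) == 1
        assert evs[0].duration == pytest.approx(0.1, abs=3 / FS)

    def test_weak_or_short_pulses_are_dropped(self):
        z = np.zeros(int(FS))
        z[100:150] = 3.0   # peak below 4
        z[500:520] = 6.0   # 16 ms < 30 ms
        params = DetectorParams((90, 180), 20, 2.0, 4.0, 30, 10)
        assert detect_threshold_events(_trace(z), params) == []

    def test_matches_runlength_oracle_on_random_traces(self, rng):
        """Event set equals a brute-force scan over piecewise-constant z."""
        params = DetectorParams((90, 180), 20, 1.5, 3.0, 24, 16, 400)
        for _ in range(20):
            z = np.repeat(rng.choice([0.0, 2.0, 4.0, 6.0], size=80),
                          rng.integers(5, 40))
            evs = detect_threshold_events(_trace(z), params)
            oracle = _oracle_events(z, FS, params)
            assert len(evs) == len(oracle)
            for e, (lo, hi, pk) in zip(evs, oracle):
                assert e.start == pytest.approx(lo)
                assert e.end == pytest.approx(hi)
                assert e.peak_z == pytest.approx(pk)


def _oracle_events(z, fs, p):
    runs = []
    in_run = False
    for i, v in enumerate(z):
        if v > p.enter_z and not in_run:
            runs.append([i, i + 1])
            in_run = True
        elif v > p.enter_z:
            runs[-1][1] = i + 1
        else:
            in_run = False
    merged = []
    for lo, hi in runs:
        if merged and (lo - merged[-1][1]) / fs < p.merge_gap_ms / 1000:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    out = []
    for lo, hi in merged:
        dur = (hi - lo) / fs * 1000
        pk = z[lo:hi].max()
        if dur >= p.min_dur_ms and dur < p.max_dur_ms and pk >= p.peak_z:
            out.append((lo / fs, hi / fs, pk))
    return out


def test_concatenate_overlapping_unions_spans():
    evs = [OscEvent("x", 1.0, 1.2, 1.1, 5.0), OscEvent("x", 1.15, 1.4, 1.3, 7.0),
           OscEvent("x", 2.0, 2.1, 2.05, 4.0)]
    out = concatenate_overlapping(evs)
    assert len(out) == 2
    assert out[0].start == 1.0 and out[0].end == 1.4
    assert out[0].peak_z == 7.0  # strongest contributor keeps the peak


class TestOnSyntheticSession:
    """Detector behavior on the shared synthetic session ground truth."""

    def test_injected_events_recovered(self, small_session):
        cfg, bundle = small_session
        from sleepspike.sleep import normalize_hypnogram
        from sleepspike.detect import detect_all
        hyp = normalize_hypnogram(bundle.hypnogram)
        dets = detect_all(bundle.lfp, hyp)
        truth = bundle.truth["events"]
        for kind in ("SWR", "HFO", "cRipple", "spindle"):
            inj = truth[truth.kind == kind]
            iv = inj[["start_s", "end_s"]].to_numpy(float)
            d = dets[kind]
            hit = sum(1 for lo, hi in iv
                      if any(e.start < hi and e.end > lo for e in d))
            tp = sum(1 for e in d
                     if np.any((iv[:, 0] < e.end) & (iv[:, 1] > e.start)))
            assert hit / len(iv) >= 0.9, kind
            assert tp / len(d) >= 0.9, kind

    def test_peak_times_near_injection_centers(self, small_session):
        cfg, bundle = small_session
        from sleepspike.sleep import normalize_hypnogram
        from sleepspike.detect import detect_hfo
        hyp = normalize_hypnogram(bundle.hypnogram)
        truth = bundle.truth["events"]
        inj = truth[truth.kind == "HFO"]
        centers = inj["center_s"].to_numpy(float)
        for e in detect_hfo(bundle.lfp, hyp):
            assert np.min(np.abs(centers - e.peak_time)) < 0.020


class TestSwrRules:
    def _session(self, sharpwave: bool, state=NREM):
        """One injected ripple (with/without sharp-wave) in a tiny session."""
        from sleepspike.synth import SynthConfig, embed_oscillations
        hyp = make_hypnogram([(state, 300), (NREM, 300)]) if state != NREM \
            else make_hypnogram([(NREM, 600)])
        cfg = SynthConfig(duration_s=600.0, n_units_per_region=1, seed=3,
                          event_rates={"SWR": 1.0, "HFO": 0, "cRipple": 0,
                                       "spindle": 0, "SWR_wake": 1.0},
                          swr_sharpwave_fraction=1.0 if sharpwave else 0.0)
        lfp, _, truth = embed_oscillations(cfg, hyp, [])
        return lfp, hyp, truth

    def test_ripple_with_sharpwave_yields_swr(self):
        lfp, hyp, truth = self._session(sharpwave=True)
        evs = detect_swr(lfp, hyp)
        assert len(evs) == len(truth.events["SWR"])

    def test_ripple_without_sharpwave_yields_no_swr(self):
        lfp, hyp, truth = self._session(sharpwave=False)
        assert len(truth.events["SWR"]) > 0
        assert detect_swr(lfp, hyp) == []


class TestSpindleRules:
    @staticmethod
    def _burst_lfp(rng, burst_times, fs=FS, dur=600.0, burst_dur=0.6):
        """Three PL5 channels of independent noise carrying coherent
        12 Hz bursts (the detector averages prelimbic channels)."""
        from sleepspike.core import LfpSet
        from sleepspike.detect import bandpass
        n = int(dur * fs)
        t = np.arange(n) / fs
        data = rng.standard_normal((3, n))
        amp = 10 * np.std(bandpass(data[0], fs, (9, 18)))
        for t0 in burst_times:
            seg = (t >= t0) & (t < t0 + burst_dur)
            data[:, seg] += amp * np.sin(2 * np.pi * 12.0 * (t[seg] - t0))
        chans = [{"name": f"PL5_ch{i}", "region": "PL5", "shank": 0,
                  "depth_order": i} for i in range(3)]
        return LfpSet(data, fs, chans)

    def test_nrem_burst_detected_wake_burst_gated_out(self, rng):
        hyp = make_hypnogram([(NREM, 300), (WAKE, 100), (NREM, 200)])
        lfp = self._burst_lfp(rng, burst_times=[100.0, 330.0])
        evs = detect_spindles(lfp, hyp)
        hits_nrem = [e for e in evs if e.start < 100.6 and e.end > 100.0]
        hits_wake = [e for e in evs if e.start < 330.6 and e.end > 330.0]
        assert len(hits_nrem) == 1
        assert hits_wake == []

    def test_minimum_duration_rule_is_applied(self, rng):
        hyp = make_hypnogram([(NREM, 600)])
        lfp = self._burst_lfp(rng, burst_times=[100.0, 300.0])
        evs = detect_spindles(lfp, hyp)
        for t0 in (100.0, 300.0):
            assert any(e.start < t0 + 0.6 and e.end > t0 for e in evs)
        # a stricter sustain requirement rejects even the strong bursts
        assert detect_spindles(lfp, hyp, min_dur_ms=2000.0) == []


def test_morlet_power_peaks_at_matching_frequency():
    fs = 1250.0
    t = np.arange(int(20 * fs)) / fs
    x = np.sin(2 * np.pi * 12.0 * t)
    freqs = np.geomspace(9, 18, 11)
    p = morlet_power(x, fs, freqs)
    mid = p[:, int(5 * fs):int(15 * fs)].mean(axis=1)
    assert freqs[np.argmax(mid)] == pytest.approx(12.0, rel=0.08)


class TestEventSummary:
    def test_rate_and_median(self):
        evs = [OscEvent("x", i, i + 0.05, i + 0.01, 5.0) for i in range(10)]
        s = event_summary(evs, [(0.0, 100.0)])
        assert s["rate_per_s"] == pytest.approx(0.1)
        assert s["dur_ms_median"] == pytest.approx(50.0)

    def test_empty_events(self):
        s = event_summary([], [(0.0, 100.0)])
        assert s["rate_per_s"] == 0.0
        assert np.isnan(s["dur_ms_median"])

    def test_quartiles_match_sort_oracle(self, rng):
        durs = rng.uniform(0.02, 0.4, size=37)
        evs = [OscEvent("x", float(i), float(i + d), float(i), 5.0)
               for i, d in enumerate(durs)]
        s = event_summary(evs, [(0.0, 100.0)])
        assert s["dur_ms_q1"] == pytest.approx(np.percentile(durs * 1000, 25))
        assert s["dur_ms_q3"] == pytest.approx(np.percentile(durs * 1000, 75))
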