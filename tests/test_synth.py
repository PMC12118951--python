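import hashlib
from pathlib import Path

import numpy as np
import pytest

from sleepspike.core import MA, NREM, REM, WAKE
from sleepspike.synth import (SynthConfig, embed_oscillations,
                              generate_hypnogram, generate_session,
                              generate_units, simulate_state_poisson)
from conftest import make_hypnogram


class TestConfig:
    def test_rejects_low_sampling_rate(self):
        with pytest.raises(ValueError, match="Nyquist"):
            SynthConfig(fs_lfp=500.0)

    def test_rejects_nonpositive_ratios(self):
        with pytest.raises(ValueError):
            SynthConfig(rem_nrem_ratio_range=(0.0, 2.0))

    def test_rejects_ripple_class_events_over_750ms(self):
        with pytest.raises(ValueError, match="750"):
            SynthConfig(event_duration_ranges={
                "SWR": (0.05, 0.9), "HFO": (0.04, 0.08),
                "cRipple": (0.06, 0.1), "spindle": (0.5, 1.0)})


class TestHypnogram:
    def test_all_nrem_transition_matrix_gives_single_interval(self):
        cfg = SynthConfig(duration_s=3600.0, seed=1,
                          transitions={NREM: {}}, initial_state=NREM,
                          dwell={NREM: (10_000.0, 0.01)})
        hyp = generate_hypnogram(cfg)
        assert len(hyp) == 1
        assert hyp.states[0] == NREM
        assert (hyp.starts[0], hyp.ends[0]) == (0.0, 3600.0)

    def test_partitions_session_exactly(self):
        cfg = SynthConfig(duration_s=7200.0, seed=1)
        hyp = generate_hypnogram(cfg)
        assert hyp.starts[0] == 0.0
        assert hyp.ends[-1] == 7200.0
        np.testing.assert_allclose(hyp.starts[1:], hyp.ends[:-1])
        assert np.sum(hyp.ends - hyp.starts) == pytest.approx(7200.0)

    def test_too_short_session_fails(self):
        with pytest.raises(ValueError, match="too short"):
            generate_hypnogram(SynthConfig(duration_s=599.0))

    def test_contains_usable_nrem_and_rem_when_long(self):
        for seed in range(5):
            hyp = generate_hypnogram(SynthConfig(duration_s=1800.0, seed=seed))
            durs = hyp.ends - hyp.starts
            assert np.any((hyp.states == NREM) & (durs > 50))
            assert np.any((hyp.states == REM) & (durs > 50))

    def test_extended_sleep_frequency_matches_dwell_simulation(self):
        """The fraction of 2-h sessions containing extended sleep agrees
        with a direct independent simulation of the semi-Markov dwell
        process (Monte-Carlo oracle)."""
        from sleepspike.sleep import find_extended_sleep, normalize_hypnogram
        n = 120
        hits = 0
        for seed in range(n):
            hyp = generate_hypnogram(SynthConfig(duration_s=7200.0, seed=seed))
            if len(find_extended_sleep(normalize_hypnogram(hyp))):
                hits += 1
        frac = hits / n

        # oracle: replay the dwell process directly and scan sleep runs
        rng = np.random.default_rng(2024)
        cfg = SynthConfig(duration_s=7200.0)
        oracle_hits = 0
        m = 400
        for _ in range(m):
            t, s = 0.0, WAKE
            runs, cur = [], 0.0
            while t < 7200.0:
                med, sig = cfg.dwell[s]
                d = float(rng.lognormal(np.log(med), sig))
                if s == MA:
                    d = min(d, 39.0)
                d = max(d, 1.0)
                d = min(d, 7200.0 - t)
                if s in (NREM, REM) or (d <= 60.0 and s in (MA, WAKE) and cur > 0):
                    cur += d
                else:
                    runs.append(cur)
                    cur = 0.0
                t += d
                opts = cfg.transitions[s]
                labels = sorted(opts)
                p = np.array([opts[k] for k in labels])
                s = labels[rng.choice(len(labels), p=p / p.sum())]
            runs.append(cur)
            if max(runs) > 1800.0:
                oracle_hits += 1
        oracle = oracle_hits / m
        assert frac == pytest.approx(oracle, abs=0.12)
        assert frac > 0.5  # 2-h sessions usually contain extended sleep


class TestUnits:
    def test_zero_rates_give_empty_train(self, rng):
        hyp = make_hypnogram([(NREM, 500), (REM, 500)])
        t = simulate_state_poisson(hyp, {NREM: 0.0, REM: 0.0}, rng)
        assert t.size == 0

    def test_poisson_count_within_three_sd(self, rng):
        hyp = make_hypnogram([(NREM, 1000)])
        t = simulate_state_poisson(hyp, {NREM: 2.0}, rng)
        assert abs(t.size - 2000) < 3 * np.sqrt(2000)
        assert np.all(np.diff(t) > 0)

    def test_negative_rate_fails(self, rng):
        hyp = make_hypnogram([(NREM, 100)])
        with pytest.raises(ValueError, match="negative"):
            simulate_state_poisson(hyp, {NREM: -1.0}, rng)

    def test_rate_ratio_recovered_by_bin_count_oracle(self, rng):
        hyp = make_hypnogram([(NREM, 900), (REM, 900)] * 2)
        t = simulate_state_poisson(hyp, {NREM: 1.0, REM: 3.0}, rng)
        # independent oracle: direct counts per state interval
        n_rem = sum(np.count_nonzero((t >= lo) & (t < hi))
                    for lo, hi in hyp.intervals(REM))
        n_nrem = sum(np.count_nonzero((t >= lo) & (t < hi))
                     for lo, hi in hyp.intervals(NREM))
        ratio = (n_rem / 1800) / (n_nrem / 1800)
        assert ratio == pytest.approx(3.0, rel=0.15)

    def test_generated_units_match_truth_rates(self):
        cfg = SynthConfig(duration_s=3600.0, n_units_per_region=3, seed=9)
        hyp = generate_hypnogram(cfg)
        units, truth = generate_units(cfg, hyp)
        assert len(units) == 9
        dur_n = hyp.state_duration(NREM)
        for u, row in zip(units, truth.itertuples()):
            n = sum(np.count_nonzero((u.times >= lo) & (u.times < hi))
                    for lo, hi in hyp.intervals(NREM))
            expect = row.rate_nrem * dur_n
            assert abs(n - expect) < 4 * np.sqrt(max(expect, 1))


class TestEmbed:
    def test_zero_event_rates_give_pure_background(self):
        cfg = SynthConfig(duration_s=900.0, seed=2, event_rates={
            "SWR": 0, "HFO": 0, "cRipple": 0, "spindle": 0, "SWR_wake": 0})
        hyp = generate_hypnogram(cfg)
        lfp, units, truth = embed_oscillations(cfg, hyp, [])
        assert all(len(v) == 0 for v in truth.events.values())
        assert lfp.n_samples == round(900.0 * cfg.fs_lfp)

    def test_injected_ripple_band_power_peaks_at_center(self):
        """Oracle: direct band-pass + argmax against injection centers."""
        from sleepspike.detect import bandpass
        cfg = SynthConfig(duration_s=900.0, seed=4, event_rates={
            "SWR": 2.0, "HFO": 0, "cRipple": 0, "spindle": 0, "SWR_wake": 0})
        hyp = generate_hypnogram(cfg)
        lfp, _, truth = embed_oscillations(cfg, hyp, [])
        filt = np.abs(bandpass(lfp.data[0].astype(float), cfg.fs_lfp,
                               (100, 250)))
        from scipy.ndimage import uniform_filter1d
        env = uniform_filter1d(filt**2, int(0.0133 * cfg.fs_lfp))
        for lo, hi, center in truth.events["SWR"]:
            i0, i1 = int(lo * cfg.fs_lfp), int(hi * cfg.fs_lfp)
            t_peak = (i0 + np.argmax(env[i0:i1])) / cfg.fs_lfp
            assert abs(t_peak - center) < 0.015

    def test_event_gain_recovered_by_thinning_oracle(self):
        cfg = SynthConfig(duration_s=3600.0, seed=6)
        hyp = make_hypnogram([(NREM, 3600.0)])
        rng = cfg.rng("t")
        lam = 4.0
        t = simulate_state_poisson(hyp, {NREM: lam}, rng)
        from sleepspike.core import SpikeTrain
        u = SpikeTrain("vCA1_000", t, "vCA1", 0)
        u.rates = {NREM: lam, REM: lam, WAKE: lam, MA: lam}
        cfg.event_rates = {"SWR": 4.0, "HFO": 0, "cRipple": 0, "spindle": 0,
                           "SWR_wake": 0}
        cfg.event_gain_range = (5.0, 5.0)
        lfp, units, truth = embed_oscillations(cfg, hyp, [u])
        ev = truth.events["SWR"][:, :2]
        tt = units[0].times
        in_ev = sum(np.count_nonzero((tt >= lo) & (tt < hi)) for lo, hi in ev)
        dur = np.sum(ev[:, 1] - ev[:, 0])
        gain_est = (in_ev / dur) / lam
        assert gain_est == pytest.approx(5.0, rel=0.2)

    def test_gain_one_leaves_rates_statistically_flat(self):
        from scipy.stats import mannwhitneyu
        cfg = SynthConfig(duration_s=3600.0, seed=8, event_gain_range=(1.0, 1.0))
        hyp = make_hypnogram([(NREM, 3600.0)])
        rng = cfg.rng("t")
        t = simulate_state_poisson(hyp, {NREM: 3.0}, rng)
        from sleepspike.core import SpikeTrain
        u = SpikeTrain("vCA1_000", t, "vCA1", 0)
        u.rates = {NREM: 3.0, REM: 3.0, WAKE: 3.0, MA: 3.0}
        lfp, units, truth = embed_oscillations(cfg, hyp, [u])
        np.testing.assert_array_equal(units[0].times, t)  # untouched at g=1

    def test_injected_intervals_nonoverlapping_within_kind(self):
        cfg = SynthConfig(duration_s=1800.0, seed=3)
        hyp = generate_hypnogram(cfg)
        _, _, truth = embed_oscillations(cfg, hyp, [])
        for kind, arr in truth.events.items():
            iv = arr[np.argsort(arr[:, 0])]
            assert np.all(iv[1:, 0] >= iv[:-1, 1]), kind
            assert np.all(iv[:, 0] >= 0) and np.all(iv[:, 1] <= 1800.0)


class TestSession:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg1 = SynthConfig(duration_s=900.0, n_units_per_region=2, seed=11)
        cfg2 = SynthConfig(duration_s=900.0, n_units_per_region=2, seed=11)
        generate_session(cfg1, tmp_path / "a")
        generate_session(cfg2, tmp_path / "b")
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        files_b = sorted(p.name for p in (tmp_path / "b").iterdir())
        assert files_a == files_b
        for name in files_a:
            ha = hashlib.sha256((tmp_path / "a" / name).read_bytes()).hexdigest()
            hb = hashlib.sha256((tmp_path / "b" / name).read_bytes()).hexdigest()
            assert ha == hb, name

    def test_manifest_bookkeeping(self, small_session):
        cfg, bundle = small_session
        man = bundle.manifest
        root = bundle.manifest_path.parent
        for rel in man["files"].values():
            assert (root / rel).exists()
        assert man["n_samples"] == round(cfg.duration_s * cfg.fs_lfp)
        assert man["counts"]["units"] == len(bundle.units)
        assert man["counts"]["spikes"] == sum(u.n_spikes for u in bundle.units)

    def test_spike_trains_strictly_increasing_in_bounds(self, small_session):
        cfg, bundle = small_session
        for u in bundle.units:
            if u.n_spikes > 1:
                assert np.all(np.diff(u.times) > 0)
            if u.n_spikes:
                assert u.times[0] >= 0 and u.times[-1] < cfg.duration_s
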