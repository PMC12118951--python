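"""Synthetic session generator with ground truth.

Emulates an overnight multi-regional rodent recording well enough to
exercise every downstream stage:

* a semi-Markov hypnogram (log-normal dwell times per state, configurable
  transition matrix) over WAKE/NREM/REM plus brief microarousals;
* per-unit state-dependent Poisson spike trains with configurable
  REM/NREM rate ratios;
* multi-channel LFP made of Gaussian 1/f background (spectral exponent 1,
  synthesized in the frequency domain) with injected oscillation bursts -
  ripples (150 Hz, 50-100 ms, paired with a negative sharp-wave on the
  superficial-deep channel difference), HFOs (120 Hz, 40-80 ms), cRipples
  (120 Hz, 60-100 ms), spindles (12 Hz, 0.5-1 s);
* multiplicative spike-rate gains inside injected events, and shock-locked
  rate transients.

The synthetic probe has exactly two vCA1 channels (superficial and deep on
one shank), three PL5 channels and one BLA channel. All randomness flows
from one seeded generator passed explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (MA, NREM, REM, WAKE, Hypnogram, LfpSet, SpikeTrain,
                   as_intervals)
from .detect import bandpass
from . import session as sio

REGIONS = ("vCA1", "PL5", "BLA")
EVENT_KINDS = ("SWR", "HFO", "cRipple", "spindle")
RIPPLE_CLASS = ("SWR", "HFO", "cRipple")

DEFAULT_DWELL = {WAKE: (120.0, 0.8), NREM: (300.0, 0.5),
                 REM: (90.0, 0.4), MA: (15.0, 0.4)}
DEFAULT_TRANSITIONS = {
    WAKE: {NREM: 1.0},
    NREM: {REM: 0.50, MA: 0.35, WAKE: 0.15},
    REM: {NREM: 0.80, WAKE: 0.20},
    MA: {NREM: 1.0},
}
DEFAULT_EVENT_RATES = {"SWR": 10.0, "HFO": 8.0, "cRipple": 8.0,
                       "spindle": 3.0, "SWR_wake": 4.0}  # events/min of state
# cRipple bursts are kept >= 60 ms so every injection can satisfy the
# detector's published >= 50 ms supra-threshold duration criterion
DEFAULT_EVENT_DURATIONS = {"SWR": (0.05, 0.10), "HFO": (0.04, 0.08),
                           "cRipple": (0.06, 0.10), "spindle": (0.5, 1.0)}
EVENT_FREQ_HZ = {"SWR": 150.0, "HFO": 120.0, "cRipple": 120.0, "spindle": 12.0}
EVENT_BAND = {"SWR": (100.0, 250.0), "HFO": (90.0, 180.0),
              "cRipple": (90.0, 180.0), "spindle": (9.0, 18.0)}
EVENT_CHANNEL_REGION = {"SWR": "vCA1", "HFO": "BLA", "cRipple": "PL5",
                        "spindle": "PL5"}
MIN_EVENT_GAP_S = {"SWR": 0.3, "HFO": 0.3, "cRipple": 0.3, "spindle": 1.5}


@dataclass
class SynthConfig:
    duration_s: float = 7200.0
    fs_lfp: float = 1250.0
    n_units_per_region: int = 10
    rem_nrem_ratio_range: tuple = (0.25, 4.0)
    base_rate_range: tuple = (0.5, 5.0)          # NREM rate, Hz
    event_rates: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_RATES))
    event_duration_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_EVENT_DURATIONS))
    event_gain_range: tuple = (1.0, 5.0)
    event_amp_sd: float = 10.0    # burst amplitude in band-limited background SDs
    sharpwave_amp_sd: float = 8.0
    swr_sharpwave_fraction: float = 1.0
    shock_times: tuple = ()       # shock onsets, s (2-s shocks)
    shock_duration_s: float = 2.0
    shock_gain_range: tuple = (2.0, 8.0)
    cs_times: tuple = ()
    seed: int = 0
    dwell: dict = field(default_factory=lambda: dict(DEFAULT_DWELL))
    transitions: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_TRANSITIONS.items()})
    initial_state: str = WAKE

    def __post_init__(self):
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if self.fs_lfp < 600:
            raise ValueError("fs_lfp must be >= 600 Hz (Nyquist above 250 Hz)")
        if min(self.rem_nrem_ratio_range) <= 0 or min(self.event_gain_range) <= 0:
            raise ValueError("rate ratios and gains must be positive")
        for kind in RIPPLE_CLASS:
            lo, hi = self.event_duration_ranges.get(kind, (0, 0))
            if hi >= 0.75:
                raise ValueError(
                    f"{kind} duration up to {hi} s would violate the 750 ms "
                    "detector maximum")

    def rng(self, *spawn_key) -> np.random.Generator:
        import zlib
        key = [zlib.crc32(str(k).encode()) for k in spawn_key]
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))


@dataclass
class GroundTruth:
    hypnogram: Hypnogram = None
    unit_rates: pd.DataFrame = None     # unit_id, region, rate per state
    unit_gains: pd.DataFrame = None     # unit_id, kind, gain
    events: dict = field(default_factory=dict)  # kind -> (n, 3) start/end/center
    swr_has_sharpwave: np.ndarray = None
    shock_gains: pd.DataFrame = None


# ---------------------------------------------------------------------------
# hypnogram
# ---------------------------------------------------------------------------

def _draw_dwell(rng, state: str, dwell: dict) -> float:
    med, sigma = dwell[state]
    d = float(rng.lognormal(np.log(med), sigma))
    if state == MA:
        d = min(d, 39.0)  # microarousals are < 40 s by definition
    return max(d, 1.0)


def _reachable(transitions: dict, start: str) -> set:
    seen = {start}
    stack = [start]
    while stack:
        s = stack.pop()
        for nxt in transitions.get(s, {}):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


def generate_hypnogram(config: SynthConfig, rng=None) -> Hypnogram:
    """Semi-Markov hypnogram partitioning [0, duration) exactly.

    With the default transition structure a draw is retried (deterministic
    child seeds) until the session contains a NREM and a REM epoch > 50 s,
    which the defaults make overwhelmingly likely for sessions >= 30 min.
    """
    if config.duration_s < 600:
        raise ValueError("duration too short to place a sleep cycle (< 600 s)")
    base = rng or config.rng("hypnogram")
    reach = _reachable(config.transitions, config.initial_state)
    need_both = (config.duration_s >= 1800 and NREM in reach and REM in reach)
    for _ in range(200):
        starts, ends, states = [], [], []
        t = 0.0
        s = config.initial_state
        while t < config.duration_s:
            d = _draw_dwell(base, s, config.dwell)
            end = min(t + d, config.duration_s)
            starts.append(t)
            ends.append(end)
            states.append(s)
            t = end
            opts = config.transitions.get(s, {})
            if not opts:
                break
            labels = sorted(opts)
            probs = np.array([opts[k] for k in labels], dtype=float)
            s = labels[base.choice(len(labels), p=probs / probs.sum())]
        if t < config.duration_s:  # absorbing state ended the chain early
            ends[-1] = config.duration_s
        hyp = Hypnogram(np.array(starts), np.array(ends),
                        np.array(states, dtype=object))
        if not need_both:
            return hyp
        durs = hyp.ends - hyp.starts
        if np.any((hyp.states == NREM) & (durs > 50)) and \
           np.any((hyp.states == REM) & (durs > 50)):
            return hyp
    raise RuntimeError("could not draw a hypnogram with NREM and REM epochs > 50 s")


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def simulate_state_poisson(hypnogram: Hypnogram, rates: dict, rng) -> np.ndarray:
    """Inhomogeneous Poisson spike train with state-constant rates (Hz)."""
    chunks = []
    for lo, hi, st in zip(hypnogram.starts, hypnogram.ends, hypnogram.states):
        lam = float(rates.get(st, 0.0))
        if lam < 0:
            raise ValueError(f"negative rate for state {st}")
        if lam == 0:
            continue
        n = rng.poisson(lam * (hi - lo))
        if n:
            chunks.append(rng.uniform(lo, hi, size=n))
    if not chunks:
        return np.empty(0)
    t = np.sort(np.concatenate(chunks))
    return np.unique(t)


def generate_units(config: SynthConfig, hypnogram: Hypnogram,
                   rng=None) -> tuple:
    """State-modulated Poisson units for all three regions + rate truth."""
    rng = rng or config.rng("units")
    units, rows = [], []
    for region in REGIONS:
        for k in range(config.n_units_per_region):
            uid = f"{region}_{k:03d}"
            lam_n = float(np.exp(rng.uniform(*np.log(config.base_rate_range))))
            ratio = float(np.exp(rng.uniform(*np.log(config.rem_nrem_ratio_range))))
            lam_r = lam_n * ratio
            lam_w = float(np.sqrt(lam_n * lam_r))
            rates = {NREM: lam_n, REM: lam_r, WAKE: lam_w, MA: lam_n}
            t = simulate_state_poisson(hypnogram, rates, rng)
            units.append(SpikeTrain(uid, t, region, 0))
            rows.append((uid, region, lam_n, lam_r, lam_w, ratio))
    truth = pd.DataFrame(rows, columns=["unit_id", "region", "rate_nrem",
                                        "rate_rem", "rate_wake", "rem_nrem_ratio"])
    return units, truth


# ---------------------------------------------------------------------------
# LFP + event injection
# ---------------------------------------------------------------------------

def one_over_f_noise(n: int, fs: float, rng, exponent: float = 1.0) -> np.ndarray:
    """Gaussian noise with 1/f^exponent power spectrum, unit SD."""
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(white) * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _schedule_events(rng, intervals: np.ndarray, n: int, dur_range: tuple,
                     min_gap: float) -> np.ndarray:
    """Place n non-overlapping [start, end) events inside the given
    intervals (each fully within one interval), >= min_gap apart."""
    iv = as_intervals(intervals)
    if len(iv) == 0 or n == 0:
        return np.empty((0, 2))
    lens = iv[:, 1] - iv[:, 0]
    placed = []
    tries = 0
    while len(placed) < n and tries < 200 * max(n, 1):
        tries += 1
        dur = rng.uniform(*dur_range)
        i = rng.choice(len(iv), p=lens / lens.sum())
        lo, hi = iv[i]
        if hi - lo <= dur + 0.2:
            continue
        start = rng.uniform(lo + 0.1, hi - dur - 0.1)
        ok = all(start - (s2 + d2) >= min_gap or s2 - (start + dur) >= min_gap
                 for s2, d2 in placed)
        if ok:
            placed.append((start, dur))
    out = np.array([(s, s + d) for s, d in sorted(placed)])
    return out.reshape(-1, 2)


def _burst(t_rel: np.ndarray, dur: float, freq: float, kind: str) -> np.ndarray:
    """Unit-amplitude oscillation burst envelope x carrier on [0, dur).

    Ripples get a Gaussian envelope; HFO/cRipple/spindle bursts use a
    flat-topped Tukey envelope so the supra-threshold run spans close to
    the nominal duration (the cRipple detector requires >= 50 ms above
    threshold).
    """
    carrier = np.sin(2 * np.pi * freq * t_rel)
    if kind == "SWR":
        env = np.exp(-0.5 * ((t_rel - dur / 2) / (dur / 5)) ** 2)
    else:
        from scipy.signal.windows import tukey
        env = tukey(t_rel.size, alpha=0.4 if kind != "spindle" else 0.5)
        # mild central emphasis keeps the power peak at the burst center
        # without narrowing the supra-threshold run
        env = env * np.exp(-0.5 * ((t_rel - dur / 2) / (dur / 2.5)) ** 2)
    return carrier * env


def _band_sd(trace: np.ndarray, fs: float, band) -> float:
    return float(np.std(bandpass(trace, fs, band)))


def embed_oscillations(config: SynthConfig, hypnogram: Hypnogram, units: list,
                       rng=None) -> tuple:
    """Build LFP with injected events and apply spike-rate gains.

    Returns (lfp, updated_units, truth) where ``truth`` is a GroundTruth
    holding injected intervals per kind, per-unit gains, and shock gains.
    """
    rng = rng or config.rng("lfp")
    fs = config.fs_lfp
    n = int(round(config.duration_s * fs))
    channels = [
        {"name": "vCA1_sup", "region": "vCA1", "shank": 0, "depth_order": 0},
        {"name": "vCA1_deep", "region": "vCA1", "shank": 0, "depth_order": 1},
        {"name": "PL5_ch0", "region": "PL5", "shank": 0, "depth_order": 0},
        {"name": "PL5_ch1", "region": "PL5", "shank": 0, "depth_order": 1},
        {"name": "PL5_ch2", "region": "PL5", "shank": 0, "depth_order": 2},
        {"name": "BLA_ch0", "region": "BLA", "shank": 0, "depth_order": 0},
    ]
    data = np.stack([one_over_f_noise(n, fs, rng) for _ in channels])

    nrem_iv = hypnogram.intervals(NREM)
    wake_iv = hypnogram.intervals(WAKE)
    nrem_min = hypnogram.state_duration(NREM) / 60.0
    wake_min = hypnogram.state_duration(WAKE) / 60.0

    events = {}
    for kind in EVENT_KINDS:
        rate = config.event_rates.get(kind, 0.0)
        n_ev = int(round(rate * nrem_min))
        iv = _schedule_events(rng, nrem_iv, n_ev,
                              config.event_duration_ranges[kind],
                              MIN_EVENT_GAP_S[kind])
        if kind == "SWR":
            n_wake = int(round(config.event_rates.get("SWR_wake", 0.0) * wake_min))
            ivw = _schedule_events(rng, wake_iv, n_wake,
                                   config.event_duration_ranges[kind],
                                   MIN_EVENT_GAP_S[kind])
            iv = np.vstack([iv, ivw]) if len(ivw) else iv
            iv = iv[np.argsort(iv[:, 0])] if len(iv) else iv
        events[kind] = iv

    # injection amplitudes relative to band-limited background SD
    sw_flags = np.ones(len(events["SWR"]), dtype=bool)
    if len(events["SWR"]):
        sw_flags = rng.uniform(size=len(events["SWR"])) < config.swr_sharpwave_fraction
    i_sup, i_deep = 0, 1
    i_pl = (2, 3, 4)
    i_bla = 5
    kind_channels = {"SWR": (i_sup, i_deep), "HFO": (i_bla,),
                     "cRipple": i_pl, "spindle": i_pl}
    sw_diff_sd = _band_sd(data[i_sup] - data[i_deep], fs, (2.0, 40.0))
    for kind, iv in events.items():
        if len(iv) == 0:
            continue
        chans = kind_channels[kind]
        amp = config.event_amp_sd * _band_sd(data[chans[0]], fs, EVENT_BAND[kind])
        for j, (lo, hi) in enumerate(iv):
            dur = hi - lo
            i0 = int(round(lo * fs))
            i1 = min(n, int(round(hi * fs)))
            t_rel = np.arange(i1 - i0) / fs
            burst = amp * _burst(t_rel, dur, EVENT_FREQ_HZ[kind], kind)
            for c in chans:
                data[c, i0:i1] += burst
            if kind == "SWR" and sw_flags[j]:
                sw_dur = 0.12
                c0 = (lo + hi) / 2.0
                j0 = max(0, int(round((c0 - sw_dur / 2) * fs)))
                j1 = min(n, int(round((c0 + sw_dur / 2) * fs)))
                tt = np.arange(j1 - j0) / fs
                env = np.exp(-0.5 * ((tt - sw_dur / 2) / (sw_dur / 6)) ** 2)
                data[i_sup, j0:j1] -= config.sharpwave_amp_sd * sw_diff_sd * env

    lfp = LfpSet(data.astype(np.float32), fs, channels)

    # spike-rate gains inside events + shock transients
    region_kinds = {"vCA1": ("SWR",), "PL5": ("cRipple", "spindle"),
                    "BLA": ("HFO",)}
    rate_lookup = _state_rate_lookup(hypnogram)
    gain_rows, shock_rows = [], []
    new_units = []
    for u in units:
        gains = {}
        for kind in region_kinds.get(u.region, ()):
            g = float(np.exp(rng.uniform(*np.log(config.event_gain_range))))
            gains[kind] = g
            gain_rows.append((u.unit_id, kind, g))
        shock_g = 1.0
        if len(config.shock_times):
            shock_g = float(np.exp(rng.uniform(*np.log(config.shock_gain_range))))
            shock_rows.append((u.unit_id, shock_g))
        t = u.times
        seg_iv, seg_gain = _gain_segments(
            {k: events[k] for k in gains}, gains,
            [(s, s + config.shock_duration_s) for s in config.shock_times], shock_g)
        if len(seg_iv):
            t = _apply_gain(t, seg_iv, seg_gain, rate_lookup, u, rng)
        new_units.append(SpikeTrain(u.unit_id, t, u.region, u.shank,
                                    rates=u.rates))

    truth = GroundTruth(
        hypnogram=hypnogram,
        unit_gains=pd.DataFrame(gain_rows, columns=["unit_id", "kind", "gain"]),
        events={k: np.column_stack([v, v.mean(axis=1)]) if len(v)
                else np.empty((0, 3)) for k, v in events.items()},
        swr_has_sharpwave=sw_flags,
        shock_gains=pd.DataFrame(shock_rows, columns=["unit_id", "shock_gain"]),
    )
    return lfp, new_units, truth


def _state_rate_lookup(hypnogram: Hypnogram):
    starts = hypnogram.starts

    def lookup(t: float, rates: dict) -> float:
        i = np.searchsorted(starts, t, side="right") - 1
        i = max(0, min(i, len(starts) - 1))
        return rates.get(hypnogram.states[i], 0.0)

    return lookup


def _gain_segments(events_by_kind: dict, gains: dict, shock_iv, shock_gain):
    """Elementary [start, end) segments with multiplicative total gain != 1."""
    edges = set()
    tagged = []  # (lo, hi, gain)
    for kind, iv in events_by_kind.items():
        g = gains[kind]
        for lo, hi in np.asarray(iv).reshape(-1, 2):
            tagged.append((lo, hi, g))
    if shock_gain != 1.0:
        for lo, hi in shock_iv:
            tagged.append((lo, hi, shock_gain))
    if not tagged:
        return np.empty((0, 2)), np.empty(0)
    for lo, hi, _ in tagged:
        edges.add(lo)
        edges.add(hi)
    edges = np.array(sorted(edges))
    seg_iv, seg_gain = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        g = 1.0
        mid = (a + b) / 2.0
        for lo, hi, gg in tagged:
            if lo <= mid < hi:
                g *= gg
        if g != 1.0:
            seg_iv.append((a, b))
            seg_gain.append(g)
    return np.asarray(seg_iv).reshape(-1, 2), np.asarray(seg_gain)


def _apply_gain(times: np.ndarray, seg_iv: np.ndarray, seg_gain: np.ndarray,
                rate_lookup, unit: SpikeTrain, rng) -> np.ndarray:
    """Thin (gain < 1) or superpose (gain > 1) spikes inside gain segments.

    Thinning a Poisson process with probability g, and superposing an
    independent Poisson of rate (g - 1) * lambda, both yield the target
    rate g * lambda exactly.
    """
    # base rates per unit are carried in closure form through rate_lookup
    keep = np.ones(times.size, dtype=bool)
    extra = []
    lam_cache = unit.rates
    for (lo, hi), g in zip(seg_iv, seg_gain):
        in_seg = (times >= lo) & (times < hi)
        if g < 1.0:
            drop = in_seg & (rng.uniform(size=times.size) >= g)
            keep &= ~drop
        elif g > 1.0:
            lam = _segment_rate(times, lo, hi, lam_cache, rate_lookup)
            n_new = rng.poisson(lam * (g - 1.0) * (hi - lo))
            if n_new:
                extra.append(rng.uniform(lo, hi, size=n_new))
    t = times[keep]
    if extra:
        t = np.sort(np.concatenate([t] + extra))
    return np.unique(t)


def _segment_rate(times, lo, hi, lam_cache, rate_lookup) -> float:
    if lam_cache is not None:
        return rate_lookup((lo + hi) / 2.0, lam_cache)
    # fall back on the local empirical rate just around the segment
    pad = max(5.0, hi - lo)
    n_local = int(np.count_nonzero((times >= lo - pad) & (times < hi + pad)))
    return n_local / (2 * pad + (hi - lo))


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

def generate_session(config: SynthConfig, out_dir) -> sio.SessionBundle:
    """Generate and write a complete session; returns the loaded bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hyp = generate_hypnogram(config)
    units, unit_rates = generate_units(config, hyp)
    # attach true rates so event-gain superposition uses exact state rates
    for u, row in zip(units, unit_rates.itertuples()):
        u.rates = {NREM: row.rate_nrem, REM: row.rate_rem,
                   WAKE: row.rate_wake, MA: row.rate_nrem}
    lfp, units, truth = embed_oscillations(config, hyp, units)
    truth.unit_rates = unit_rates

    files = {}
    sio.write_intervals(np.column_stack([hyp.starts, hyp.ends]), hyp.states,
                        out / "hypnogram.tsv")
    files["hypnogram"] = "hypnogram.tsv"
    sio.write_spikes(units, out / "spikes.tsv", out / "units.tsv")
    files["spikes"] = "spikes.tsv"
    files["units"] = "units.tsv"
    sio.write_lfp(lfp, out / "lfp.dat", out / "lfp.json")
    files["lfp"] = "lfp.dat"
    files["lfp_sidecar"] = "lfp.json"
    rows = []
    for s in config.cs_times:
        rows.append((s, s + 30.0, "CS"))
    for s in config.shock_times:
        rows.append((s, s + config.shock_duration_s, "US"))
    bdf = pd.DataFrame(sorted(rows), columns=["start_s", "end_s", "label"])
    sio.write_tsv(bdf, out / "behavior.tsv", float_fmt="%.7f")
    files["behavior"] = "behavior.tsv"

    ev_rows = []
    for kind, arr in truth.events.items():
        for (lo, hi, c), flag in zip(
                arr, truth.swr_has_sharpwave if kind == "SWR"
                else np.ones(len(arr), dtype=bool)):
            ev_rows.append((kind, lo, hi, c, int(flag)))
    sio.write_tsv(pd.DataFrame(ev_rows, columns=["kind", "start_s", "end_s",
                                                 "center_s", "has_sharpwave"]),
                  out / "events_truth.tsv", float_fmt="%.7f")
    files["truth_events"] = "events_truth.tsv"
    sio.write_tsv(truth.unit_rates, out / "unit_rates_truth.tsv")
    files["truth_unit_rates"] = "unit_rates_truth.tsv"
    sio.write_tsv(truth.unit_gains, out / "unit_gains_truth.tsv")
    files["truth_unit_gains"] = "unit_gains_truth.tsv"
    sio.write_tsv(truth.shock_gains, out / "shock_gains_truth.tsv")
    files["truth_shock_gains"] = "shock_gains_truth.tsv"

    manifest = {
        "format": "sleepspike-session/1",
        "seed": config.seed,
        "fs_lfp": config.fs_lfp,
        "duration_s": config.duration_s,
        "regions": {c["name"]: c["region"] for c in lfp.channels},
        "n_channels": len(lfp.channels),
        "n_samples": lfp.n_samples,
        "files": files,
        "counts": {"units": len(units),
                   "spikes": int(sum(u.n_spikes for u in units)),
                   "hypnogram_epochs": len(hyp),
                   "events": {k: int(len(v)) for k, v in truth.events.items()}},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True) + "\n")
    bundle = sio.load_session(out / "manifest.json")
    bundle.truth["ground"] = truth
    return bundle
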