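"""Detection of fast network oscillations from LFP.

Four event classes are covered:

* SWR - hippocampal ripple (100-250 Hz band-power) that co-occurs with a
  negative sharp-wave on the deep/superficial channel difference;
  detected in NREM and wakefulness, never REM.
* HFO - amygdalar 90-180 Hz oscillation, NREM only.
* cRipple - prelimbic 90-180 Hz oscillation, NREM only.
* Spindle - prelimbic 9-18 Hz oscillation found on Morlet-wavelet power,
  NREM only.

The threshold engine works on band-limited RMS power z-scored against NREM
baseline samples, which makes every detector invariant to LFP amplitude
scaling. Band-pass filtering is a zero-phase 4th-order Butterworth; the
moving RMS is evaluated at every sample with a centered window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import signal as sig
from scipy.ndimage import uniform_filter1d

from .core import (NREM, REM, WAKE, Hypnogram, LfpSet, OscEvent, as_intervals,
                   intersect_intervals, spikes_in_intervals, total_duration)


@dataclass
class DetectorParams:
    band: tuple          # Hz (low, high)
    rms_window_ms: float
    enter_z: float
    peak_z: float
    min_dur_ms: float
    merge_gap_ms: float
    max_dur_ms: float = None  # None = no upper bound at this stage

    def __post_init__(self):
        if self.enter_z > self.peak_z:
            raise ValueError("enter_z must not exceed peak_z")
        if self.max_dur_ms is not None and not (self.min_dur_ms < self.max_dur_ms):
            raise ValueError("min_dur_ms must be < max_dur_ms")


RIPPLE_PARAMS = DetectorParams(band=(100.0, 250.0), rms_window_ms=13.3,
                               enter_z=1.5, peak_z=4.0, min_dur_ms=30.0,
                               merge_gap_ms=10.0)
HFO_PARAMS = DetectorParams(band=(90.0, 180.0), rms_window_ms=20.0,
                            enter_z=2.0, peak_z=4.0, min_dur_ms=30.0,
                            merge_gap_ms=20.0, max_dur_ms=750.0)
CRIPPLE_PARAMS = DetectorParams(band=(90.0, 180.0), rms_window_ms=20.0,
                                enter_z=3.0, peak_z=5.0, min_dur_ms=50.0,
                                merge_gap_ms=30.0, max_dur_ms=750.0)
SHARPWAVE_BAND = (2.0, 40.0)
SHARPWAVE_ENTER_Z = -2.5
SHARPWAVE_DUR_MS = (20.0, 400.0)
SWR_MAX_DUR_MS = 750.0
SPINDLE_BAND = (9.0, 18.0)
SPINDLE_N_SCALES = 11
SPINDLE_ENTER_Z = 1.4
SPINDLE_PEAK_Z = 2.0
SPINDLE_MIN_DUR_MS = 350.0

#: peak-power thresholds of the stringent robustness re-analysis
#: (SWR, HFO, cRipple, spindle)
STRINGENT_PEAK_Z = {"SWR": 5.0, "HFO": 5.0, "cRipple": 6.0, "spindle": 3.0}


@dataclass
class PowerTrace:
    """Z-scored band power on the LFP sample grid."""

    z: np.ndarray
    fs: float
    band: tuple
    window_ms: float
    baseline: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.z.size) / self.fs


def bandpass(x: np.ndarray, fs: float, band) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass."""
    lo, hi = band
    if fs <= 2 * hi:
        raise ValueError(f"sampling rate {fs} Hz too low for band {band}")
    sos = sig.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sig.sosfiltfilt(sos, np.asarray(x, dtype=float))


def _interval_mask(n: int, fs: float, intervals) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for lo, hi in as_intervals(intervals):
        i0 = max(0, int(np.ceil(lo * fs)))
        i1 = min(n, int(np.ceil(hi * fs)))
        mask[i0:i1] = True
    return mask


def zscore_trace(x: np.ndarray, fs: float, baseline_intervals) -> np.ndarray:
    """Z-score a sample-grid trace by its mean/SD over baseline intervals."""
    mask = _interval_mask(x.size, fs, baseline_intervals)
    if not mask.any():
        raise ValueError("empty baseline for z-scoring")
    mu = float(np.mean(x[mask]))
    sd = float(np.std(x[mask]))
    if sd == 0:
        raise ValueError("zero-variance baseline")
    return (x - mu) / sd


def band_rms_z(lfp_channel, fs: float, band, rms_window_ms: float,
               baseline_intervals) -> PowerTrace:
    """Band-pass, moving-RMS, NREM-z-scored power trace."""
    filt = bandpass(lfp_channel, fs, band)
    n_win = max(1, int(round(rms_window_ms / 1000.0 * fs)))
    rms = np.sqrt(uniform_filter1d(filt**2, size=n_win, mode="nearest"))
    z = zscore_trace(rms, fs, baseline_intervals)
    return PowerTrace(z=z, fs=fs, band=tuple(band), window_ms=rms_window_ms,
                      baseline=as_intervals(baseline_intervals))


def _runs_above(z: np.ndarray, thr: float) -> np.ndarray:
    """(n, 2) sample-index runs where z > thr, half-open."""
    above = z > thr
    if not above.any():
        return np.empty((0, 2), dtype=int)
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    return np.column_stack([starts, ends])


def detect_threshold_events(power: PowerTrace, params: DetectorParams,
                            kind: str = "event", source: str = "") -> list:
    """Supra-threshold runs -> merge close candidates -> peak/duration gates."""
    fs = power.fs
    runs = _runs_above(power.z, params.enter_z)
    if len(runs) == 0:
        return []
    # merge in the integer sample domain to keep gap comparisons exact
    gap_samples = params.merge_gap_ms / 1000.0 * fs
    merged = [list(runs[0])]
    for lo, hi in runs[1:]:
        if lo - merged[-1][1] < gap_samples:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    out = []
    for i0, i1 in merged:
        dur_ms = (i1 - i0) / fs * 1000.0
        if dur_ms < params.min_dur_ms:
            continue
        if params.max_dur_ms is not None and dur_ms >= params.max_dur_ms:
            continue
        i_pk = i0 + int(np.argmax(power.z[i0:i1]))
        pk = float(power.z[i_pk])
        if pk < params.peak_z:
            continue
        out.append(OscEvent(kind=kind, start=i0 / fs, end=i1 / fs,
                            peak_time=i_pk / fs, peak_z=pk, source=source))
    return out


def concatenate_overlapping(events: list, kind: str = None) -> list:
    """Union-span events with nonempty pairwise intersection (e.g. the same
    oscillation seen on several channels/shanks); peak = strongest
    contributor."""
    if not events:
        return []
    evs = sorted(events, key=lambda e: (e.start, e.end))
    out = [evs[0]]
    for e in evs[1:]:
        last = out[-1]
        if e.start < last.end:  # nonempty intersection
            best = e if e.peak_z > last.peak_z else last
            out[-1] = OscEvent(kind=kind or last.kind, start=last.start,
                               end=max(last.end, e.end), peak_time=best.peak_time,
                               peak_z=best.peak_z,
                               source=last.source if best is last else e.source)
        else:
            out.append(e if kind is None else
                       OscEvent(kind, e.start, e.end, e.peak_time, e.peak_z, e.source))
    return out


def _state_filter(events: list, hyp: Hypnogram, allowed_states) -> list:
    allowed = np.vstack([hyp.intervals(s) for s in allowed_states]) \
        if allowed_states else np.empty((0, 2))
    allowed = allowed[np.argsort(allowed[:, 0])] if len(allowed) else allowed
    peaks = np.array([e.peak_time for e in events])
    keep = spikes_in_intervals(peaks, allowed)
    return [e for e, k in zip(events, keep) if k]


def detect_ripple_band_events(lfp: LfpSet, hyp: Hypnogram, region: str,
                              kind: str, params: DetectorParams,
                              per_shank_median: bool = False) -> list:
    """Shared engine for HFO (per-shank median LFP) and cRipple (per
    channel); candidates overlapping across shanks/channels are
    concatenated, and only NREM events are kept."""
    baseline = hyp.intervals(NREM)
    if len(baseline) == 0:
        raise ValueError("no NREM epochs for baseline")
    chans = lfp.channel_index(region=region)
    if not chans:
        raise ValueError(f"no channels in region {region}")
    events = []
    if per_shank_median:
        shanks = sorted({lfp.channels[i]["shank"] for i in chans})
        for sh in shanks:
            idx = [i for i in chans if lfp.channels[i]["shank"] == sh]
            trace = np.median(lfp.data[idx].astype(float), axis=0)
            pw = band_rms_z(trace, lfp.fs, params.band, params.rms_window_ms, baseline)
            events += detect_threshold_events(pw, params, kind=kind,
                                              source=f"{region}/shank{sh}")
    else:
        for i in chans:
            pw = band_rms_z(lfp.data[i].astype(float), lfp.fs, params.band,
                            params.rms_window_ms, baseline)
            events += detect_threshold_events(pw, params, kind=kind,
                                              source=lfp.channels[i]["name"])
    events = concatenate_overlapping(events, kind=kind)
    if params.max_dur_ms is not None:
        events = [e for e in events if e.duration * 1000.0 < params.max_dur_ms]
    return _state_filter(events, hyp, (NREM,))


def detect_hfo(lfp: LfpSet, hyp: Hypnogram, params: DetectorParams = None) -> list:
    return detect_ripple_band_events(lfp, hyp, "BLA", "HFO",
                                     params or HFO_PARAMS, per_shank_median=True)


def detect_cripple(lfp: LfpSet, hyp: Hypnogram, params: DetectorParams = None) -> list:
    return detect_ripple_band_events(lfp, hyp, "PL5", "cRipple",
                                     params or CRIPPLE_PARAMS, per_shank_median=False)


def detect_sharpwaves(lfp: LfpSet, hyp: Hypnogram, region: str = "vCA1",
                      shank: int = 0) -> list:
    """Sharp-waves on the superficial-minus-deep channel difference.

    2-40 Hz band-passed, NREM-z-scored; candidates are runs below -2.5 z
    lasting 20-400 ms; the trough is the z minimum.
    """
    i_sup, i_deep = lfp.shank_pair(region, shank)
    diff = lfp.data[i_sup].astype(float) - lfp.data[i_deep].astype(float)
    filt = bandpass(diff, lfp.fs, SHARPWAVE_BAND)
    z = zscore_trace(filt, lfp.fs, hyp.intervals(NREM))
    runs = _runs_above(-z, -SHARPWAVE_ENTER_Z)
    out = []
    for i0, i1 in runs:
        dur_ms = (i1 - i0) / lfp.fs * 1000.0
        if not (SHARPWAVE_DUR_MS[0] <= dur_ms <= SHARPWAVE_DUR_MS[1]):
            continue
        i_tr = i0 + int(np.argmin(z[i0:i1]))
        out.append(OscEvent("sharpwave", i0 / lfp.fs, i1 / lfp.fs,
                            i_tr / lfp.fs, float(z[i_tr]),
                            source=f"{region}/shank{shank}"))
    return out


def detect_swr(lfp: LfpSet, hyp: Hypnogram, params: DetectorParams = None,
               region: str = "vCA1") -> list:
    """Ripples co-occurring with a same-shank sharp-wave trough.

    Per channel: 100-250 Hz RMS (13.3 ms windows) > 1.5 z candidates, peak
    >= 4 z, duration >= 30 ms, gaps < 10 ms merged; same-shank overlapping
    candidates concatenated. A candidate containing >= 1 same-shank
    sharp-wave trough becomes an SWR candidate; cross-shank overlaps are
    concatenated and events >= 750 ms dropped. Detected during NREM and
    wakefulness only.
    """
    params = params or RIPPLE_PARAMS
    baseline = hyp.intervals(NREM)
    if len(baseline) == 0:
        raise ValueError("no NREM epochs for baseline")
    chans = lfp.channel_index(region=region)
    if not chans:
        raise ValueError(f"no channels in region {region}")
    shanks = sorted({lfp.channels[i]["shank"] for i in chans})
    swr_cands = []
    for sh in shanks:
        idx = [i for i in chans if lfp.channels[i]["shank"] == sh]
        cands = []
        for i in idx:
            pw = band_rms_z(lfp.data[i].astype(float), lfp.fs, params.band,
                            params.rms_window_ms, baseline)
            cands += detect_threshold_events(pw, params, kind="ripple",
                                             source=lfp.channels[i]["name"])
        cands = concatenate_overlapping(cands, kind="ripple")
        troughs = np.array([sw.peak_time for sw in
                            detect_sharpwaves(lfp, hyp, region=region, shank=sh)])
        for c in cands:
            if np.any((troughs >= c.start) & (troughs < c.end)):
                swr_cands.append(OscEvent("SWR", c.start, c.end, c.peak_time,
                                          c.peak_z, source=f"{region}/shank{sh}"))
    swrs = concatenate_overlapping(swr_cands, kind="SWR")
    swrs = [e for e in swrs if e.duration * 1000.0 < SWR_MAX_DUR_MS]
    return _state_filter(swrs, hyp, (NREM, WAKE))


# ---------------------------------------------------------------------------
# spindles (Morlet wavelet power)
# ---------------------------------------------------------------------------

def morlet_power(x: np.ndarray, fs: float, freqs) -> np.ndarray:
    """|CWT|^2 of a real trace with a Morlet mother wavelet (omega0 = 6).

    FFT-domain implementation; per-scale normalization constants are
    irrelevant downstream because every scale is z-scored before use.
    Returns an (n_scales, n_samples) float64 power array.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    omega0 = 6.0
    nfft = sfft.next_fast_len(n + 4096)
    xh = sfft.fft(x - x.mean(), nfft)
    w = 2.0 * np.pi * sfft.fftfreq(nfft, d=1.0 / fs)
    fourier_factor = (omega0 + np.sqrt(2.0 + omega0**2)) / (4.0 * np.pi)
    out = np.empty((len(freqs), n))
    for k, f in enumerate(freqs):
        s = fourier_factor / f
        psi = np.where(w > 0, np.exp(-0.5 * (s * w - omega0) ** 2), 0.0)
        wt = sfft.ifft(xh * psi)[:n]
        out[k] = np.abs(wt) ** 2
    return out


def spindle_power_trace(lfp: LfpSet, hyp: Hypnogram, region: str = "PL5",
                        band=SPINDLE_BAND, n_scales: int = SPINDLE_N_SCALES) -> PowerTrace:
    """Spindle power: per-scale NREM-z-scored Morlet power, max over scales.

    The channel-average prelimbic LFP is transformed on ``n_scales``
    log-spaced center frequencies spanning the 9-18 Hz band.
    """
    chans = lfp.channel_index(region=region)
    if not chans:
        raise ValueError(f"no channels in region {region}")
    trace = np.mean(lfp.data[chans].astype(float), axis=0)
    freqs = np.geomspace(band[0], band[1], n_scales)
    baseline = hyp.intervals(NREM)
    if len(baseline) == 0:
        raise ValueError("no NREM epochs for baseline")
    mask = _interval_mask(trace.size, lfp.fs, baseline)
    best = np.full(trace.size, -np.inf)
    nfft_pow = morlet_power(trace, lfp.fs, freqs)
    for k in range(len(freqs)):
        p = nfft_pow[k]
        mu, sd = float(np.mean(p[mask])), float(np.std(p[mask]))
        if sd == 0:
            raise ValueError("zero-variance spindle baseline")
        np.maximum(best, (p - mu) / sd, out=best)
    return PowerTrace(z=best, fs=lfp.fs, band=tuple(band), window_ms=0.0,
                      baseline=baseline)


def detect_spindles(lfp: LfpSet, hyp: Hypnogram, peak_z: float = SPINDLE_PEAK_Z,
                    enter_z: float = SPINDLE_ENTER_Z,
                    min_dur_ms: float = SPINDLE_MIN_DUR_MS,
                    region: str = "PL5") -> list:
    """Spindles: spindle power > 1.4 z sustained > 350 ms inside NREM,
    confirmed when the maximum reaches >= 2 z. The sustained run must stay
    above threshold throughout (no sub-threshold dips)."""
    pw = spindle_power_trace(lfp, hyp, region=region)
    fs = pw.fs
    runs = _runs_above(pw.z, enter_z).astype(float) / fs
    if len(runs) == 0:
        return []
    nrem = hyp.intervals(NREM)
    clipped = intersect_intervals(runs, nrem)
    out = []
    for lo, hi in clipped:
        if (hi - lo) * 1000.0 <= min_dur_ms:
            continue
        i0, i1 = int(round(lo * fs)), int(round(hi * fs))
        i_pk = i0 + int(np.argmax(pw.z[i0:i1]))
        pk = float(pw.z[i_pk])
        if pk < peak_z:
            continue
        out.append(OscEvent("spindle", lo, hi, i_pk / fs, pk, source=region))
    return out


def detect_all(lfp: LfpSet, hyp: Hypnogram, stringent: bool = False) -> dict:
    """Run all four detectors; ``stringent`` switches to the robustness
    peak thresholds (z > 5, 5, 6, 3 for SWR/HFO/cRipple/spindle)."""
    from dataclasses import replace
    rp, hp, cp = RIPPLE_PARAMS, HFO_PARAMS, CRIPPLE_PARAMS
    sp_peak = SPINDLE_PEAK_Z
    if stringent:
        rp = replace(rp, peak_z=STRINGENT_PEAK_Z["SWR"])
        hp = replace(hp, peak_z=STRINGENT_PEAK_Z["HFO"])
        cp = replace(cp, peak_z=STRINGENT_PEAK_Z["cRipple"])
        sp_peak = STRINGENT_PEAK_Z["spindle"]
    return {
        "SWR": detect_swr(lfp, hyp, rp),
        "HFO": detect_hfo(lfp, hyp, hp),
        "cRipple": detect_cripple(lfp, hyp, cp),
        "spindle": detect_spindles(lfp, hyp, peak_z=sp_peak),
    }


def event_summary(events: list, state_intervals) -> dict:
    """Duration quartiles (ms) and occurrence rate (events/s of state time)."""
    tot = total_duration(state_intervals)
    durs = np.array([e.duration * 1000.0 for e in events])
    rate = len(events) / tot if tot > 0 else np.nan
    if durs.size:
        q1, med, q3 = np.percentile(durs, [25, 50, 75])
    else:
        q1 = med = q3 = np.nan
    return {"n": len(events), "rate_per_s": rate,
            "dur_ms_q1": float(q1), "dur_ms_median": float(med),
            "dur_ms_q3": float(q3)}
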