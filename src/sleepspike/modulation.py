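"""Firing-rate modulation by oscillatory events, sleep time, and shocks.

Covers peri-event time histograms around event power peaks, FR gain inside
versus outside an event class, sleep-long firing trends across extended
sleep, within-event FR change between the first and last NREM epoch, shock
PSTH gain, and censoring of spikes around shock-artifact pulses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import (as_intervals, count_spikes_per_interval,
                   events_to_intervals, spikes_in_intervals,
                   subtract_intervals, total_duration)
from .stats import spearman

#: PETH bin / smoothing defaults per event kind (ms)
PETH_PARAMS = {
    "SWR": (10.0, 50.0, 500.0),
    "HFO": (10.0, 50.0, 500.0),
    "cRipple": (10.0, 50.0, 500.0),
    "spindle": (50.0, 250.0, 2000.0),
}


@dataclass
class Peth:
    lags: np.ndarray       # bin centers, s
    mean_rate: np.ndarray  # Hz, event-averaged smoothed rate
    per_event: np.ndarray  # (n_events, n_bins) smoothed rates
    bin_ms: float
    sigma_ms: float


@dataclass
class GainResult:
    unit_id: str
    fr_in: float
    fr_out: float
    gain: float
    flag: str = ""


def peri_event_rate(spike_times, event_peaks, kind: str = "SWR",
                    bin_ms: float = None, sigma_ms: float = None,
                    window_ms: float = None) -> Peth:
    """Event-peak-aligned firing rate (per-event binned, Gaussian-smoothed,
    then event-averaged). Kind presets: 10-ms bins / sigma 50 ms for
    ripple-class events, 50-ms bins / sigma 250 ms for spindles."""
    d_bin, d_sig, d_win = PETH_PARAMS.get(kind, PETH_PARAMS["SWR"])
    bin_ms = d_bin if bin_ms is None else bin_ms
    sigma_ms = d_sig if sigma_ms is None else sigma_ms
    window_ms = d_win if window_ms is None else window_ms
    peaks = np.asarray(event_peaks, dtype=float)
    if peaks.size == 0:
        raise ValueError("need >= 1 event")
    t = np.asarray(spike_times, dtype=float)
    half = window_ms / 1000.0
    w_bin = bin_ms / 1000.0
    n_half = int(round(half / w_bin))
    edges = (np.arange(2 * n_half + 1) - n_half) * w_bin
    centers = (edges[:-1] + edges[1:]) / 2.0
    mat = np.empty((peaks.size, centers.size))
    for i, pk in enumerate(peaks):
        counts, _ = np.histogram(t - pk, bins=edges)
        mat[i] = counts / w_bin
    mat = gaussian_filter1d(mat, sigma=sigma_ms / bin_ms, axis=1, mode="nearest")
    return Peth(centers, mat.mean(axis=0), mat, bin_ms, sigma_ms)


def fr_gain(spike_times, events, reference_intervals, unit_id: str = "") -> GainResult:
    """FR inside the events over FR outside them (within the reference
    state time). ``events`` may be OscEvents or (n, 2) intervals."""
    t = np.asarray(spike_times, dtype=float)
    if isinstance(events, np.ndarray):
        ev = as_intervals(events)
    elif len(events) == 0:
        ev = np.empty((0, 2))
    elif hasattr(events[0], "start"):
        ev = events_to_intervals(events)
    else:
        ev = as_intervals(events)
    if len(ev):
        ev = ev[np.argsort(ev[:, 0])]
    ref = as_intervals(reference_intervals)
    ev_in_ref = _clip_to_ref(ev, ref)
    dur_in = total_duration(ev_in_ref) if len(ev_in_ref) else 0.0
    out_iv = subtract_intervals(ref, ev)
    dur_out = total_duration(out_iv)
    n_in = int(np.count_nonzero(spikes_in_intervals(t, ev_in_ref))) if dur_in > 0 else 0
    n_out = int(np.count_nonzero(spikes_in_intervals(t, out_iv))) if dur_out > 0 else 0
    fr_in = n_in / dur_in if dur_in > 0 else np.nan
    fr_out = n_out / dur_out if dur_out > 0 else np.nan
    if not fr_out > 0:
        return GainResult(unit_id, fr_in, fr_out, np.nan, flag="fr_out zero or undefined")
    return GainResult(unit_id, fr_in, fr_out, fr_in / fr_out)


def _clip_to_ref(ev: np.ndarray, ref: np.ndarray) -> np.ndarray:
    from .core import intersect_intervals
    if len(ev) == 0:
        return np.empty((0, 2))
    order = np.argsort(ev[:, 0])
    return intersect_intervals(ev[order], ref)


def epoch_rates(spike_times, epochs) -> np.ndarray:
    """Mean FR (Hz) per epoch interval."""
    iv = as_intervals(epochs)
    cnt = count_spikes_per_interval(np.asarray(spike_times, dtype=float), iv)
    return cnt / (iv[:, 1] - iv[:, 0])


def zscore_unit(values: np.ndarray) -> np.ndarray:
    """Within-unit z-score across its epoch values; NaN-safe."""
    v = np.asarray(values, dtype=float)
    mu = np.nanmean(v)
    sd = np.nanstd(v)
    if not sd > 0:
        return np.zeros_like(v)
    return (v - mu) / sd


def sleep_fr_trend(spikes_by_unit: dict, extended_sleep, nrem_by_period: list,
                   n_time_bins: int = 10) -> dict:
    """FR trend across NREM epochs of extended-sleep periods.

    For each unit: epoch-mean FRs z-scored within unit (over all NREM epochs
    of all periods), Spearman rho of z-FR against time from the period's
    sleep onset to the epoch midpoint, per-period first-vs-last epoch
    difference, and a ``n_time_bins``-bin population summary.
    """
    spans = as_intervals(extended_sleep)
    rows = {}
    binned = []
    for uid, t in spikes_by_unit.items():
        frs, times, periods = [], [], []
        for p, (span, nrem) in enumerate(zip(spans, nrem_by_period)):
            nrem = as_intervals(nrem)
            if len(nrem) < 2:
                continue
            fr = epoch_rates(t, nrem)
            mid = nrem.mean(axis=1)
            frs.append(fr)
            times.append(mid - span[0])
            periods.append(np.full(len(nrem), p))
        if not frs:
            continue
        fr = np.concatenate(frs)
        tt = np.concatenate(times)
        pp = np.concatenate(periods)
        z = zscore_unit(fr)
        try:
            rho = spearman(tt, z).statistic if len(np.unique(z)) > 1 else np.nan
        except ValueError:
            rho = np.nan
        deltas = []
        for p in np.unique(pp):
            zsel = z[pp == p]
            deltas.append(zsel[-1] - zsel[0])
        rows[uid] = {"rho": rho, "delta_first_last": float(np.mean(deltas)),
                     "z": z, "t": tt}
        binned.append((tt, z))
    # population 10-bin summary over normalized time within period
    all_t = np.concatenate([b[0] for b in binned]) if binned else np.empty(0)
    all_z = np.concatenate([b[1] for b in binned]) if binned else np.empty(0)
    summary = np.full(n_time_bins, np.nan)
    if all_t.size:
        edges = np.linspace(0, all_t.max() + 1e-9, n_time_bins + 1)
        which = np.digitize(all_t, edges) - 1
        for b in range(n_time_bins):
            sel = which == b
            if sel.any():
                summary[b] = float(all_z[sel].mean())
    return {"per_unit": rows, "time_bin_mean_z": summary}


def within_event_fr_change(spike_times, events_first, events_last,
                           all_epoch_event_rates=None) -> float:
    """Last-minus-first NREM-epoch within-event FR, z-scored within unit.

    ``events_first``/``events_last``: event intervals in the first and last
    NREM epoch of an extended-sleep period. The z-normalization population
    is the unit's within-event FR over all epochs (``all_epoch_event_rates``,
    one FR per epoch); when omitted, the two epochs themselves are used.
    """
    def wev_fr(ev):
        iv = as_intervals(ev)
        if len(iv) == 0:
            raise ValueError("epoch with zero events")
        n = int(np.count_nonzero(spikes_in_intervals(
            np.asarray(spike_times, dtype=float), iv)))
        return n / total_duration(iv)

    fr_first = wev_fr(events_first)
    fr_last = wev_fr(events_last)
    pop = np.asarray(all_epoch_event_rates, dtype=float) \
        if all_epoch_event_rates is not None else np.array([fr_first, fr_last])
    mu, sd = np.nanmean(pop), np.nanstd(pop)
    if not sd > 0:
        return 0.0
    return float((fr_last - mu) / sd - (fr_first - mu) / sd)


def shock_gain(spike_times, shock_intervals, first_cs_time: float,
               bin_s: float = 0.1, baseline_s: float = 20.0,
               unit_id: str = "") -> GainResult:
    """Peak of the shock PSTH (0.1-s bins, averaged over shocks) over the
    mean FR in the 20 s preceding the first CS."""
    t = np.asarray(spike_times, dtype=float)
    iv = as_intervals(shock_intervals)
    if len(iv) == 0:
        raise ValueError("need >= 1 shock")
    dur = float(np.max(iv[:, 1] - iv[:, 0]))
    n_bins = int(round(dur / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    mat = np.empty((len(iv), n_bins))
    for i, (lo, _) in enumerate(iv):
        counts, _ = np.histogram(t - lo, bins=edges)
        mat[i] = counts / bin_s
    peak = float(mat.mean(axis=0).max())
    base_iv = [(first_cs_time - baseline_s, first_cs_time)]
    n_base = int(np.count_nonzero(spikes_in_intervals(t, base_iv)))
    fr_base = n_base / baseline_s
    if not fr_base > 0:
        return GainResult(unit_id, peak, fr_base, np.nan, flag="zero baseline FR")
    return GainResult(unit_id, peak, fr_base, peak / fr_base)


def censor_shock_artifacts(spike_times, shock_pulses,
                           pre_ms: float = 0.1, post_ms: float = 5.0) -> np.ndarray:
    """Drop spikes in [pulse_onset - 0.1 ms, pulse_offset + 5 ms).

    ``shock_pulses``: (n, 2) pulse on/off times in seconds.
    """
    t = np.asarray(spike_times, dtype=float)
    iv = as_intervals(shock_pulses)
    if len(iv) == 0:
        return t.copy()
    cens = np.column_stack([iv[:, 0] - pre_ms / 1000.0,
                            iv[:, 1] + post_ms / 1000.0])
    return t[~spikes_in_intervals(t, cens)]
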