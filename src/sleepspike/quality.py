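"""Cluster-quality and waveform metrics with the four inclusion criteria.

A sorted unit enters the analyses only if all four hold: isolation distance
> 15, refractory-period contamination low by either the ISI index (< 0.2) or
the autocorrelogram contamination rate (< 0.05), overall mean firing rate
> 0.01 Hz, and spike amplitude > 50 uV.

ISI/ACG windows are half-open in ms ([0.5, 2) etc.) to avoid double counting
at shared bounds. Both rate-ratio metrics are normalized by window length so
that a homogeneous (refractoriness-free) train scores ~1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass
class UnitQuality:
    unit_id: str
    isolation_distance: float = np.nan
    isi_index: float = np.nan
    contamination_rate: float = np.nan
    amplitude: float = np.nan   # uV
    spike_width: float = np.nan  # ms
    mean_fr: float = np.nan     # Hz
    included: bool = False


def _isi_counts(spike_times, lo_ms: float, hi_ms: float) -> int:
    """Count inter-spike intervals in the half-open window [lo, hi) ms."""
    isi_ms = np.diff(np.asarray(spike_times, dtype=float)) * 1000.0
    return int(np.count_nonzero((isi_ms >= lo_ms) & (isi_ms < hi_ms)))


def isi_index(spike_times) -> float:
    """Refractory-window ISI rate over baseline-window ISI rate.

    (count in [0.5, 2) ms / count in [2, 10) ms) * (8 / 1.5); the factor
    normalizes the 1.5 ms refractory window against the 8 ms baseline window.
    Returns NaN (criterion branch fails) when the baseline window is empty
    but the refractory window is not; 0 when both are empty.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        raise ValueError("isi_index needs >= 2 spikes")
    refr = _isi_counts(t, 0.5, 2.0)
    base = _isi_counts(t, 2.0, 10.0)
    if refr == 0:
        return 0.0
    if base == 0:
        return np.nan
    return (refr / base) * (8.0 / 1.5)


def _acg_counts(t: np.ndarray, lo_ms: float, hi_ms: float) -> int:
    """Count ordered spike pairs with positive lag in [lo, hi) ms."""
    lo = lo_ms / 1000.0
    hi = hi_ms / 1000.0
    a = np.searchsorted(t, t + lo, side="left")
    b = np.searchsorted(t, t + hi, side="left")
    return int(np.sum(b - a))


def contamination_rate(spike_times) -> float:
    """Minimum window-normalized refractory/baseline ACG rate ratio.

    For n in {1.5, 2.5, ..., 9.5} ms the refractory count ACG[0.5, n) is
    rated against two baselines, ACG[0.5, 49.5) and ACG[250, 500), each
    normalized by window length; the overall minimum over n and baselines is
    returned. NaN when both baselines are empty.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        raise ValueError("contamination_rate needs >= 2 spikes")
    base_near = _acg_counts(t, 0.5, 49.5)
    base_far = _acg_counts(t, 250.0, 500.0)
    if base_near == 0 and base_far == 0:
        return np.nan
    best = np.inf
    for n in np.arange(1.5, 9.5 + 1e-9, 1.0):
        refr = _acg_counts(t, 0.5, n)
        vals = []
        if base_near > 0:
            vals.append((refr / base_near) * 49.0 / (n - 0.5))
        if base_far > 0:
            vals.append((refr / base_far) * 250.0 / (n - 0.5))
        best = min(best, min(vals))
    return float(best)


def isolation_distance(cluster_features, noise_features) -> float:
    """Mahalanobis isolation of a cluster from same-shank noise spikes.

    Squared Mahalanobis distance (w.r.t. the cluster covariance) of the
    n_c-th nearest noise point to the cluster centroid, n_c the cluster
    size. NaN when the noise set is smaller than the cluster (standard
    convention).
    """
    c = np.asarray(cluster_features, dtype=float)
    z = np.asarray(noise_features, dtype=float)
    if c.ndim != 2 or z.ndim != 2 or c.shape[1] != z.shape[1]:
        raise ValueError("feature matrices must be 2-D with matching columns")
    n_c = c.shape[0]
    if z.shape[0] < n_c:
        return np.nan
    mu = c.mean(axis=0)
    cov = np.cov(c, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        icov = np.linalg.inv(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular cluster covariance; reduce feature space") from err
    d = z - mu
    d2 = np.einsum("ij,jk,ik->i", d, icov, d)
    return float(np.sort(d2)[n_c - 1])


def waveform_metrics(mean_waveform, fs: float) -> tuple:
    """(amplitude uV, trough-to-peak width ms) from a mean spike waveform.

    The waveform is cubic-spline upsampled to 200 kHz; baseline is the mean
    of the first 20% of samples, amplitude the trough depth below baseline,
    and width the time from the trough to the subsequent maximum (the global
    post-trough maximum for monophasic waveforms).
    """
    w = np.asarray(mean_waveform, dtype=float)
    if w.size < 4 or np.ptp(w) == 0:
        raise ValueError("waveform is flat or too short")
    t = np.arange(w.size) / fs
    fs_up = 200_000.0
    t_up = np.arange(0.0, t[-1] + 0.5 / fs_up, 1.0 / fs_up)
    w_up = CubicSpline(t, w)(t_up)
    n_base = max(1, int(round(0.2 * w_up.size)))
    baseline = float(np.mean(w_up[:n_base]))
    i_trough = int(np.argmin(w_up))
    amplitude = baseline - float(w_up[i_trough])
    if amplitude <= 0:
        raise ValueError("waveform has no trough below baseline")
    tail = w_up[i_trough:]
    i_peak = i_trough + int(np.argmax(tail))
    width_ms = (t_up[i_peak] - t_up[i_trough]) * 1000.0
    return amplitude, width_ms


def apply_inclusion_criteria(q: UnitQuality) -> bool:
    """All four criteria; NaN on a metric fails that branch."""
    def gt(v, thr):
        return (not np.isnan(v)) and v > thr

    def lt(v, thr):
        return (not np.isnan(v)) and v < thr

    ok = (
        gt(q.isolation_distance, 15.0)
        and (lt(q.isi_index, 0.2) or lt(q.contamination_rate, 0.05))
        and gt(q.mean_fr, 0.01)
        and gt(q.amplitude, 50.0)
    )
    q.included = bool(ok)
    return q.included
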