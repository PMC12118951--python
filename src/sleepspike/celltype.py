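"""Putative excitatory/inhibitory classification from CCG monosynaptic signatures.

For same-region pairs, the spike-time cross-correlogram (0.1 ms bins,
Gaussian-smoothed with sigma = 0.5 ms) is compared against 99% global bands
built from 1,000 spike-jitter surrogates (uniform jitter in [-5, +5] ms,
independently per spike per train). A significant peak (trough) in the
[+1, +4] ms lag window marks a candidate excitatory (inhibitory) connection.
Units with only excitatory or only inhibitory significant outputs are typed
by CCG evidence; the rest fall back to spike width (> 0.6 ms excitatory,
< 0.5 ms inhibitory, in between unclassified).

Manual curation of suspicious connections is approximated by an automatic
rule: a candidate is rejected when its band exceedance also covers zero lag
([-0.4, +0.4] ms) or is broader than 3 ms of contiguous bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

DETECT_WINDOW_MS = (1.0, 4.0)
BAND_WINDOW_MS = 5.0
ZERO_LAG_MS = 0.4
# a monosynaptic trough filling the whole [+1, +4] ms window is ~3 ms wide
# before smoothing, so "broad" must mean clearly wider than that
BROAD_MS = 6.0
WIDTH_EXC_MS = 0.6
WIDTH_INH_MS = 0.5


@dataclass
class CcgResult:
    lags: np.ndarray      # bin centers, ms
    counts: np.ndarray    # raw pair counts per bin
    smoothed: np.ndarray  # Gaussian-smoothed counts
    bin_ms: float = 0.1


@dataclass
class CellTypeCall:
    unit_id: str
    label: str            # excitatory | inhibitory | unclassified
    evidence: str         # ccg | width | none
    out_excitatory_count: int = 0
    out_inhibitory_count: int = 0


def _pair_lags(ref: np.ndarray, target: np.ndarray, half_window_s: float):
    """All (i, j, lag) with |target[j] - ref[i]| <= half_window_s.

    Zero-lag self pairs are excluded when the two trains are identical.
    Returns (ref_idx, tgt_idx, lags_s).
    """
    ref = np.asarray(ref, dtype=float)
    target = np.asarray(target, dtype=float)
    if ref.size == 0 or target.size == 0:
        return (np.empty(0, dtype=int), np.empty(0, dtype=int), np.empty(0))
    lo = np.searchsorted(ref, target - half_window_s, side="left")
    hi = np.searchsorted(ref, target + half_window_s, side="right")
    counts = hi - lo
    tgt_idx = np.repeat(np.arange(target.size), counts)
    ref_idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)]) \
        if counts.sum() else np.empty(0, dtype=int)
    lags = target[tgt_idx] - ref[ref_idx]
    if ref.size == target.size and np.array_equal(ref, target):
        keep = ref_idx != tgt_idx
        ref_idx, tgt_idx, lags = ref_idx[keep], tgt_idx[keep], lags[keep]
    return ref_idx, tgt_idx, lags


def _bin_edges(window_ms: float, bin_ms: float):
    n_half = int(round(window_ms / bin_ms))
    edges = (np.arange(2 * n_half + 1) - n_half) * bin_ms
    centers = (edges[:-1] + edges[1:]) / 2.0
    return edges, centers


def compute_ccg(ref_spikes, target_spikes, window_ms: float = 8.0,
                bin_ms: float = 0.1, smooth_sigma_ms: float = 0.5) -> CcgResult:
    """Cross-correlogram of (target - ref) lags; positive lag = target later."""
    if window_ms < BAND_WINDOW_MS:
        raise ValueError("window must cover at least +/-5 ms")
    edges, centers = _bin_edges(window_ms, bin_ms)
    _, _, lags = _pair_lags(np.asarray(ref_spikes, dtype=float),
                            np.asarray(target_spikes, dtype=float),
                            window_ms / 1000.0)
    counts, _ = np.histogram(lags * 1000.0, bins=edges)
    smoothed = gaussian_filter1d(counts.astype(float), sigma=smooth_sigma_ms / bin_ms,
                                 mode="constant")
    return CcgResult(lags=centers, counts=counts, smoothed=smoothed, bin_ms=bin_ms)


def jitter_global_bands(ref_spikes, target_spikes, rng,
                        n_surrogates: int = 1000, jitter_ms: float = 5.0,
                        window_ms: float = 8.0, bin_ms: float = 0.1,
                        smooth_sigma_ms: float = 0.5) -> tuple:
    """99% global bands of the smoothed CCG over [-5, +5] ms.

    Every surrogate jitters each spike of each train independently
    (uniform on [-jitter, +jitter] ms), recomputes the smoothed CCG, and
    records its extrema over the band window; the bands are the 99.5th
    percentile of the maxima and the 0.5th percentile of the minima.

    Vectorized over surrogates: only spike pairs that can fall inside the
    CCG window after jittering (|lag| <= window + 2*jitter) are tracked.
    """
    if n_surrogates < 200:
        import warnings
        warnings.warn("n_surrogates < 200: global-band quantiles are unstable")
    ref = np.asarray(ref_spikes, dtype=float)
    target = np.asarray(target_spikes, dtype=float)
    if ref.size == 0 or target.size == 0:
        return 0.0, 0.0
    j = jitter_ms / 1000.0
    reach = window_ms / 1000.0 + 2.0 * j
    ref_idx, tgt_idx, lags = _pair_lags(ref, target, reach)
    edges, centers = _bin_edges(window_ms, bin_ms)
    n_bins = centers.size
    band_sel = np.abs(centers) <= BAND_WINDOW_MS + 1e-9
    if lags.size == 0:
        return 0.0, 0.0
    maxima = np.empty(n_surrogates)
    minima = np.empty(n_surrogates)
    # chunk surrogates to bound the (chunk, n_pairs) lag matrix at ~2e7 cells
    chunk = max(1, min(n_surrogates, int(2e7 / max(1, lags.size))))
    done = 0
    while done < n_surrogates:
        m = min(chunk, n_surrogates - done)
        jit_r = rng.uniform(-j, j, size=(m, ref.size))
        jit_t = rng.uniform(-j, j, size=(m, target.size))
        lag_ms = (lags[None, :] + jit_t[:, tgt_idx] - jit_r[:, ref_idx]) * 1000.0
        b = np.floor((lag_ms - edges[0]) / bin_ms).astype(np.int64)
        ok = (b >= 0) & (b < n_bins)
        flat = (np.arange(m)[:, None] * n_bins + b)[ok]
        hist = np.bincount(flat, minlength=m * n_bins).reshape(m, n_bins).astype(float)
        sm = gaussian_filter1d(hist, sigma=smooth_sigma_ms / bin_ms, axis=1,
                               mode="constant")
        maxima[done:done + m] = sm[:, band_sel].max(axis=1)
        minima[done:done + m] = sm[:, band_sel].min(axis=1)
        done += m
    upper = float(np.percentile(maxima, 99.5))
    lower = float(np.percentile(minima, 0.5))
    return upper, lower


def detect_monosynaptic(ccg: CcgResult, bands: tuple,
                        detect_window_ms: tuple = DETECT_WINDOW_MS,
                        reject_suspicious: bool = True) -> dict:
    """Candidate connection calls from one CCG against its global bands.

    Returns {"excitatory": bool, "inhibitory": bool, "rejected": [...]};
    exceedance is strict (CCG equal to the band is not significant).
    """
    upper, lower = bands
    lags = ccg.lags
    in_det = (lags >= detect_window_ms[0]) & (lags <= detect_window_ms[1])
    out = {"excitatory": False, "inhibitory": False, "rejected": []}
    for name, exceed in (("excitatory", ccg.smoothed > upper),
                         ("inhibitory", ccg.smoothed < lower)):
        if not np.any(exceed & in_det):
            continue
        if reject_suspicious:
            zero_lag = np.any(exceed & (np.abs(lags) <= ZERO_LAG_MS))
            broad = _max_run_ms(exceed, ccg.bin_ms) > BROAD_MS
            if zero_lag or broad:
                out["rejected"].append(name)
                continue
        out[name] = True
    return out


def _max_run_ms(mask: np.ndarray, bin_ms: float) -> float:
    """Longest contiguous True run, in ms."""
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best * bin_ms


def classify_pair(ref_spikes, target_spikes, rng, n_surrogates: int = 1000,
                  **kw) -> dict:
    """Full candidate call for one ordered pair (ref -> target)."""
    ccg = compute_ccg(ref_spikes, target_spikes, **{k: v for k, v in kw.items()
                      if k in ("window_ms", "bin_ms", "smooth_sigma_ms")})
    bands = jitter_global_bands(ref_spikes, target_spikes, rng,
                                n_surrogates=n_surrogates, **kw)
    call = detect_monosynaptic(ccg, bands)
    call["bands"] = bands
    return call


def assign_cell_types(pair_calls, widths_ms: dict) -> dict:
    """Unit-level labels from directed pair calls plus spike-width fallback.

    ``pair_calls``: iterable of (ref_unit, target_unit, call) with call in
    {"excitatory", "inhibitory"}; ``widths_ms`` maps unit -> spike width
    (may be missing). Returns {unit: CellTypeCall}.
    """
    units = set(widths_ms) | {r for r, _, _ in pair_calls} | {t for _, t, _ in pair_calls}
    n_exc = {u: 0 for u in units}
    n_inh = {u: 0 for u in units}
    for ref, _, call in pair_calls:
        if call == "excitatory":
            n_exc[ref] += 1
        elif call == "inhibitory":
            n_inh[ref] += 1
    out = {}
    for u in sorted(units, key=str):
        e, i = n_exc[u], n_inh[u]
        if e > 0 and i == 0:
            out[u] = CellTypeCall(u, "excitatory", "ccg", e, i)
        elif i > 0 and e == 0:
            out[u] = CellTypeCall(u, "inhibitory", "ccg", e, i)
        else:
            w = widths_ms.get(u)
            if w is None:
                out[u] = CellTypeCall(u, "unclassified", "none", e, i)
            elif w > WIDTH_EXC_MS:
                out[u] = CellTypeCall(u, "excitatory", "width", e, i)
            elif w < WIDTH_INH_MS:
                out[u] = CellTypeCall(u, "inhibitory", "width", e, i)
            else:
                out[u] = CellTypeCall(u, "unclassified", "width", e, i)
    return out
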