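"""REM/NREM firing preference: rates, index, shuffle-null classification,
triplet profiles, and cross-session correlation/bootstrap analyses.

The REM-preference index of a unit is (FR_R - FR_N) / (FR_R + FR_N), with
FR_R and FR_N the mean firing rates over 1-s REM and NREM bins. Whether the
index deviates from chance is judged against a null built by shuffling the
REM/NREM labels across bins (n = 1,000): above the 97.5th percentile ->
REM-preferring, below the 2.5th -> NREM-preferring, otherwise
non-significant (NS). Stricter criteria are available through ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NREM, REM, Hypnogram, count_spikes_per_interval
from .stats import spearman


@dataclass
class PreferenceResult:
    unit_id: str
    fr_rem: float
    fr_nrem: float
    index: float
    null_lo: float
    null_hi: float
    label: str           # REM | NREM | NS
    n_shuffles: int
    flag: str = ""


@dataclass
class TripletProfile:
    """Per-neuron firing profile over NREM1/REM/NREM2 thirds.

    ``thirds`` holds the 9 raw mean rates (3 per epoch, averaged over
    triplets); ``z`` is the within-neuron z-scored profile.
    """
    unit_id: str
    thirds: np.ndarray   # shape (9,)
    z: np.ndarray        # shape (9,)
    n_triplets: int


def state_bins(hypnogram: Hypnogram, states=(REM, NREM)) -> tuple:
    """Whole-second bins inside usable epochs of the given states.

    Bins are laid from each epoch start; a trailing fraction < 1 s is
    dropped. Returns (bin_starts, labels) sorted by time.
    """
    starts, labels = [], []
    for st in states:
        for lo, hi in hypnogram.intervals(st, usable_only=True):
            n = int(np.floor(hi - lo))
            if n <= 0:
                continue
            starts.append(lo + np.arange(n, dtype=float))
            labels.append(np.full(n, st, dtype=object))
    if not starts:
        return np.empty(0), np.empty(0, dtype=object)
    s = np.concatenate(starts)
    l = np.concatenate(labels)
    order = np.argsort(s, kind="stable")
    return s[order], l[order]


def bin_spike_counts(spike_times, bin_starts: np.ndarray) -> np.ndarray:
    """Spike counts in the 1-s bins [start, start + 1)."""
    iv = np.column_stack([bin_starts, bin_starts + 1.0])
    if len(iv) == 0:
        return np.empty(0, dtype=int)
    return count_spikes_per_interval(np.asarray(spike_times, dtype=float), iv)


def state_rates(spike_times, hypnogram: Hypnogram) -> tuple:
    """(FR_R, FR_N): mean rate over 1-s REM and NREM bins of usable epochs.

    NaN for a state with no usable bins.
    """
    starts, labels = state_bins(hypnogram)
    counts = bin_spike_counts(spike_times, starts)
    out = []
    for st in (REM, NREM):
        sel = labels == st
        out.append(float(np.mean(counts[sel])) if sel.any() else np.nan)
    return tuple(out)


def rem_preference_index(fr_rem: float, fr_nrem: float) -> float:
    """(FR_R - FR_N) / (FR_R + FR_N), in [-1, 1]; NaN when both rates are 0."""
    tot = fr_rem + fr_nrem
    if not tot > 0:
        return np.nan
    return (fr_rem - fr_nrem) / tot


def _index_from_sums(sum_rem, n_rem, sum_nrem, n_nrem):
    fr_r = sum_rem / n_rem
    fr_n = sum_nrem / n_nrem
    tot = fr_r + fr_n
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, (fr_r - fr_n) / tot, np.nan)


def classify_preference(bin_counts, bin_state_labels, n_shuffles: int = 1000,
                        alpha: float = 0.05, rng=None,
                        unit_id: str = "") -> PreferenceResult:
    """Shuffle-null classification of one unit's REM-preference index.

    REM/NREM labels are permuted across bins preserving the number of each
    label; the observed index is compared with the surrogate percentiles at
    alpha/2 on each side (linear interpolation). Ties at the threshold are
    called NS.
    """
    counts = np.asarray(bin_counts, dtype=float)
    labels = np.asarray(bin_state_labels, dtype=object)
    is_rem = labels == REM
    is_nrem = labels == NREM
    n_rem, n_nrem = int(is_rem.sum()), int(is_nrem.sum())
    if n_rem == 0 or n_nrem == 0:
        raise ValueError("need >= 1 REM and >= 1 NREM bin")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fr_r = float(counts[is_rem].mean())
    fr_n = float(counts[is_nrem].mean())
    idx = rem_preference_index(fr_r, fr_n)
    c = counts[is_rem | is_nrem]
    if np.all(c == 0):
        return PreferenceResult(unit_id, fr_r, fr_n, np.nan, np.nan, np.nan,
                                "NS", n_shuffles, flag="all-zero counts")
    # a shuffle only needs the sum of counts over a random n_rem-bin subset
    perm = rng.permuted(np.broadcast_to(c, (n_shuffles, c.size)).copy(), axis=1)
    sum_rem = perm[:, :n_rem].sum(axis=1)
    total = c.sum()
    null = _index_from_sums(sum_rem, n_rem, total - sum_rem, n_nrem)
    lo, hi = np.nanpercentile(null, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    if idx > hi:
        label = REM
    elif idx < lo:
        label = NREM
    else:
        label = "NS"
    return PreferenceResult(unit_id, fr_r, fr_n, idx, float(lo), float(hi),
                            label, n_shuffles)


def classify_unit(spike_times, hypnogram: Hypnogram, n_shuffles: int = 1000,
                  alpha: float = 0.05, rng=None, unit_id: str = "") -> PreferenceResult:
    """state_rates + classify_preference on a unit's spike train."""
    starts, labels = state_bins(hypnogram)
    counts = bin_spike_counts(spike_times, starts)
    return classify_preference(counts, labels, n_shuffles=n_shuffles,
                               alpha=alpha, rng=rng, unit_id=unit_id)


def triplet_profile(spike_times, triplets, unit_id: str = "") -> TripletProfile:
    """Mean rate in each third of NREM1/REM/NREM2, averaged over triplets,
    then z-scored within the neuron (across the 9 thirds)."""
    if not triplets:
        raise ValueError("no triplets")
    t = np.asarray(spike_times, dtype=float)
    rows = []
    for trip in triplets:
        vals = []
        for (lo, hi) in trip:
            edges = np.linspace(lo, hi, 4)
            iv = np.column_stack([edges[:-1], edges[1:]])
            cnt = count_spikes_per_interval(t, iv)
            vals.extend(cnt / np.diff(edges))
        rows.append(vals)
    thirds = np.mean(np.asarray(rows, dtype=float), axis=0)
    sd = thirds.std()
    z = (thirds - thirds.mean()) / sd if sd > 0 else np.zeros_like(thirds)
    return TripletProfile(unit_id, thirds, z, len(triplets))


def preference_correlation(indices_by_session: dict, min_shared: int = 3):
    """Spearman rho of REM-preference indices for every session pair.

    ``indices_by_session`` maps session -> {unit: index}; all units present
    in both sessions (including NS-labeled) enter. Returns a nested dict
    rho[s1][s2]; NaN when fewer than ``min_shared`` shared units.
    """
    sessions = list(indices_by_session)
    out = {s: {} for s in sessions}
    for i, s1 in enumerate(sessions):
        for s2 in sessions[i + 1:]:
            shared = sorted(set(indices_by_session[s1]) & set(indices_by_session[s2]))
            if len(shared) < min_shared:
                rho = np.nan
            else:
                x = [indices_by_session[s1][u] for u in shared]
                y = [indices_by_session[s2][u] for u in shared]
                rho = spearman(x, y).statistic
            out[s1][s2] = rho
            out[s2][s1] = rho
    return out


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    from scipy.stats import spearmanr
    return float(spearmanr(x, y).statistic)


def bootstrap_correlation_compare(indices_by_session_by_region: dict,
                                  session_pairs=None, n_resample: int = 92,
                                  n_boot: int = 5000, rng=None) -> dict:
    """Bootstrap analyses of cross-session index correlations.

    For each region and hc-session pair, units shared by the two sessions
    are resampled with replacement (n = ``n_resample``) and the Spearman rho
    of their indices recomputed, ``n_boot`` times. Three outputs:

    * ``rho``: per (region, pair) bootstrap mean, 95% CI and the fraction of
      resamples <= 0 (significance of rho vs 0);
    * ``adjacent_diff``: per region, difference in rho between temporally
      adjacent session pairs, with 95% CI;
    * ``region_diff``: per session pair, difference in rho between regions,
      with 95% CI.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    regions = list(indices_by_session_by_region)
    boot = {}
    for reg in regions:
        by_sess = indices_by_session_by_region[reg]
        sessions = list(by_sess)
        pairs = session_pairs or [(sessions[i], sessions[i + 1])
                                  for i in range(len(sessions) - 1)]
        for (s1, s2) in pairs:
            shared = sorted(set(by_sess[s1]) & set(by_sess[s2]))
            x = np.array([by_sess[s1][u] for u in shared])
            y = np.array([by_sess[s2][u] for u in shared])
            rhos = np.empty(n_boot)
            for b in range(n_boot):
                take = rng.integers(0, len(shared), size=n_resample)
                rhos[b] = _spearman_rho(x[take], y[take])
            boot[(reg, (s1, s2))] = rhos
    out = {"rho": {}, "adjacent_diff": {}, "region_diff": {}}
    for key, rhos in boot.items():
        lo, hi = np.percentile(rhos, [2.5, 97.5])
        out["rho"][key] = {"mean": float(rhos.mean()), "ci": (float(lo), float(hi)),
                           "p_le_0": float(np.mean(rhos <= 0))}
    keys = list(boot)
    for reg in regions:
        reg_keys = [k for k in keys if k[0] == reg]
        for a, b in zip(reg_keys[:-1], reg_keys[1:]):
            d = boot[b] - boot[a]
            lo, hi = np.percentile(d, [2.5, 97.5])
            out["adjacent_diff"][(reg, a[1], b[1])] = {
                "mean": float(d.mean()), "ci": (float(lo), float(hi))}
    pair_set = sorted({k[1] for k in keys})
    for pr in pair_set:
        regs = [k[0] for k in keys if k[1] == pr]
        for i, r1 in enumerate(regs):
            for r2 in regs[i + 1:]:
                d = boot[(r1, pr)] - boot[(r2, pr)]
                lo, hi = np.percentile(d, [2.5, 97.5])
                out["region_diff"][(pr, r1, r2)] = {
                    "mean": float(d.mean()), "ci": (float(lo), float(hi))}
    return out
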