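"""Pairwise coactivation during oscillatory events.

A neuron is "active" in an event when it emits at least one spike inside
the event's [start, end) interval. For a pair active in n_A and n_B of N
events and jointly active in R, independence makes R hypergeometric, so

    E = n_A n_B / N,
    sigma^2 = n_A n_B (N - n_A)(N - n_B) / (N^2 (N - 1)),
    Z = (R - E) / sigma.

Z is undefined (pair excluded, with reason) when sigma = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import count_spikes_per_interval, events_to_intervals
from .stats import kruskal_steel_dwass, spearman

REGION_ORDER = ("vCA1", "PL5", "BLA")


@dataclass
class CoactivityResult:
    unit_a: str
    unit_b: str
    n_a: int
    n_b: int
    n_events: int
    r: int
    expected: float
    sigma: float
    z: float
    pair_type: str = ""
    flag: str = ""


@dataclass
class ResponseIndexResult:
    unit_id: str
    r: float            # Pearson correlation between X and Y
    n_events: int
    flag: str = ""


def activity_vector(spike_times, event_intervals) -> np.ndarray:
    """Boolean per-event activity (>= 1 spike in [start, end))."""
    iv = np.asarray(event_intervals, dtype=float)
    return count_spikes_per_interval(np.asarray(spike_times, dtype=float), iv) > 0


def coactivity_from_vectors(act_a, act_b, unit_a: str = "A",
                            unit_b: str = "B") -> CoactivityResult:
    act_a = np.asarray(act_a, dtype=bool)
    act_b = np.asarray(act_b, dtype=bool)
    n = act_a.size
    if n < 1 or act_b.size != n:
        raise ValueError("activity vectors must be equal length, N >= 1")
    n_a = int(act_a.sum())
    n_b = int(act_b.sum())
    r = int(np.count_nonzero(act_a & act_b))
    e = n_a * n_b / n
    if n == 1 or n_a in (0, n) or n_b in (0, n):
        return CoactivityResult(unit_a, unit_b, n_a, n_b, n, r, e, 0.0, np.nan,
                                flag="sigma zero (degenerate margins)")
    var = n_a * n_b * (n - n_a) * (n - n_b) / (n**2 * (n - 1))
    sigma = float(np.sqrt(var))
    return CoactivityResult(unit_a, unit_b, n_a, n_b, n, r, e, sigma,
                            (r - e) / sigma)


def coactivity_z(spikes_a, spikes_b, events, unit_a: str = "A",
                 unit_b: str = "B") -> CoactivityResult:
    """Coactivity Z-score of a pair over a set of events."""
    iv = events_to_intervals(events) if len(events) and hasattr(events[0], "start") \
        else np.asarray(events, dtype=float).reshape(-1, 2)
    if len(iv) == 0:
        raise ValueError("need >= 1 event")
    return coactivity_from_vectors(activity_vector(spikes_a, iv),
                                   activity_vector(spikes_b, iv),
                                   unit_a, unit_b)


def pair_type(label_a: str, region_a: str, label_b: str, region_b: str) -> str:
    """NN/RR for matching preferences; NR/RN ordered by the fixed region
    order (vCA1, PL5, BLA) for cross-regional mixed pairs; within-region
    mixed pairs are unordered NR; any NS member -> other."""
    if label_a == "NS" or label_b == "NS":
        return "other"
    a = "N" if label_a == "NREM" else "R"
    b = "N" if label_b == "NREM" else "R"
    if a == b:
        return a + b
    if region_a == region_b:
        return "NR"
    order = {r: i for i, r in enumerate(REGION_ORDER)}
    ia = order.get(region_a, len(order))
    ib = order.get(region_b, len(order))
    if ia <= ib:
        return a + b
    return b + a


def response_index(source_units: dict, target_spikes, events,
                   unit_id: str = "") -> ResponseIndexResult:
    """NREM-preferring neuron response index of one target neuron.

    ``source_units``: {unit: (spike_times, label)} with label in
    {"NREM", "REM"} for preference-labeled neurons of the oscillation's
    source region. Per event i, X(i) is the fraction of active
    NREM-preferring neurons among active labeled neurons; Y(i) is the
    target's FR during the event. The index is Pearson's r over events
    where X is defined.
    """
    iv = events_to_intervals(events) if len(events) and hasattr(events[0], "start") \
        else np.asarray(events, dtype=float).reshape(-1, 2)
    if len(iv) < 3:
        raise ValueError("need >= 3 events")
    n_n = np.zeros(len(iv))
    n_r = np.zeros(len(iv))
    for _, (t, lab) in source_units.items():
        act = activity_vector(t, iv)
        if lab == "NREM":
            n_n += act
        elif lab == "REM":
            n_r += act
    tot = n_n + n_r
    ok = tot > 0
    if ok.sum() < 3:
        return ResponseIndexResult(unit_id, np.nan, int(ok.sum()),
                                   flag="fewer than 3 events with active labeled neurons")
    x = n_n[ok] / tot[ok]
    cnt = count_spikes_per_interval(np.asarray(target_spikes, dtype=float), iv)
    y = (cnt / (iv[:, 1] - iv[:, 0]))[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ResponseIndexResult(unit_id, np.nan, int(ok.sum()),
                                   flag="zero variance in X or Y")
    r = float(np.corrcoef(x, y)[0, 1])
    return ResponseIndexResult(unit_id, r, int(ok.sum()))


def coactivity_vs_preference(pairs, gate_alpha: float = 0.05) -> dict:
    """Relate index products to coactivity Z across a pair population.

    ``pairs``: iterable of (CoactivityResult, index_product). Returns the
    Spearman rho of product vs Z over all pairs with defined Z, per-type
    group means, and the Kruskal-Wallis + Steel-Dwass comparison across
    pair types (NN/RR/NR/RN).
    """
    prods, zs, types = [], [], []
    for res, prod in pairs:
        if np.isnan(res.z):
            continue
        prods.append(prod)
        zs.append(res.z)
        types.append(res.pair_type)
    prods = np.asarray(prods)
    zs = np.asarray(zs)
    types = np.asarray(types, dtype=object)
    out = {"n_pairs": len(zs)}
    if len(zs) >= 3 and np.ptp(prods) > 0 and np.ptp(zs) > 0:
        sp = spearman(prods, zs)
        out["rho"], out["rho_p"] = sp.statistic, sp.p_value
    else:
        out["rho"], out["rho_p"] = np.nan, np.nan
        out["flag"] = "rho undefined (ties or too few pairs)"
    groups, labels = [], []
    for ty in ("NN", "RR", "NR", "RN"):
        sel = types == ty
        if sel.sum() >= 2:
            groups.append(zs[sel])
            labels.append(ty)
    out["group_mean_z"] = {ty: float(np.mean(g)) for ty, g in zip(labels, groups)}
    if len(groups) >= 2:
        omnibus, pairwise = kruskal_steel_dwass(groups, gate_alpha=gate_alpha)
        out["kruskal"] = omnibus
        out["steel_dwass"] = {(labels[i], labels[j]): t for (i, j), t in pairwise.items()}
    else:
        out["kruskal"] = None
        out["steel_dwass"] = {}
    return out
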