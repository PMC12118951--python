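"""Hypnogram post-processing into analysis epochs.

Microarousals (brief wake < 40 s inside NREM or at REM-to-NREM transitions)
are folded into NREM; epochs lasting <= 50 s are kept in the timeline but
flagged unusable; "extended sleep" is uninterrupted sleep > 30 min with no
wake bout > 60 s; NREM-REM-NREM triplets are consecutive qualifying epochs
used for firing-profile analyses.
"""

from __future__ import annotations

import numpy as np

from .core import MA, NREM, REM, WAKE, Hypnogram

SLEEP_STATES = (NREM, REM)
MA_MAX_S = 40.0
SHORT_EPOCH_S = 50.0
EXTENDED_SLEEP_MIN_S = 1800.0
EXTENDED_WAKE_GAP_S = 60.0


def _merge_adjacent(starts, ends, states):
    """Fuse touching intervals that share a state label."""
    out_s, out_e, out_l = [], [], []
    for s, e, l in zip(starts, ends, states):
        if out_l and out_l[-1] == l and abs(out_e[-1] - s) < 1e-9:
            out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
            out_l.append(l)
    return np.array(out_s), np.array(out_e), np.array(out_l, dtype=object)


def normalize_hypnogram(raw: Hypnogram) -> Hypnogram:
    """Merge microarousals into NREM, then flag short epochs unusable.

    A wake/MA interval shorter than 40 s is relabeled NREM when it sits
    inside NREM (NREM on both sides) or at a REM-to-NREM transition; wake at
    sleep onset/offset is never merged. Afterwards NREM/REM/WAKE epochs
    lasting <= 50 s are flagged unusable (but retained in the timeline).
    Idempotent.
    """
    states = np.array(raw.states, dtype=object)
    starts = np.array(raw.starts, dtype=float)
    ends = np.array(raw.ends, dtype=float)
    durs = ends - starts
    wake_like = np.isin(states, (WAKE, MA))
    for i in range(1, len(states) - 1):
        if not wake_like[i] or durs[i] >= MA_MAX_S:
            continue
        prev, nxt = states[i - 1], states[i + 1]
        if (prev == NREM and nxt == NREM) or (prev == REM and nxt == NREM):
            states[i] = NREM
    # any leftover MA labels are brief arousals at non-mergeable positions:
    # keep them in the timeline as WAKE
    states[states == MA] = WAKE
    starts, ends, states = _merge_adjacent(starts, ends, states)
    usable = (ends - starts) > SHORT_EPOCH_S
    return Hypnogram(starts, ends, states, usable)


def find_extended_sleep(hyp: Hypnogram) -> np.ndarray:
    """Maximal sleep periods > 30 min containing no wake bout > 60 s.

    Returns an (n, 2) array of [start, end) spans, each trimmed to its first
    and last sleep epoch.
    """
    spans = []
    cur = None  # [start, end] of current sleep run
    for s, e, l in zip(hyp.starts, hyp.ends, hyp.states):
        if l in SLEEP_STATES:
            if cur is None:
                cur = [s, e]
            else:
                cur[1] = e
        else:  # wake bout
            if cur is not None and (e - s) > EXTENDED_WAKE_GAP_S:
                spans.append(cur)
                cur = None
            # short wake bouts are absorbed (cur end not extended; trimmed)
    if cur is not None:
        spans.append(cur)
    out = [sp for sp in spans if sp[1] - sp[0] > EXTENDED_SLEEP_MIN_S]
    return np.asarray(out, dtype=float).reshape(-1, 2)


def nrem_epochs_in(hyp: Hypnogram, span, usable_only: bool = True) -> np.ndarray:
    """Usable NREM epochs wholly inside [span[0], span[1])."""
    iv = hyp.intervals(NREM, usable_only=usable_only)
    sel = (iv[:, 0] >= span[0] - 1e-9) & (iv[:, 1] <= span[1] + 1e-9)
    return iv[sel]


def find_triplets(hyp: Hypnogram, tolerate_excluded: bool = True) -> list:
    """All consecutive NREM-REM-NREM epoch triples, each member > 50 s.

    With ``tolerate_excluded`` (default) intervening unusable (<= 50 s)
    epochs of any state do not break consecutiveness, because excluded
    epochs drop out of the analysed sequence. Overlapping triplets share
    epochs as the sequence dictates. Returns a list of three (start, end)
    pairs per triplet.
    """
    if tolerate_excluded:
        keep = hyp.usable
    else:
        keep = np.ones(len(hyp), dtype=bool)
    sts = hyp.states[keep]
    ivs = np.column_stack([hyp.starts[keep], hyp.ends[keep]])
    us = hyp.usable[keep]
    trips = []
    for i in range(len(sts) - 2):
        if (sts[i], sts[i + 1], sts[i + 2]) == (NREM, REM, NREM) and us[i:i + 3].all():
            trips.append((tuple(ivs[i]), tuple(ivs[i + 1]), tuple(ivs[i + 2])))
    return trips
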