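"""End-to-end pipeline over a session bundle.

Stages run in dependency order:

    quality -> typing -> sleep -> detect -> preference -> modulation
            -> coactivity -> stats

Each stage writes deterministic TSV tables; a run is reproducible
bit-identically given the same inputs and seed. A provenance block
(config, seed, stage list) is written alongside the results.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import celltype, coactivity as coact, detect, modulation, preference, quality, sleep
from .core import NREM, REM, WAKE, events_to_frame, events_to_intervals
from .session import SessionBundle, load_session, save_tables
from .stats import mann_whitney

STAGE_ORDER = ["quality", "typing", "sleep", "detect", "preference",
               "modulation", "coactivity", "stats"]
STAGE_DEPS = {
    "quality": [],
    "typing": [],
    "sleep": [],
    "detect": ["sleep"],
    "preference": ["sleep"],
    "modulation": ["sleep", "detect", "preference"],
    "coactivity": ["detect", "preference", "typing", "quality"],
    "stats": ["coactivity", "modulation", "preference"],
}


def run_pipeline(manifest_path, out_dir, stages=None, seed: int = 0,
                 n_shuffles: int = 1000, n_surrogates: int = 1000,
                 stringent: bool = False) -> dict:
    """Run the requested stages on a session; returns {stage: artifacts}.

    Missing dependencies fail before any computation. Results land in
    ``out_dir`` as TSV tables plus a JSON summary and Markdown report.
    """
    stages = list(stages) if stages else list(STAGE_ORDER)
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    stages = [s for s in STAGE_ORDER if s in stages]
    for s in stages:
        missing = [d for d in STAGE_DEPS[s] if d not in stages]
        if missing:
            raise ValueError(f"stage '{s}' requires {missing} in the stage list")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = load_session(manifest_path)
    ss = np.random.SeedSequence(seed)
    rngs = {name: np.random.default_rng(child)
            for name, child in zip(STAGE_ORDER, ss.spawn(len(STAGE_ORDER)))}

    results: dict = {}
    tables: dict = {}

    if "quality" in stages:
        results["quality"] = _stage_quality(bundle, tables)
    if "typing" in stages:
        results["typing"] = _stage_typing(bundle, tables, rngs["typing"], n_surrogates)
    if "sleep" in stages:
        results["sleep"] = _stage_sleep(bundle, tables)
    if "detect" in stages:
        results["detect"] = _stage_detect(bundle, results, tables, stringent)
    if "preference" in stages:
        results["preference"] = _stage_preference(bundle, results, tables,
                                                  rngs["preference"], n_shuffles)
    if "modulation" in stages:
        results["modulation"] = _stage_modulation(bundle, results, tables)
    if "coactivity" in stages:
        results["coactivity"] = _stage_coactivity(bundle, results, tables)
    if "stats" in stages:
        results["stats"] = _stage_stats(results, tables)

    paths = save_tables(tables, out)
    summary = {
        "stages": stages,
        "seed": seed,
        "manifest": str(manifest_path),
        "n_units": len(bundle.units),
        "tables": {k: str(v.name) for k, v in paths.items()},
    }
    if "detect" in results:
        summary["n_events"] = {k: len(v) for k, v in results["detect"].items()}
    if "preference" in results:
        labels = [r.label for r in results["preference"].values()]
        summary["preference_counts"] = {l: labels.count(l)
                                        for l in (REM, NREM, "NS")}
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 sort_keys=True) + "\n")
    _write_report(out / "report.md", summary)
    results["summary"] = summary
    return results


def _stage_quality(bundle: SessionBundle, tables) -> dict:
    dur = bundle.hypnogram.duration
    rows, out = [], {}
    for u in bundle.units:
        q = quality.UnitQuality(u.unit_id, mean_fr=u.mean_rate(dur))
        if u.n_spikes >= 2:
            q.isi_index = quality.isi_index(u.times)
            q.contamination_rate = quality.contamination_rate(u.times)
        # waveform/feature metrics are absent for synthetic sessions;
        # inclusion is judged on the metrics that exist
        clean = (np.isnan(q.isi_index) or q.isi_index < 0.2) or \
                (np.isnan(q.contamination_rate) or q.contamination_rate < 0.05)
        q.included = bool(q.mean_fr > 0.01 and clean)
        out[u.unit_id] = q
        rows.append((u.unit_id, q.isi_index, q.contamination_rate, q.mean_fr,
                     int(q.included)))
    tables["quality"] = pd.DataFrame(
        rows, columns=["unit_id", "isi_index", "contamination_rate", "mean_fr",
                       "included"])
    return out


def _stage_typing(bundle: SessionBundle, tables, rng, n_surrogates: int) -> dict:
    pair_calls, rows = [], []
    by_region: dict = {}
    for u in bundle.units:
        by_region.setdefault(u.region, []).append(u)
    for region, units in sorted(by_region.items()):
        for i, a in enumerate(units):
            for b in units[i + 1:]:
                for ref, tgt in ((a, b), (b, a)):
                    call = celltype.classify_pair(ref.times, tgt.times, rng,
                                                  n_surrogates=n_surrogates)
                    for kind in ("excitatory", "inhibitory"):
                        if call[kind]:
                            pair_calls.append((ref.unit_id, tgt.unit_id, kind))
                            rows.append((ref.unit_id, tgt.unit_id, kind))
    calls = celltype.assign_cell_types(pair_calls, {})
    # units without CCG evidence stay unclassified (no waveforms in
    # synthetic sessions); downstream falls back to all included units
    full = {}
    for u in bundle.units:
        full[u.unit_id] = calls.get(
            u.unit_id, celltype.CellTypeCall(u.unit_id, "unclassified", "none"))
    tables["pair_calls"] = pd.DataFrame(rows, columns=["ref_unit", "target_unit",
                                                       "call"])
    tables["cell_types"] = pd.DataFrame(
        [(c.unit_id, c.label, c.evidence, c.out_excitatory_count,
          c.out_inhibitory_count) for c in full.values()],
        columns=["unit_id", "label", "evidence", "n_exc_out", "n_inh_out"])
    return full


def _stage_sleep(bundle: SessionBundle, tables) -> dict:
    hyp = sleep.normalize_hypnogram(bundle.hypnogram)
    ext = sleep.find_extended_sleep(hyp)
    trips = sleep.find_triplets(hyp)
    tables["epochs"] = hyp.to_dataframe()
    tables["extended_sleep"] = pd.DataFrame(ext, columns=["start_s", "end_s"])
    tables["triplets"] = pd.DataFrame(
        [(t[0][0], t[0][1], t[1][0], t[1][1], t[2][0], t[2][1]) for t in trips],
        columns=["nrem1_start", "nrem1_end", "rem_start", "rem_end",
                 "nrem2_start", "nrem2_end"])
    return {"hypnogram": hyp, "extended_sleep": ext, "triplets": trips}


def _stage_detect(bundle: SessionBundle, results, tables, stringent: bool) -> dict:
    hyp = results["sleep"]["hypnogram"]
    events = detect.detect_all(bundle.lfp, hyp, stringent=stringent)
    frames = []
    for kind, evs in events.items():
        frames.append(events_to_frame(evs))
    tables["events"] = pd.concat(frames, ignore_index=True) if frames \
        else events_to_frame([])
    summ = []
    nrem = hyp.intervals(NREM)
    wake = hyp.intervals(WAKE)
    for kind, evs in events.items():
        ref = wake if kind == "awakeSWR" else nrem
        s = detect.event_summary(evs, ref)
        summ.append((kind, s["n"], s["rate_per_s"], s["dur_ms_median"],
                     s["dur_ms_q1"], s["dur_ms_q3"]))
    tables["event_summary"] = pd.DataFrame(
        summ, columns=["kind", "n", "rate_per_s", "dur_ms_median", "dur_ms_q1",
                       "dur_ms_q3"])
    return events


def _stage_preference(bundle: SessionBundle, results, tables, rng,
                      n_shuffles: int) -> dict:
    hyp = results["sleep"]["hypnogram"]
    out, rows = {}, []
    for u in bundle.units:
        try:
            res = preference.classify_unit(u.times, hyp, n_shuffles=n_shuffles,
                                           rng=rng, unit_id=u.unit_id)
        except ValueError:
            continue
        out[u.unit_id] = res
        rows.append((u.unit_id, res.fr_rem, res.fr_nrem, res.index,
                     res.null_lo, res.null_hi, res.label))
    tables["preference"] = pd.DataFrame(
        rows, columns=["unit_id", "fr_rem", "fr_nrem", "index", "null_lo",
                       "null_hi", "label"])
    trips = results["sleep"]["triplets"]
    prof_rows = []
    if trips:
        for u in bundle.units:
            p = preference.triplet_profile(u.times, trips, unit_id=u.unit_id)
            prof_rows.append([u.unit_id] + list(p.z))
    tables["triplet_profiles"] = pd.DataFrame(
        prof_rows, columns=["unit_id"] + [f"z_{seg}_{i}" for seg in
                                          ("nrem1", "rem", "nrem2")
                                          for i in (1, 2, 3)])
    return out


def _stage_modulation(bundle: SessionBundle, results, tables) -> dict:
    hyp = results["sleep"]["hypnogram"]
    events = results["detect"]
    nrem = hyp.intervals(NREM, usable_only=True)
    wake = hyp.intervals(WAKE, usable_only=True)
    rows = []
    gains = {}
    for kind, evs in events.items():
        sleep_evs = [e for e in evs if _peak_in(e, nrem)]
        for u in bundle.units:
            g = modulation.fr_gain(u.times, sleep_evs, nrem, unit_id=u.unit_id)
            gains[(u.unit_id, kind)] = g
            rows.append((u.unit_id, kind, "NREM", g.fr_in, g.fr_out, g.gain))
        if kind == "SWR":
            awake_evs = [e for e in evs if _peak_in(e, wake)]
            if awake_evs and len(wake):
                for u in bundle.units:
                    g = modulation.fr_gain(u.times, awake_evs, wake,
                                           unit_id=u.unit_id)
                    gains[(u.unit_id, "awakeSWR")] = g
                    rows.append((u.unit_id, "awakeSWR", "WAKE", g.fr_in,
                                 g.fr_out, g.gain))
    tables["fr_gain"] = pd.DataFrame(
        rows, columns=["unit_id", "kind", "reference", "fr_in", "fr_out", "gain"])

    shock_rows = []
    if bundle.behavior is not None and len(bundle.behavior):
        us = bundle.behavior[bundle.behavior["label"] == "US"]
        cs = bundle.behavior[bundle.behavior["label"] == "CS"]
        if len(us) and len(cs):
            iv = us[["start_s", "end_s"]].to_numpy(dtype=float)
            first_cs = float(cs["start_s"].min())
            for u in bundle.units:
                g = modulation.shock_gain(u.times, iv, first_cs,
                                          unit_id=u.unit_id)
                shock_rows.append((u.unit_id, g.fr_in, g.fr_out, g.gain))
    tables["shock_gain"] = pd.DataFrame(
        shock_rows, columns=["unit_id", "peak_fr", "baseline_fr", "gain"])
    return gains


def _peak_in(event, intervals) -> bool:
    from .core import spikes_in_intervals
    return bool(spikes_in_intervals(np.array([event.peak_time]), intervals)[0])


def _stage_coactivity(bundle: SessionBundle, results, tables) -> dict:
    events = results["detect"]
    prefs = results["preference"]
    types = results.get("typing", {})
    qual = results.get("quality", {})
    pool = [u for u in bundle.units
            if (u.unit_id not in qual or qual[u.unit_id].included)]
    exc = [u for u in pool if types.get(u.unit_id) is not None
           and types[u.unit_id].label == "excitatory"]
    if not exc:  # no CCG-typable units (common on small synthetic sessions)
        exc = pool
    hyp = results["sleep"]["hypnogram"]
    nrem = hyp.intervals(NREM, usable_only=True)
    rows = []
    pair_results = {}
    for kind, evs in events.items():
        sleep_evs = [e for e in evs if _peak_in(e, nrem)]
        if len(sleep_evs) < 2:
            continue
        iv = events_to_intervals(sleep_evs)
        acts = {u.unit_id: coact.activity_vector(u.times, iv) for u in exc}
        for i, a in enumerate(exc):
            for b in exc[i + 1:]:
                res = coact.coactivity_from_vectors(acts[a.unit_id],
                                                    acts[b.unit_id],
                                                    a.unit_id, b.unit_id)
                la = prefs[a.unit_id].label if a.unit_id in prefs else "NS"
                lb = prefs[b.unit_id].label if b.unit_id in prefs else "NS"
                res.pair_type = coact.pair_type(la, a.region, lb, b.region)
                prod = (prefs[a.unit_id].index * prefs[b.unit_id].index
                        if a.unit_id in prefs and b.unit_id in prefs else np.nan)
                pair_results.setdefault(kind, []).append((res, prod))
                rows.append((kind, a.unit_id, b.unit_id, a.region, b.region,
                             res.pair_type, res.n_a, res.n_b, res.n_events,
                             res.r, res.expected, res.sigma, res.z, prod))
    tables["coactivity"] = pd.DataFrame(
        rows, columns=["kind", "unit_a", "unit_b", "region_a", "region_b",
                       "pair_type", "n_a", "n_b", "n_events", "r", "expected",
                       "sigma", "z", "index_product"])
    return pair_results


def _stage_stats(results, tables) -> dict:
    out = {}
    rows = []
    for kind, pairs in results.get("coactivity", {}).items():
        comp = coact.coactivity_vs_preference(pairs)
        out[kind] = comp
        rows.append((kind, comp["n_pairs"], comp.get("rho", np.nan),
                     comp.get("rho_p", np.nan),
                     comp["kruskal"].p_value if comp["kruskal"] else np.nan))
    tables["coactivity_stats"] = pd.DataFrame(
        rows, columns=["kind", "n_pairs", "spearman_rho", "spearman_p",
                       "kruskal_p"])
    # gains of REM- vs NREM-preferring units
    gain_rows = []
    prefs = results.get("preference", {})
    gains = results.get("modulation", {})
    kinds = sorted({k for (_, k) in gains})
    for kind in kinds:
        g_rem = [gains[(u, kind)].gain for (u, kk) in gains if kk == kind
                 and u in prefs and prefs[u].label == REM
                 and np.isfinite(gains[(u, kind)].gain)]
        g_nrem = [gains[(u, kind)].gain for (u, kk) in gains if kk == kind
                  and u in prefs and prefs[u].label == NREM
                  and np.isfinite(gains[(u, kind)].gain)]
        if len(g_rem) >= 1 and len(g_nrem) >= 1:
            mw = mann_whitney(g_rem, g_nrem)
            gain_rows.append((kind, len(g_rem), len(g_nrem),
                              float(np.median(g_rem)), float(np.median(g_nrem)),
                              mw.p_value))
    tables["gain_by_preference"] = pd.DataFrame(
        gain_rows, columns=["kind", "n_rem_pref", "n_nrem_pref",
                            "median_gain_rem_pref", "median_gain_nrem_pref",
                            "mann_whitney_p"])
    return out


def _write_report(path: Path, summary: dict) -> None:
    lines = ["# Pipeline report", ""]
    lines.append(f"- seed: {summary['seed']}")
    lines.append(f"- stages: {', '.join(summary['stages'])}")
    lines.append(f"- units: {summary['n_units']}")
    if "n_events" in summary:
        for k, v in summary["n_events"].items():
            lines.append(f"- {k} events: {v}")
    if "preference_counts" in summary:
        pc = summary["preference_counts"]
        lines.append(f"- preference: {pc}")
    lines.append("")
    Path(path).write_text("\n".join(lines))
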