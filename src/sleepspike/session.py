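"""Session artifact I/O: manifests, TSV tables, flat-binary LFP.

On-disk layout (all plain text except the LFP):

* ``manifest.json`` - file map, sampling rate, region map, session windows;
* ``spikes.tsv`` (unit_id, spike_time_s) grouped by unit, time-ascending;
  ``units.tsv`` (unit_id, region, shank);
* ``lfp.dat`` - little-endian float32, channel-major, with a JSON sidecar
  carrying fs, channel count and per-channel (region, shank, depth_order);
* interval tables (hypnogram, events, behavior) as TSV with half-open
  [start_s, end_s) rows.

Floats in result tables are serialized with 9 significant digits and NaN as
"NA"; re-reading reproduces the values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Hypnogram, LfpSet, SpikeTrain, ValidationError

FLOAT_FMT = "%.9g"


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, float_fmt: str = FLOAT_FMT) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_fmt, na_rep="NA",
              lineterminator="\n")
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def save_tables(results: dict, out_dir) -> dict:
    """Write one TSV per named DataFrame; returns {name: path}."""
    out = {}
    for name, df in results.items():
        out[name] = write_tsv(df, Path(out_dir) / f"{name}.tsv")
    return out


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def write_lfp(lfp: LfpSet, dat_path, sidecar_path) -> None:
    dat_path, sidecar_path = Path(dat_path), Path(sidecar_path)
    dat_path.parent.mkdir(parents=True, exist_ok=True)
    lfp.data.astype("<f4").tofile(dat_path)
    meta = {"fs": lfp.fs, "n_channels": int(lfp.data.shape[0]),
            "n_samples": int(lfp.data.shape[1]), "dtype": "<f4",
            "order": "channel-major", "channels": lfp.channels}
    sidecar_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def read_lfp(dat_path, sidecar_path) -> LfpSet:
    meta = json.loads(Path(sidecar_path).read_text())
    raw = np.fromfile(dat_path, dtype="<f4")
    n_ch, n_s = meta["n_channels"], meta["n_samples"]
    if raw.size != n_ch * n_s:
        raise ValidationError(
            f"LFP file has {raw.size} samples, sidecar says {n_ch}x{n_s}")
    return LfpSet(raw.reshape(n_ch, n_s), float(meta["fs"]), meta["channels"])


# ---------------------------------------------------------------------------
# spikes / intervals
# ---------------------------------------------------------------------------

def write_spikes(units: list, spikes_path, units_path) -> None:
    rows = []
    for u in units:
        for t in u.times:
            rows.append((u.unit_id, t))
    df = pd.DataFrame(rows, columns=["unit_id", "spike_time_s"])
    write_tsv(df, spikes_path, float_fmt="%.7f")
    udf = pd.DataFrame([(u.unit_id, u.region, u.shank) for u in units],
                       columns=["unit_id", "region", "shank"])
    write_tsv(udf, units_path)


def read_spikes(spikes_path, units_path) -> list:
    sdf = read_tsv(spikes_path)
    udf = read_tsv(units_path)
    meta = {str(r.unit_id): (str(r.region), int(r.shank)) for r in udf.itertuples()}
    units = []
    for uid, grp in sdf.groupby("unit_id", sort=False):
        t = grp["spike_time_s"].to_numpy(dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            row = int(grp.index[int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1]) + 2
            raise ValidationError(
                f"spikes for unit {uid} out of order at file row {row}")
        region, shank = meta.get(str(uid), ("", 0))
        units.append(SpikeTrain(str(uid), t, region, shank))
    # units with zero spikes still exist in the units table
    seen = {u.unit_id for u in units}
    for r in udf.itertuples():
        if str(r.unit_id) not in seen:
            units.append(SpikeTrain(str(r.unit_id), np.empty(0), str(r.region),
                                    int(r.shank)))
    return units


def write_intervals(intervals, labels, path) -> None:
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    df = pd.DataFrame({"start_s": iv[:, 0], "end_s": iv[:, 1], "label": labels})
    write_tsv(df, path, float_fmt="%.7f")


def read_hypnogram(path) -> Hypnogram:
    df = read_tsv(path)
    return Hypnogram(df["start_s"].to_numpy(), df["end_s"].to_numpy(),
                     df["label"].to_numpy(dtype=object),
                     df["usable"].to_numpy(dtype=bool) if "usable" in df else None)


# ---------------------------------------------------------------------------
# session bundle
# ---------------------------------------------------------------------------

@dataclass
class SessionBundle:
    manifest_path: Path
    hypnogram: Hypnogram
    units: list
    lfp: LfpSet
    behavior: pd.DataFrame = None
    truth: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def load_session(manifest_path) -> SessionBundle:
    """Load and validate every artifact referenced by a session manifest."""
    manifest_path = Path(manifest_path)
    man = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    files = man["files"]
    for key, rel in files.items():
        if not (root / rel).exists():
            raise ValidationError(f"manifest entry '{key}' missing: {rel}")
    hyp = read_hypnogram(root / files["hypnogram"])
    units = read_spikes(root / files["spikes"], root / files["units"])
    lfp = read_lfp(root / files["lfp"], root / files["lfp_sidecar"])
    behavior = read_tsv(root / files["behavior"]) if "behavior" in files else None
    truth = {}
    for key in files:
        if key.startswith("truth_"):
            truth[key[len("truth_"):]] = read_tsv(root / files[key])
    return SessionBundle(manifest_path, hyp, units, lfp, behavior, truth, man)


def select_state_time(hypnogram: Hypnogram, state: str, session_windows) -> np.ndarray:
    """State intervals clipped to the requested session windows."""
    from .core import STATES, intersect_intervals
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
    wins = np.asarray(session_windows, dtype=float).reshape(-1, 2)
    wins = wins[np.argsort(wins[:, 0])]
    return intersect_intervals(hypnogram.intervals(state), wins)
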