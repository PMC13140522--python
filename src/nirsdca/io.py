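"""Disk formats: the recording bundle CSV dialect, SNIRF ingestion and
result writers.

A recording bundle is a directory with ``manifest.json`` plus one CSV per
stream.  CSVs are RFC-4180, UTF-8, with a header row followed by a units
row; floats are written with 17 significant digits so read→write round
trips are bit-identical.  The manifest lists every file with its SHA-256
checksum, the clock origin (ISO-8601), sampling rates and channel metadata.
"""
from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .mbll import OpticalDensitySeries
from .types import ChannelMeta, Event, NirsChannel, RawRecording

SCHEMA_VERSION = 1
_FLOAT_FMT = "%.17g"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_series_csv(path: Path, columns: dict[str, np.ndarray], units: dict[str, str]) -> None:
    names = list(columns)
    arrays = [np.asarray(columns[c]) for c in names]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(names)
        w.writerow([units.get(c, "") for c in names])
        for row in zip(*arrays):
            w.writerow([_FLOAT_FMT % v for v in row])


def _read_series_csv(path: Path) -> tuple[pd.DataFrame, dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        r = csv.reader(fh)
        names = next(r)
        units = dict(zip(names, next(r)))
    df = pd.read_csv(path, skiprows=[1], float_precision="round_trip")
    for c in df.columns:
        if not units.get(c):
            raise ValueError(f"column {c!r} in {path.name} has no unit declared")
    return df, units


def write_recording(recording: RawRecording, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = len(recording.abp)
    t = np.arange(n) / recording.fs_raw
    _write_series_csv(out / "abp.csv", {"time_s": t, "abp": recording.abp},
                      {"time_s": "s", "abp": "mmHg"})
    cols = {"time_s": t}
    units = {"time_s": "s"}
    for ch in recording.channels:
        cols[ch.name] = ch.oxyhb
        units[ch.name] = "uM*mm"
    _write_series_csv(out / "nirs.csv", cols, units)
    vit_units = {"time_s": "s", "hr": "bpm", "mean_abp": "mmHg", "spo2": "%", "etco2": "kPa"}
    _write_series_csv(
        out / "vitals.csv",
        {c: recording.vitals[c].to_numpy() for c in recording.vitals.columns},
        {c: vit_units.get(c, "a.u.") for c in recording.vitals.columns},
    )
    with open(out / "events.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "time_s"])
        for ev in recording.events:
            w.writerow([ev.name, _FLOAT_FMT % ev.time_s])
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": recording.subject_id,
        "clock_origin": "1970-01-01T00:00:00Z",
        "fs_raw_hz": recording.fs_raw,
        "vitals_fs_hz": recording.vitals_fs,
        "channels": [
            {"name": ch.name, **asdict(ch.meta)} for ch in recording.channels
        ],
        "files": {},
    }
    for name in ("abp.csv", "nirs.csv", "vitals.csv", "events.csv"):
        manifest["files"][name] = _sha256(out / name)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def read_recording(in_dir: str | Path) -> RawRecording:
    src = Path(in_dir)
    mpath = src / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"manifest.json missing in {src}")
    manifest = json.loads(mpath.read_text())
    if manifest.get("schema_version", 0) > SCHEMA_VERSION:
        raise ValueError(
            f"recording schema version {manifest['schema_version']} is newer "
            f"than supported version {SCHEMA_VERSION}"
        )
    for name, checksum in manifest["files"].items():
        p = src / name
        if not p.exists():
            raise FileNotFoundError(f"file listed in manifest is missing: {name}")
        if _sha256(p) != checksum:
            raise ValueError(f"checksum mismatch for {name}")
    abp_df, _ = _read_series_csv(src / "abp.csv")
    nirs_df, _ = _read_series_csv(src / "nirs.csv")
    vitals_df, _ = _read_series_csv(src / "vitals.csv")
    events = []
    with open(src / "events.csv", newline="", encoding="utf-8") as fh:
        r = csv.DictReader(fh)
        for row in r:
            events.append(Event(row["name"], float(row["time_s"])))
    channels = []
    for entry in manifest["channels"]:
        meta = dict(entry)
        name = meta.pop("name")
        channels.append(
            NirsChannel(
                name=name,
                meta=ChannelMeta(**meta),
                oxyhb=nirs_df[name].to_numpy(),
            )
        )
    return RawRecording(
        subject_id=manifest["subject_id"],
        fs_raw=float(manifest["fs_raw_hz"]),
        abp=abp_df["abp"].to_numpy(),
        channels=channels,
        vitals=vitals_df,
        vitals_fs=float(manifest["vitals_fs_hz"]),
        events=events,
    )


def read_snirf(path: str | Path) -> list[OpticalDensitySeries]:
    """Read a two-wavelength continuous-wave SNIRF file into per-channel
    optical-density series, deriving role (long/short) and hemisphere from
    the probe geometry: source-detector separation 35 mm → long cortical
    channel, 10 mm → short scalp channel; negative x → ischaemic side by the
    stored landmark convention, unless a hemisphere field is present in the
    channel metadata tags."""
    import h5py

    out: list[OpticalDensitySeries] = []
    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        probe = nirs["probe"]
        src_pos = np.asarray(probe["sourcePos3D" if "sourcePos3D" in probe else "sourcePos2D"])
        det_pos = np.asarray(probe["detectorPos3D" if "detectorPos3D" in probe else "detectorPos2D"])
        wavelengths = tuple(np.asarray(probe["wavelengthes" if "wavelengthes" in probe else "wavelengths"], dtype=float))
        data = nirs["data1"]
        ts = np.asarray(data["dataTimeSeries"], dtype=float)
        time = np.asarray(data["time"], dtype=float)
        if len(time) == 2 and len(ts) > 2:  # start/step form
            time = time[0] + time[1] * np.arange(len(ts))
        # group measurement-list columns by (source, detector)
        pairs: dict[tuple[int, int], dict[float, int]] = {}
        k = 1
        while f"measurementList{k}" in data:
            ml = data[f"measurementList{k}"]
            s = int(np.asarray(ml["sourceIndex"]))
            d = int(np.asarray(ml["detectorIndex"]))
            wli = int(np.asarray(ml["wavelengthIndex"]))
            pairs.setdefault((s, d), {})[wavelengths[wli - 1]] = k - 1
            k += 1
        for (s, d), cols in sorted(pairs.items()):
            if len(cols) != 2:
                raise ValueError(f"channel S{s}-D{d} does not have exactly two wavelengths")
            sp = src_pos[s - 1]
            dp = det_pos[d - 1]
            sep = float(np.linalg.norm(np.asarray(sp) - np.asarray(dp)))
            role = "short" if sep < 20 else "long"
            hemi = "ischaemic" if 0.5 * (sp[0] + dp[0]) < 0 else "contralateral"
            wl = tuple(sorted(cols))
            od = np.column_stack([ts[:, cols[wl[0]]], ts[:, cols[wl[1]]]])
            meta = ChannelMeta(
                hemisphere=hemi,
                separation_mm=35.0 if role == "long" else 10.0,
                role=role,
                territory_label=f"S{s}-D{d}",
            )
            out.append(OpticalDensitySeries(time=time, od=od, wavelengths=wl, channel_meta=meta))
    return out


TFA_COLUMNS = [
    "schema_version", "subject_id", "segment", "hemisphere", "channel",
    "band", "psd_input", "psd_output", "coherence", "gain",
    "normalized_gain", "phase_deg", "mean_input", "mean_output", "flags",
]


def write_tfa_results(rows: pd.DataFrame, path: str | Path) -> Path:
    """TFA rows → CSV with fixed column order and a schema-version column.

    Raises on non-finite values: NaNs are forbidden after preprocessing.
    """
    path = Path(path)
    df = rows.copy()
    df["schema_version"] = SCHEMA_VERSION
    for col in TFA_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col == "flags" else np.nan
    num = df[["psd_input", "psd_output", "coherence", "gain", "phase_deg"]]
    if not np.all(np.isfinite(num.to_numpy(dtype=float))):
        raise ValueError("non-finite TFA values cannot be written")
    df = df[TFA_COLUMNS]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def read_tfa_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "schema_version" not in df.columns:
        raise ValueError("not a TFA results file (no schema_version column)")
    if len(df) and int(df["schema_version"].iloc[0]) > SCHEMA_VERSION:
        raise ValueError(
            f"TFA results schema {int(df['schema_version'].iloc[0])} is newer "
            f"than supported version {SCHEMA_VERSION}"
        )
    return df


def write_fits(fits: dict, path: str | Path) -> Path:
    """Model fits → JSON with schema version and deterministic key order."""
    path = Path(path)

    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"cannot serialize {type(o)}")

    payload = {"schema_version": SCHEMA_VERSION, "fits": fits}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
    return path
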