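"""Serialization: sessions, segmented contacts and feature matrices.

Every artefact is columnar: one file per device stream (timestamp +
channels) plus a JSON metadata sidecar.  Both plain CSV and parquet are
supported (``fmt="csv" | "parquet"``); parquet is the default for bulk
traces, CSV for small tables.

Session directory layout::

    meta.json            participant, condition, device offsets, geometry
    force.parquet        t, force_v, force_ap            (1,000 Hz)
    pressure.parquet     t, fsr_01..fsr_16               (50 Hz, stance only)
    imu.parquet          t, accel_x/y/z, gyro_x/y/z      (1,138 Hz)
    truth_intervals.csv  start, end                      (master clock)
    truth_grf.parquet    contact, sample, grf_v, grf_ap, cop_x, cop_y
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from grfest.features import FeatureMatrix
from grfest.preprocess import NORMALIZED_LENGTH, FootContact
from grfest.synth import (
    Condition,
    ForceStream,
    ImuStream,
    InsoleGeometry,
    ParticipantProfile,
    PressureStream,
    SensorSession,
    SessionTruth,
)

FSR_COLS = [f"fsr_{i + 1:02d}" for i in range(16)]


def _write_table(df: pd.DataFrame, path: Path, fmt: str) -> Path:
    if fmt == "parquet":
        out = path.with_suffix(".parquet")
        df.to_parquet(out, index=False)
    elif fmt == "csv":
        out = path.with_suffix(".csv")
        df.to_csv(out, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return out


def _read_table(path: Path) -> pd.DataFrame:
    for suffix, reader in ((".parquet", pd.read_parquet), (".csv", pd.read_csv)):
        cand = path.with_suffix(suffix)
        if cand.exists():
            return reader(cand)
    raise FileNotFoundError(f"no parquet/csv table at {path}")


def write_session(session: SensorSession, out_dir: str | Path, fmt: str = "parquet") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "profile": asdict(session.profile),
        "condition": asdict(session.condition),
        "device_offsets": session.device_offsets,
        "geometry": {
            "sensor_coords": session.geometry.sensor_coords.tolist(),
            "insole_length": session.geometry.insole_length,
        },
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))

    f = session.force
    t = np.arange(len(f.vertical)) / f.fs
    _write_table(
        pd.DataFrame({"t": t, "force_v": f.vertical, "force_ap": f.anteroposterior}),
        out / "force", fmt,
    )
    p = pd.DataFrame(session.pressure.values, columns=FSR_COLS)
    p.insert(0, "t", session.pressure.times)
    _write_table(p, out / "pressure", fmt)

    imu = session.imu
    ti = np.arange(len(imu.accel)) / imu.fs
    d = pd.DataFrame(imu.accel, columns=["accel_x", "accel_y", "accel_z"])
    d.insert(0, "t", ti)
    if imu.gyro is not None:
        d[["gyro_x", "gyro_y", "gyro_z"]] = imu.gyro
    _write_table(d, out / "imu", fmt)

    tr = session.truth
    pd.DataFrame(tr.contact_intervals, columns=["start", "end"]).to_csv(
        out / "truth_intervals.csv", index=False
    )
    frames = []
    for k, (gv, gap, cen) in enumerate(zip(tr.grf_v, tr.grf_ap, tr.centroids)):
        frames.append(
            pd.DataFrame(
                {
                    "contact": k,
                    "sample": np.arange(len(gv)),
                    "grf_v": gv,
                    "grf_ap": gap,
                    "cop_x": cen[:, 0],
                    "cop_y": cen[:, 1],
                }
            )
        )
    _write_table(pd.concat(frames, ignore_index=True), out / "truth_grf", fmt)
    return out


def read_session(session_dir: str | Path) -> SensorSession:
    d = Path(session_dir)
    meta = json.loads((d / "meta.json").read_text())
    profile = ParticipantProfile(**meta["profile"])
    condition = Condition(**meta["condition"])
    geometry = InsoleGeometry(
        sensor_coords=np.asarray(meta["geometry"]["sensor_coords"]),
        insole_length=meta["geometry"]["insole_length"],
    )
    ft = _read_table(d / "force")
    fs_force = 1.0 / float(np.median(np.diff(ft["t"]))) if len(ft) > 1 else 1000.0
    force = ForceStream(
        fs=round(fs_force), vertical=ft["force_v"].to_numpy(), anteroposterior=ft["force_ap"].to_numpy()
    )
    pt = _read_table(d / "pressure")
    pressure = PressureStream(times=pt["t"].to_numpy(), values=pt[FSR_COLS].to_numpy())
    it = _read_table(d / "imu")
    fs_imu = 1.0 / float(np.median(np.diff(it["t"]))) if len(it) > 1 else 1138.0
    gyro_cols = [c for c in ("gyro_x", "gyro_y", "gyro_z") if c in it.columns]
    imu = ImuStream(
        fs=round(fs_imu),
        accel=it[["accel_x", "accel_y", "accel_z"]].to_numpy(),
        gyro=it[gyro_cols].to_numpy() if gyro_cols else None,
    )
    iv = pd.read_csv(d / "truth_intervals.csv").to_numpy()
    tg = _read_table(d / "truth_grf")
    grf_v, grf_ap, cents = [], [], []
    for k, grp in tg.groupby("contact"):
        grf_v.append(grp["grf_v"].to_numpy())
        grf_ap.append(grp["grf_ap"].to_numpy())
        cents.append(grp[["cop_x", "cop_y"]].to_numpy())
    truth = SessionTruth(
        contact_intervals=iv,
        grf_v=grf_v,
        grf_ap=grf_ap,
        centroids=cents,
        stride_times=np.diff(iv[:, 0]),
    )
    return SensorSession(
        force=force, pressure=pressure, imu=imu,
        device_offsets=meta["device_offsets"], profile=profile, condition=condition,
        geometry=geometry, truth=truth,
    )


# --------------------------------------------------------------------------
# contacts
# --------------------------------------------------------------------------

_CONTACT_META = ("gct", "mass", "speed", "gradient", "insole_length", "participant_id", "condition_id")


def write_contacts(contacts: list[FootContact], path: str | Path, fmt: str = "parquet") -> Path:
    """Long-format contact table: one row per contact x sample, channels as
    columns, discrete descriptors broadcast."""
    frames = []
    for k, c in enumerate(contacts):
        df = pd.DataFrame(c.pressure, columns=FSR_COLS)
        df.insert(0, "sample", np.arange(NORMALIZED_LENGTH))
        df.insert(0, "contact", k)
        df["cop_x"], df["cop_y"] = c.cop_x, c.cop_y
        df[["accel_x", "accel_y", "accel_z"]] = c.accel
        df["force_v"], df["force_ap"] = c.force_v, c.force_ap
        for name in _CONTACT_META:
            df[name] = getattr(c, name)
        frames.append(df)
    return _write_table(pd.concat(frames, ignore_index=True), Path(path), fmt)


def read_contacts(path: str | Path) -> list[FootContact]:
    df = _read_table(Path(path).with_suffix(""))
    contacts = []
    for _, grp in df.groupby("contact"):
        grp = grp.sort_values("sample")
        row = grp.iloc[0]
        contacts.append(
            FootContact(
                force_v=grp["force_v"].to_numpy(),
                force_ap=grp["force_ap"].to_numpy(),
                pressure=grp[FSR_COLS].to_numpy(),
                cop_x=grp["cop_x"].to_numpy(),
                cop_y=grp["cop_y"].to_numpy(),
                accel=grp[["accel_x", "accel_y", "accel_z"]].to_numpy(),
                gct=float(row["gct"]),
                mass=float(row["mass"]),
                speed=float(row["speed"]),
                gradient=float(row["gradient"]),
                insole_length=float(row["insole_length"]),
                participant_id=str(row["participant_id"]),
                condition_id=str(row["condition_id"]),
            )
        )
    return contacts


# --------------------------------------------------------------------------
# feature matrices
# --------------------------------------------------------------------------


def write_feature_matrix(fm: FeatureMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Columnar binary file + JSON sidecar (channel names, flags, row index)."""
    prefix = Path(prefix)
    flat = fm.values.reshape(-1, len(fm.channel_names))
    df = pd.DataFrame(flat, columns=list(fm.channel_names))
    data_path = prefix.with_suffix(".parquet")
    df.to_parquet(data_path, index=False)
    sidecar = {
        "n_contacts": fm.n_contacts,
        "channel_names": list(fm.channel_names),
        "standardized": fm.standardized,
        "contact_index": [list(ci) for ci in fm.contact_index],
    }
    meta_path = prefix.with_suffix(".json")
    meta_path.write_text(json.dumps(sidecar))
    return data_path, meta_path


def read_feature_matrix(prefix: str | Path) -> FeatureMatrix:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    df = pd.read_parquet(prefix.with_suffix(".parquet"))
    values = df[sidecar["channel_names"]].to_numpy().reshape(
        sidecar["n_contacts"], NORMALIZED_LENGTH, len(sidecar["channel_names"])
    )
    return FeatureMatrix(
        values=values,
        channel_names=tuple(sidecar["channel_names"]),
        contact_index=[tuple(ci) for ci in sidecar["contact_index"]],
        standardized=sidecar["standardized"],
    )
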