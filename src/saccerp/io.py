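"""Plain-text and HDF5 interchange formats.

Gaze traces and event tables travel as TSV, EEG as an HDF5 container
with rate/label attributes, drift models and configuration as flat
``key: value`` text. All readers are the inverse of the corresponding
writers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alignment import DriftModel
from .epochs import EEGRecording
from .gaze import GazeTrace

GAZE_COLUMNS = (
    "time_s", "az_deg", "el_deg", "head_x_m", "head_y_m", "head_z_m",
    "head_yaw_deg", "gaze_dist_m",
)


def write_gaze_tsv(path, trace: GazeTrace) -> None:
    n = len(trace)
    head = trace.head_pos if trace.head_pos is not None else np.full((n, 3), np.nan)
    yaw = trace.head_yaw if trace.head_yaw is not None else np.full(n, np.nan)
    dist = trace.gaze_dist if trace.gaze_dist is not None else np.full(n, np.nan)
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "az_deg": trace.az,
            "el_deg": trace.el,
            "head_x_m": head[:, 0],
            "head_y_m": head[:, 1],
            "head_z_m": head[:, 2],
            "head_yaw_deg": yaw,
            "gaze_dist_m": dist,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_gaze_tsv(path, rate: float | None = None) -> GazeTrace:
    df = pd.read_csv(path, sep="\t")
    for col in ("time_s", "az_deg", "el_deg"):
        if col not in df.columns:
            raise ValueError(f"gaze TSV is missing required column {col!r}")
    t = df["time_s"].to_numpy(float)
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t)))
    head = None
    if {"head_x_m", "head_y_m", "head_z_m"} <= set(df.columns):
        head = df[["head_x_m", "head_y_m", "head_z_m"]].to_numpy(float)
        if np.all(np.isnan(head)):
            head = None
    dist = df["gaze_dist_m"].to_numpy(float) if "gaze_dist_m" in df.columns else None
    if dist is not None and np.all(np.isnan(dist)):
        dist = None
    yaw = df["head_yaw_deg"].to_numpy(float) if "head_yaw_deg" in df.columns else None
    return GazeTrace(
        time=t, az=df["az_deg"].to_numpy(float), el=df["el_deg"].to_numpy(float),
        rate=rate, head_pos=head, head_yaw=yaw, gaze_dist=dist,
    )


def write_events_tsv(path, events) -> None:
    from .summaries import events_to_frame

    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    df = df[["onset_s", "offset_s", "kind", "duration_s", "amplitude_deg", "category"]]
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_triggers_tsv(path, samples, metadata: pd.DataFrame | None = None) -> None:
    df = pd.DataFrame({"sample": np.asarray(samples, int)})
    if metadata is not None:
        df = pd.concat([df, metadata.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_triggers_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_eeg_h5(path, eeg: EEGRecording) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        ds = f.create_dataset("eeg", data=eeg.data)
        ds.attrs["rate_hz"] = eeg.rate
        ds.attrs["t0_s"] = eeg.t0
        ds.attrs["labels"] = list(eeg.labels)
        f.create_dataset("bad_mask", data=eeg.bad_mask.astype(np.uint8))


def read_eeg_h5(path) -> EEGRecording:
    import h5py

    with h5py.File(path, "r") as f:
        ds = f["eeg"]
        labels = tuple(
            x.decode() if isinstance(x, bytes) else str(x) for x in ds.attrs["labels"]
        )
        bad = f["bad_mask"][:].astype(bool) if "bad_mask" in f else None
        return EEGRecording(
            data=ds[:], rate=float(ds.attrs["rate_hz"]),
            labels=labels, t0=float(ds.attrs["t0_s"]), bad_mask=bad,
        )


def write_keyvalue(path, mapping: dict) -> None:
    with open(path, "w") as f:
        for k, v in mapping.items():
            f.write(f"{k}: {v!r}\n" if isinstance(v, str) else f"{k}: {v}\n")


def read_keyvalue(path) -> dict:
    out = {}
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition(":")
            v = v.strip()
            try:
                out[k.strip()] = int(v)
            except ValueError:
                try:
                    out[k.strip()] = float(v)
                except ValueError:
                    out[k.strip()] = v.strip("'\"")
    return out


def write_drift(path, model: DriftModel) -> None:
    write_keyvalue(
        path,
        {"offset_s": model.offset, "rate": model.rate, "residual_check_s": model.residual_check},
    )


def read_drift(path) -> DriftModel:
    kv = read_keyvalue(path)
    return DriftModel(
        offset=float(kv["offset_s"]), rate=float(kv["rate"]),
        residual_check=float(kv.get("residual_check_s", 0.0)),
    )
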