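"""Readers and writers for the pipeline's on-disk formats.

Canonical formats (all plain text except TIFF masks):

* localizations — CSV, Thunderstorm dialect by default (columns
  ``"frame","x [nm]","y [nm]","intensity [photon]","uncertainty [nm]"``)
  or a generic dialect (``frame,x,y,intensity,uncertainty``);
* tracks — CSV ``track_id,frame,x_nm,y_nm``;
* spots — CSV ``x_nm,y_nm`` plus ROI metadata in a header comment;
* traces — CSV ``spot_id,frame,intensity``;
* reports/truth — JSON; masks — 8-bit TIFF.

Coordinates are persisted in nm with 0-based frames; files written with
µm units are converted on read when declared via ``units="um"``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ._utils import NM_PER_UM, Rect
from .colocalization import SpotSet
from .dynamics import Track, TrackSet
from .stoichiometry import IntensityTrace

__all__ = [
    "THUNDERSTORM_COLUMNS",
    "read_localizations",
    "write_localizations",
    "read_tracks",
    "write_tracks",
    "read_spots",
    "write_spots",
    "read_traces",
    "write_traces",
    "write_mask",
    "read_mask",
    "write_report",
    "file_checksum",
]

THUNDERSTORM_COLUMNS = {
    "frame": "frame",
    "x [nm]": "x",
    "y [nm]": "y",
    "intensity [photon]": "intensity",
    "uncertainty [nm]": "uncertainty",
}
_GENERIC_COLUMNS = ("frame", "x", "y")


def read_localizations(path, dialect: str = "thunderstorm", units: str = "nm") -> pd.DataFrame:
    """Read a localization table, unit-normalized to nm.

    Malformed (non-numeric) rows are dropped; their count is attached as
    ``df.attrs["n_malformed"]``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if dialect == "thunderstorm":
        missing = [c for c in ("frame", "x [nm]", "y [nm]") if c not in df.columns]
        if missing:
            raise ValueError(f"not a Thunderstorm table, missing columns: {missing}")
        df = df.rename(columns=THUNDERSTORM_COLUMNS)
    elif dialect == "generic":
        missing = [c for c in _GENERIC_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing mandatory columns: {missing}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    n0 = len(df)
    for col in df.columns:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=[c for c in _GENERIC_COLUMNS if c in df.columns]).reset_index(drop=True)
    df.attrs["n_malformed"] = n0 - len(df)
    if units == "um":
        for col in ("x", "y", "uncertainty"):
            if col in df.columns:
                df[col] = df[col] * NM_PER_UM
    elif units != "nm":
        raise ValueError("units must be 'nm' or 'um'")
    df["frame"] = df["frame"].astype(int)
    return df


def write_localizations(df: pd.DataFrame, path, dialect: str = "thunderstorm") -> None:
    path = Path(path)
    out = df.copy()
    if dialect == "thunderstorm":
        inverse = {v: k for k, v in THUNDERSTORM_COLUMNS.items()}
        out = out.rename(columns=inverse)
    out.to_csv(path, index=False)


def read_tracks(path, frame_interval: float = 0.05, units: str = "nm") -> TrackSet:
    """Read a track table CSV (track_id, frame, x_nm, y_nm).

    Unsorted frames within a track are sorted on read and flagged via a
    per-track attribute count in ``TrackSet``; an empty file gives an
    empty set.
    """
    df = pd.read_csv(path, comment="#")
    if df.empty:
        return TrackSet(tracks=[])
    need = {"track_id", "frame", "x_nm", "y_nm"}
    if not need.issubset(df.columns):
        raise ValueError(f"track table must have columns {sorted(need)}")
    scale = NM_PER_UM if units == "um" else 1.0
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                track_id=str(tid),
                frames=grp["frame"].to_numpy(dtype=int),
                positions=grp[["x_nm", "y_nm"]].to_numpy(dtype=float) * scale,
                frame_interval=frame_interval,
                roi_label=str(grp["roi_label"].iloc[0]) if "roi_label" in grp else "unassigned",
            )
        )
    return TrackSet(tracks=tracks)


def write_tracks(tracks: TrackSet, path) -> None:
    rows = []
    for tr in tracks:
        for f, (x, y) in zip(tr.frames, tr.positions):
            rows.append(
                {"track_id": tr.track_id, "frame": int(f), "x_nm": x, "y_nm": y,
                 "roi_label": tr.roi_label}
            )
    pd.DataFrame(rows, columns=["track_id", "frame", "x_nm", "y_nm", "roi_label"]).to_csv(
        path, index=False
    )


def write_spots(spots: SpotSet, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "# roi_x_nm={:.6g} roi_y_nm={:.6g} roi_w_nm={:.6g} roi_h_nm={:.6g} "
            "channel={} cell={}\n".format(
                spots.roi.x, spots.roi.y, spots.roi.w, spots.roi.h,
                spots.channel_label, spots.cell_id,
            )
        )
        pd.DataFrame(spots.points, columns=["x_nm", "y_nm"]).to_csv(fh, index=False)


def read_spots(path) -> SpotSet:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    meta = dict(
        kv.split("=") for kv in header.lstrip("# ").split() if "=" in kv
    )
    roi = Rect(
        float(meta.get("roi_x_nm", 0)), float(meta.get("roi_y_nm", 0)),
        float(meta.get("roi_w_nm", 1)), float(meta.get("roi_h_nm", 1)),
    )
    df = pd.read_csv(path, comment="#")
    return SpotSet(
        points=df[["x_nm", "y_nm"]].to_numpy(dtype=float) if len(df) else np.empty((0, 2)),
        roi=roi,
        channel_label=str(meta.get("channel", "")),
        cell_id=str(meta.get("cell", "")),
    )


def write_traces(traces: list[IntensityTrace], path) -> None:
    rows = []
    for tr in traces:
        for f, v in enumerate(tr.values):
            rows.append({"spot_id": tr.spot_id, "frame": f, "intensity": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traces(path, frame_interval: float = 0.1) -> list[IntensityTrace]:
    df = pd.read_csv(path)
    need = {"spot_id", "frame", "intensity"}
    if not need.issubset(df.columns):
        raise ValueError(f"trace table must have columns {sorted(need)}")
    traces = []
    for sid, grp in df.groupby("spot_id", sort=True):
        grp = grp.sort_values("frame")
        traces.append(
            IntensityTrace(
                values=grp["intensity"].to_numpy(dtype=float),
                frame_interval=frame_interval,
                spot_id=str(sid),
            )
        )
    return traces


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    return obj


def write_report(results: dict, path) -> None:
    """Write an analysis report as JSON (numpy types coerced)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=2)
        fh.write("\n")


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
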