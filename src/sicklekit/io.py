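"""Readers and writers: event TIFFs + CSV manifests, video stacks,
feature tables with parameter sidecars, and JSON configs.

Formats are deliberately plain: multi-page TIFF for pixels (one page
per channel, float32, lossless), CSV for tables, JSON for
configurations and summaries.  No proprietary cytometry formats.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate.shapes import ImageEvent
from .simulate.video import VideoField

__all__ = [
    "write_events",
    "read_events",
    "write_video",
    "write_feature_table",
    "read_feature_table",
    "write_json",
    "read_json",
]


def write_events(
    events: list[ImageEvent],
    out_dir: str | Path,
    truth: pd.DataFrame | None = None,
    manifest_name: str = "manifest.csv",
) -> Path:
    """Write one multi-page TIFF per event plus a CSV manifest.

    Manifest columns: event_id, file, shape_class (if known), channel
    names (semicolon-joined, page order), pixel_size_um, seed.
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_by_id = (
        truth.set_index("event_id") if truth is not None and len(truth) else None
    )
    rows = []
    for ev in events:
        fname = f"{ev.event_id}.tif"
        names = list(ev.channels)
        stack = np.stack([ev.channels[c] for c in names]).astype(np.float32)
        tifffile.imwrite(out_dir / fname, stack, photometric="minisblack")
        row = {
            "event_id": ev.event_id,
            "file": fname,
            "shape_class": ev.meta.get("shape_class", ""),
            "channels": ";".join(names),
            "pixel_size_um": ev.pixel_size_um,
            "seed": "",
        }
        if truth_by_id is not None and ev.event_id in truth_by_id.index:
            t = truth_by_id.loc[ev.event_id]
            row["shape_class"] = t.get("shape_class", row["shape_class"])
            row["seed"] = t.get("seed", "")
        rows.append(row)
    manifest = out_dir / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_events(manifest_path: str | Path) -> tuple[list[ImageEvent], list[dict]]:
    """Load events from a manifest; missing files are recorded, not fatal.

    Returns ``(events, errors)`` where each error is a dict with the
    manifest row number (0-based data row), event id and message.
    """
    manifest_path = Path(manifest_path)
    try:
        manifest = pd.read_csv(manifest_path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed manifest {manifest_path}: {exc}") from exc
    required = {"event_id", "file", "channels", "pixel_size_um"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    events: list[ImageEvent] = []
    errors: list[dict] = []
    for i, row in manifest.iterrows():
        path = manifest_path.parent / str(row["file"])
        try:
            stack = tifffile.imread(path)
        except (FileNotFoundError, OSError) as exc:
            errors.append({"row": int(i), "event_id": row["event_id"], "error": str(exc)})
            continue
        if stack.ndim == 2:
            stack = stack[None]
        names = str(row["channels"]).split(";")
        channels = {name: stack[j] for j, name in enumerate(names)}
        meta = {}
        if "shape_class" in row and not pd.isna(row["shape_class"]):
            meta["shape_class"] = row["shape_class"]
        events.append(
            ImageEvent(
                event_id=str(row["event_id"]),
                channels=channels,
                pixel_size_um=float(row["pixel_size_um"]),
                meta=meta,
            )
        )
    return events, errors


def write_video(
    video: VideoField,
    out_dir: str | Path,
    frame_indices=None,
    stack_name: str = "video.tif",
) -> Path:
    """Write (a sampled subset of) the video as a multi-page TIFF stack,
    plus the cell-centre CSV and the kinetics config as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if frame_indices is None:
        frame_indices = range(video.n_frames)
    frame_indices = [int(i) for i in frame_indices]
    with tifffile.TiffWriter(out_dir / stack_name) as tw:
        for i in frame_indices:
            tw.write(video.frame(i), contiguous=True, photometric="minisblack")
    centers = video.centers.copy()
    centers["true_time_min"] = video.truth["true_time_min"].to_numpy()
    centers.to_csv(out_dir / "cells.csv", index=False)
    write_json(
        {
            "config": asdict(video.config),
            "layout": asdict(video.layout),
            "frame_indices": frame_indices,
        },
        out_dir / "video_config.json",
    )
    return out_dir / stack_name


def write_feature_table(
    features: pd.DataFrame, path: str | Path, params: dict | None = None
) -> Path:
    """Write a feature table CSV with a JSON sidecar of metric parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features.to_csv(path, index=False)
    if params is not None:
        write_json(params, path.with_suffix(".params.json"))
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(data: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(data), fh, indent=2, default=str)
        fh.write("\n")
    return path


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
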