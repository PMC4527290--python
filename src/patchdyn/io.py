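"""File I/O: OME-TIFF movies, CSV tables, run manifests."""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .models import Movie, PatchTrack, SpotDetection

__all__ = [
    "write_movie",
    "read_movie",
    "tracks_to_table",
    "table_to_tracks",
    "write_manifest",
]


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as OME-TIFF (TCYX or TCZYX) with physical metadata."""
    path = Path(path)
    axes = "TCZYX" if movie.has_z else "TCYX"
    meta = {
        "axes": axes,
        "PhysicalSizeX": movie.pixel_size,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": movie.pixel_size,
        "PhysicalSizeYUnit": "µm",
        "TimeIncrement": movie.frame_interval,
        "TimeIncrementUnit": "s",
        "Channel": {"Name": list(movie.channel_names)},
    }
    if movie.has_z and movie.z_step:
        meta["PhysicalSizeZ"] = movie.z_step
        meta["PhysicalSizeZUnit"] = "µm"
    tifffile.imwrite(path, movie.data.astype(np.float32), ome=True,
                     metadata=meta)


def read_movie(path: str | Path, pixel_size_fallback: float = 0.16,
               frame_interval_fallback: float = 2.0) -> Movie:
    """Read an OME-TIFF movie, normalising axes to (T, C, [Z,] Y, X).

    Errors when the file lacks a time axis; missing pixel size or frame
    interval fall back to the supplied defaults with a warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        # generic sequence axes (Q/I) are treated as time, samples as channels
        axes = (series.axes.upper().replace("S", "C").replace("Q", "T")
                .replace("I", "T"))
        data = series.asarray()
        ome = tf.ome_metadata

    for ax in axes:
        if ax not in "TCZYX":
            raise ValueError(f"unsupported axis {ax!r} in {path.name}")
    if "T" not in axes:
        if data.ndim <= 2:
            raise ValueError(f"{path.name}: no time axis (axes={axes!r})")
        # single-frame stacks (T squeezed away on write) are still movies
        data = np.expand_dims(data, 0)
        axes = "T" + axes
    if "C" not in axes:
        data = np.expand_dims(data, axes.index("Y"))
        axes = axes.replace("Y", "CY", 1)

    target = "TCZYX" if "Z" in axes else "TCYX"
    order = [axes.index(a) for a in target]
    data = np.transpose(data, order).astype(np.float32)

    pixel_size = pixel_size_fallback
    frame_interval = frame_interval_fallback
    z_step = None
    channel_names: tuple[str, ...] = tuple(
        f"ch{i}" for i in range(data.shape[1])
    )
    if ome:
        import re

        m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', ome)
        if m:
            pixel_size = float(m.group(1))
        else:
            warnings.warn(f"{path.name}: no PhysicalSizeX; using fallback")
        m = re.search(r'TimeIncrement="([\d.eE+-]+)"', ome)
        if m:
            frame_interval = float(m.group(1))
        m = re.search(r'PhysicalSizeZ="([\d.eE+-]+)"', ome)
        if m:
            z_step = float(m.group(1))
        names = re.findall(r'<Channel[^>]*Name="([^"]+)"', ome)
        if len(names) == data.shape[1]:
            channel_names = tuple(names)
    else:
        warnings.warn(f"{path.name}: no OME metadata; using fallbacks")

    return Movie(data=data, pixel_size=pixel_size,
                 frame_interval=frame_interval, z_step=z_step,
                 channel_names=channel_names)


def tracks_to_table(tracks: list[PatchTrack]) -> pd.DataFrame:
    """Flatten tracks into a (frame, track_id, x, y, ...) table."""
    rows = []
    for tr in tracks:
        for d in tr.detections:
            rows.append({
                "track_id": tr.track_id, "frame": d.frame,
                "channel": d.channel, "x": d.x, "y": d.y,
                "intensity": d.integrated_intensity,
                "background": d.local_background,
            })
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "channel", "x", "y",
                       "intensity", "background"])


def table_to_tracks(table: pd.DataFrame) -> list[PatchTrack]:
    tracks = []
    for tid, grp in table.groupby("track_id"):
        grp = grp.sort_values("frame")
        dets = [
            SpotDetection(frame=int(r.frame), channel=int(r.channel),
                          x=float(r.x), y=float(r.y),
                          integrated_intensity=float(r.intensity),
                          local_background=float(r.background))
            for r in grp.itertuples()
        ]
        tracks.append(PatchTrack(track_id=int(tid), detections=dets,
                                 channel=dets[0].channel))
    return tracks


def write_manifest(out_dir: str | Path, config: dict) -> Path:
    """Write a run manifest (config + software version + config hash)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"software": "patchdyn", "version": __version__,
               "config": config}
    text = json.dumps(payload, indent=2, sort_keys=True, default=str)
    digest = hashlib.sha256(text.encode()).hexdigest()[:16]
    payload["manifest_hash"] = digest
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path
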