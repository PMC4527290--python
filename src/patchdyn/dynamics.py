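"""Patch-dynamics statistics.

Implements the measurements behind the patch-dynamics figures: per-track
lifetime / assembly / disassembly times and peak intensity, distance-from-
origin traces, internalization classification, peak-aligned ensemble
averaging with the reference-channel peak as time zero, molecule-count
calibration, and whole-cell intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import DynamicsSummary, PatchTrack

__all__ = [
    "compute_dynamics",
    "distance_from_origin",
    "classify_internalization",
    "align_to_peak",
    "AlignedEnsemble",
    "intensity_to_molecules",
    "whole_cell_intensity",
    "is_complete",
]

DISPLACEMENT_THRESHOLD_UM = 0.32   # 2 px at 0.16 um/px
MIN_INTERNALIZED_FRAMES = 1


def _peak_index(series: np.ndarray) -> int:
    """Index of the first occurrence of the maximum (ties -> earliest)."""
    finite = np.where(np.isfinite(series), series, -np.inf)
    return int(np.argmax(finite))


def compute_dynamics(track: PatchTrack, intensity: np.ndarray,
                     frame_interval: float) -> DynamicsSummary:
    """Lifetime, assembly/disassembly times and peak intensity of one track.

    ``intensity`` is the track's background-subtracted intensity series, one
    value per frame from first to last detection (NaN allowed in gaps).  The
    peak frame is the first frame attaining the maximum; assembly time runs
    from the first frame to the peak, disassembly from the peak to the last
    frame, so ``lifetime == assembly + disassembly`` exactly.
    """
    intensity = np.asarray(intensity, dtype=float)
    if len(track) < 3:
        raise ValueError("track must have at least 3 detections")
    if len(intensity) != track.frames[-1] - track.frames[0] + 1:
        raise ValueError("intensity series must span the track's frame range")
    ipk = _peak_index(intensity)
    assembly = ipk * frame_interval
    disassembly = (len(intensity) - 1 - ipk) * frame_interval
    return DynamicsSummary(
        track_id=track.track_id,
        lifetime=assembly + disassembly,
        assembly_time=assembly,
        disassembly_time=disassembly,
        peak_intensity=float(intensity[ipk]),
    )


def distance_from_origin(track: PatchTrack, pixel_size: float = 0.16
                         ) -> np.ndarray:
    """Euclidean distance of each detection from the first, in um."""
    pos = track.positions
    d = np.hypot(pos[:, 0] - pos[0, 0], pos[:, 1] - pos[0, 1])
    return d * pixel_size


def classify_internalization(
    track: PatchTrack,
    intensity: np.ndarray,
    pixel_size: float = 0.16,
    displacement_threshold: float = DISPLACEMENT_THRESHOLD_UM,
    min_frames: int = MIN_INTERNALIZED_FRAMES,
) -> bool:
    """Did this patch move away from the cortex after its peak?

    True when the distance from the track origin exceeds
    ``displacement_threshold`` (um) for at least ``min_frames`` consecutive
    detections after the peak-intensity frame.
    """
    if displacement_threshold <= 0:
        raise ValueError("displacement_threshold must be > 0")
    dist = distance_from_origin(track, pixel_size)
    frames = track.frames
    peak_frame = frames[0] + _peak_index(np.asarray(intensity, dtype=float))
    run = best = 0
    for f, d in zip(frames, dist):
        if f <= peak_frame:
            continue
        if d > displacement_threshold:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best >= min_frames


def internalized_percentage(flags: list[bool]) -> float:
    if not flags:
        raise ValueError("no tracks to classify")
    return 100.0 * sum(flags) / len(flags)


@dataclass
class AlignedEnsemble:
    """Peak-aligned ensemble averages.

    ``table`` is indexed by aligned time (s, reference peak = 0) with columns
    ``ch{c}_mean/sd/n`` per channel and ``dist_mean/sd/n``.
    """

    table: pd.DataFrame
    reference_channel: int

    @property
    def aligned_times(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def peak_time(self, channel: int) -> float:
        col = self.table[f"ch{channel}_mean"]
        return float(col.idxmax())


def align_to_peak(track_tables: list[pd.DataFrame], frame_interval: float,
                  reference_channel: int = 0, pixel_size: float = 0.16
                  ) -> AlignedEnsemble:
    """Average intensity and distance traces after aligning reference peaks.

    Each element of ``track_tables`` is a per-track DataFrame indexed by frame
    with ``ch{c}`` intensity columns and x, y positions (as produced by
    ``measure_track_intensity``).  Every track is shifted so its
    reference-channel peak sits at time zero; means, SDs and per-time-point n
    are computed across tracks at each aligned time without interpolation.
    """
    if not track_tables:
        raise ValueError("empty track set")
    channels = sorted(
        int(c[2:]) for c in track_tables[0].columns if c.startswith("ch")
    )
    if reference_channel not in channels:
        raise ValueError(f"reference channel {reference_channel} not measured")

    records: dict[int, dict[str, list[float]]] = {}
    for tab in track_tables:
        ref = tab[f"ch{reference_channel}"].to_numpy(dtype=float)
        ipk = _peak_index(ref)
        frames = tab.index.to_numpy()
        dist = np.hypot(tab["x"] - tab["x"].iloc[0],
                        tab["y"] - tab["y"].iloc[0]).to_numpy() * pixel_size
        for i, f in enumerate(frames):
            rel = int(f - frames[ipk])
            bucket = records.setdefault(rel, {f"ch{c}": [] for c in channels}
                                        | {"dist": []})
            for c in channels:
                v = tab[f"ch{c}"].iloc[i]
                if np.isfinite(v):
                    bucket[f"ch{c}"].append(float(v))
            bucket["dist"].append(float(dist[i]))

    rows = []
    for rel in sorted(records):
        row: dict[str, float] = {"time": rel * frame_interval}
        for key, vals in records[rel].items():
            arr = np.asarray(vals)
            row[f"{key}_mean"] = float(arr.mean()) if arr.size else np.nan
            row[f"{key}_sd"] = float(arr.std(ddof=1)) if arr.size > 1 else np.nan
            row[f"{key}_n"] = int(arr.size)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("time")
    return AlignedEnsemble(table=table, reference_channel=reference_channel)


def intensity_to_molecules(peak_intensity: float | np.ndarray,
                           calibration_factor: float) -> float | np.ndarray:
    """Convert background-subtracted intensity to a fluorophore count.

    ``calibration_factor`` is recorded units per molecule and must come from
    an explicit calibration; it is never guessed.
    """
    if calibration_factor is None or calibration_factor <= 0:
        raise ValueError("calibration_factor must be a positive number")
    return peak_intensity / calibration_factor


def whole_cell_intensity(image: np.ndarray, cell_mask: np.ndarray) -> float:
    """Background-subtracted mean intensity inside a cell mask.

    Mean of the masked pixels minus the median of the extracellular region,
    measured on a single mid-plane confocal section.
    """
    image = np.asarray(image, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != image.shape:
        raise ValueError("mask shape must match image")
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    inside = float(image[cell_mask].mean())
    outside = float(np.median(image[~cell_mask])) if (~cell_mask).any() else 0.0
    return inside - outside


def is_complete(track: PatchTrack, n_frames: int) -> bool:
    """True when the track's whole lifetime lies inside the movie.

    Tracks touching the first or last frame are censored (their birth or
    death was not observed) and are excluded from lifetime ensembles.
    """
    return track.frames[0] > 0 and track.frames[-1] < n_frames - 1
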