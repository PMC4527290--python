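"""Frame-to-frame linking of spot detections and track re-measurement.

Linking is greedy gated nearest-neighbour: for each frame transition, all
(track, detection) pairs within the displacement gate are sorted by distance
and assigned greedily.  Patch densities on the cortex are low, so greedy
assignment matches globally optimal assignment in practice; there is no
split/merge topology.  Ties break on smallest distance, then lowest track id,
then lowest detection index, making the result deterministic and independent
of detection input order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import Movie, PatchTrack, SpotDetection
from .detect import detect_spots, measure_aperture

__all__ = ["link_detections", "measure_track_intensity", "detect_movie",
           "track_movie"]

DEFAULT_MAX_DISP = 4.0   # px per frame
DEFAULT_MAX_GAP = 1      # frames
DEFAULT_MIN_TRACK_LEN = 3


def link_detections(
    detections_per_frame: list[list[SpotDetection]],
    max_disp: float = DEFAULT_MAX_DISP,
    max_gap: int = DEFAULT_MAX_GAP,
    min_track_len: int = DEFAULT_MIN_TRACK_LEN,
) -> list[PatchTrack]:
    """Link per-frame detections into tracks.

    A track that goes unmatched survives ``max_gap`` missing frames (with the
    displacement gate scaled by the elapsed frames) and then terminates;
    unmatched detections seed new tracks.  Tracks shorter than
    ``min_track_len`` detections are dropped.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")

    active: list[list[SpotDetection]] = []
    finished: list[list[SpotDetection]] = []

    for dets in detections_per_frame:
        dets = sorted(dets, key=lambda d: (d.y, d.x))
        if not dets:
            continue
        frame = dets[0].frame
        # retire tracks whose gap exceeded max_gap
        still = []
        for tr in active:
            if frame - tr[-1].frame - 1 > max_gap:
                finished.append(tr)
            else:
                still.append(tr)
        active = still

        pairs = []
        for ti, tr in enumerate(active):
            last = tr[-1]
            span = frame - last.frame
            gate = max_disp * span
            for di, d in enumerate(dets):
                dist = float(np.hypot(d.x - last.x, d.y - last.y))
                if dist <= gate:
                    pairs.append((dist, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            active[ti].append(dets[di])
            used_t.add(ti)
            used_d.add(di)
        for di, d in enumerate(dets):
            if di not in used_d:
                active.append([d])

    finished.extend(active)
    finished.sort(key=lambda tr: (tr[0].frame, tr[0].y, tr[0].x))
    tracks = []
    for chain in finished:
        if len(chain) >= min_track_len:
            tracks.append(PatchTrack(track_id=len(tracks), detections=chain,
                                     channel=chain[0].channel))
    return tracks


def measure_track_intensity(track: PatchTrack, movie: Movie,
                            channels: list[int] | None = None) -> pd.DataFrame:
    """Re-measure aperture-minus-annulus intensity along a track.

    Measures every requested channel at the track's positions, so a
    reference-channel track can report the query-channel intensity at the
    same spot.  Gap frames are interpolated linearly in position.  Values
    where the aperture crosses the image edge are NaN.  Returns a DataFrame
    indexed by frame with one ``ch{c}`` column per channel plus x, y.
    """
    if channels is None:
        channels = list(range(movie.n_channels))
    frames = track.frames
    pos = track.positions
    all_frames = np.arange(frames[0], frames[-1] + 1)
    xs = np.interp(all_frames, frames, pos[:, 0])
    ys = np.interp(all_frames, frames, pos[:, 1])

    rows = []
    for f, x, y in zip(all_frames, xs, ys):
        row: dict[str, float] = {"frame": int(f), "x": x, "y": y}
        for c in channels:
            phot = measure_aperture(movie.frame(int(f), c), x, y)
            row[f"ch{c}"] = np.nan if phot is None else phot[0]
        rows.append(row)
    df = pd.DataFrame(rows).set_index("frame")
    return df


def detect_movie(movie: Movie, channel: int = 0,
                 threshold_k: float = 5.0,
                 psf_sigma: float = 0.10,
                 exclude_mask: np.ndarray | None = None
                 ) -> list[list[SpotDetection]]:
    """Run spot detection on every frame of one channel."""
    out = []
    for t in range(movie.n_frames):
        out.append(
            detect_spots(movie.frame(t, channel), psf_sigma=psf_sigma,
                         threshold_k=threshold_k, pixel_size=movie.pixel_size,
                         frame=t, channel=channel, exclude_mask=exclude_mask)
        )
    return out


def track_movie(movie: Movie, channel: int = 0,
                threshold_k: float = 5.0, psf_sigma: float = 0.10,
                max_disp: float = DEFAULT_MAX_DISP,
                max_gap: int = DEFAULT_MAX_GAP,
                min_track_len: int = DEFAULT_MIN_TRACK_LEN) -> list[PatchTrack]:
    """Detect + link one channel of a movie."""
    dets = detect_movie(movie, channel=channel, threshold_k=threshold_k,
                        psf_sigma=psf_sigma)
    return link_detections(dets, max_disp=max_disp, max_gap=max_gap,
                           min_track_len=min_track_len)
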