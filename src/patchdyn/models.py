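"""Core data containers for the patch-dynamics pipeline.

Everything downstream of the simulator and the detectors speaks in terms of
these types: the imaging model, the rod-cell geometry, the generative event
descriptions (patches, eisosomes, cytoplasmic puncta), rendered movies, and
the measurement records (spot detections, tracks, ridge segments, lane
profiles).

Unit conventions
----------------
* Physical positions are in micrometres; pixel positions are 0-based floats
  with the origin at the centre of the top-left pixel.
* Times are in seconds; frame ``k`` is acquired at ``k * frame_interval``.
* Patch amplitudes are carried as "molecules-equivalent": the rendered photon
  amplitude is ``molecules * photons_per_molecule`` before camera gain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

__all__ = [
    "ImagingModel",
    "CellGeometry",
    "PatchEvent",
    "EisosomeSegment",
    "Punctum",
    "EventSet",
    "GenotypePreset",
    "Movie",
    "SpotDetection",
    "PatchTrack",
    "RidgeSegment",
    "DynamicsSummary",
    "ColocalizationResult",
    "EisosomeCensus",
    "LaneProfileSpec",
    "LaneProfile",
    "Band",
    "BandQuantification",
]

REF_CHANNEL = 0
QUERY_CHANNEL = 1


@dataclass(frozen=True)
class ImagingModel:
    """Acquisition model for a spinning-disc confocal time lapse.

    Defaults reflect a 100x objective with 16-um camera pixels (0.16 um/px),
    2-s frames for 1 min, and 0.4-um z-steps for the top-surface stacks.
    """

    pixel_size: float = 0.16            # um / pixel
    frame_interval: float = 2.0         # s
    n_frames: int = 31
    psf_sigma: float = 0.10             # um (lateral Gaussian PSF sd)
    background_level: float = 100.0     # photons / pixel
    camera_gain: float = 1.0            # recorded units / photon
    read_noise_sd: float = 2.0          # recorded units
    z_step: float = 0.4                 # um
    bit_depth: int = 16
    photons_per_molecule: float = 10.0  # photons per fluorophore at patch peak
    fov_shape: tuple[int, int] = (48, 96)  # (ny, nx) pixels

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size

    @property
    def duration(self) -> float:
        """Time span covered by the movie (first to last frame), seconds."""
        return (self.n_frames - 1) * self.frame_interval

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def calibration_factor(self) -> float:
        """Recorded intensity units per fluorophore (for molecule counting)."""
        return self.camera_gain * self.photons_per_molecule

    @property
    def max_value(self) -> float:
        return float(2**self.bit_depth - 1)


@dataclass(frozen=True)
class CellGeometry:
    """Rod-shaped fission-yeast cell: a rectangle capped by two semicircles.

    ``orientation`` rotates the long axis anticlockwise from +x. The cortex is
    the rod outline; arc length ``s`` parameterises it starting at the bottom
    left corner of the straight section and running anticlockwise.
    """

    center: tuple[float, float] = (7.68, 3.84)  # um
    half_length: float = 5.5                    # um, centre to tip
    radius: float = 1.8                         # um
    orientation: float = 0.0                    # radians

    def __post_init__(self) -> None:
        if not (self.half_length >= self.radius > 0):
            raise ValueError("require half_length >= radius > 0")

    @property
    def side_length(self) -> float:
        """Length of each straight cortex segment, um."""
        return 2.0 * (self.half_length - self.radius)

    @property
    def perimeter(self) -> float:
        return 2.0 * self.side_length + 2.0 * math.pi * self.radius

    @property
    def projected_area(self) -> float:
        """Top-view footprint of the rod, um^2."""
        return self.side_length * 2.0 * self.radius + math.pi * self.radius**2

    def _to_world(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        wx = self.center[0] + c * x - s * y
        wy = self.center[1] + s * x + c * y
        return np.stack([wx, wy], axis=-1)

    def _rot_vec(self, vx: np.ndarray, vy: np.ndarray) -> np.ndarray:
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        return np.stack([c * vx - s * vy, s * vx + c * vy], axis=-1)

    def point_at(self, s: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cortex point and inward unit normal at arc length ``s``.

        Returns ``(position, inward_normal)``, each shaped ``(..., 2)`` in um.
        """
        s = np.asarray(s, dtype=float) % self.perimeter
        L, r = self.side_length, self.radius
        a = self.half_length - self.radius  # half of the straight section
        x = np.empty_like(s)
        y = np.empty_like(s)
        nx = np.empty_like(s)
        ny = np.empty_like(s)

        # bottom side: left -> right
        m = s < L
        x[m] = -a + s[m]
        y[m] = -r
        nx[m], ny[m] = 0.0, 1.0
        # right cap
        m = (s >= L) & (s < L + math.pi * r)
        th = (s[m] - L) / r - math.pi / 2.0
        x[m] = a + r * np.cos(th)
        y[m] = r * np.sin(th)
        nx[m], ny[m] = -np.cos(th), -np.sin(th)
        # top side: right -> left
        m = (s >= L + math.pi * r) & (s < 2 * L + math.pi * r)
        x[m] = a - (s[m] - L - math.pi * r)
        y[m] = r
        nx[m], ny[m] = 0.0, -1.0
        # left cap
        m = s >= 2 * L + math.pi * r
        th = (s[m] - 2 * L - math.pi * r) / r + math.pi / 2.0
        x[m] = -a + r * np.cos(th)
        y[m] = r * np.sin(th)
        nx[m], ny[m] = -np.cos(th), -np.sin(th)

        return self._to_world(x, y), self._rot_vec(nx, ny)

    def side_arcs(self) -> list[tuple[float, float]]:
        """Arc-length intervals of the two straight cortex segments."""
        L, r = self.side_length, self.radius
        return [(0.0, L), (L + math.pi * r, 2 * L + math.pi * r)]

    def mask(self, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
        """Boolean interior mask of the rod on a pixel grid."""
        ny, nx = shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        px = xx * pixel_size - self.center[0]
        py = yy * pixel_size - self.center[1]
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        lx = c * px + s * py   # along long axis
        ly = -s * px + c * py
        a = self.half_length - self.radius
        dx = np.maximum(np.abs(lx) - a, 0.0)
        return dx**2 + ly**2 <= self.radius**2


@dataclass
class PatchEvent:
    """One endocytic patch with a triangular intensity time course.

    The amplitude is 0 at ``birth_time - support_pad`` and at
    ``birth_time + lifetime + support_pad``, rising linearly to
    ``peak_molecules`` at ``birth_time + assembly_time``.  ``support_pad``
    (one frame interval by default) implements the instantaneous-appearance
    convention: the patch is already visible at the frame acquired at
    ``birth_time``, and the frame-grid span first..last visible frame equals
    ``lifetime`` exactly for grid-aligned events, making the generative times
    directly recoverable by the tracking pipeline.

    Per-channel behaviour: the query channel's whole time course is shifted
    *earlier* by ``query_lead`` seconds (the query marker both appears and
    peaks before the reference marker) and scaled by ``query_amplitude``.
    If ``internalizes``, the patch moves from the cortex along the inward
    normal at ``internalization_speed`` starting at the reference peak time,
    travelling at most ``max_depth``.
    """

    birth_time: float
    assembly_time: float
    disassembly_time: float
    peak_molecules: float
    cortex_position: tuple[float, float]   # um
    inward_normal: tuple[float, float]
    internalizes: bool
    internalization_speed: float = 0.10    # um/s
    max_depth: float = 1.2                 # um
    query_amplitude: float = 0.0           # relative to reference amplitude
    query_lead: float = 1.5                # s
    support_pad: float = 2.0               # s

    def __post_init__(self) -> None:
        if self.assembly_time <= 0 or self.disassembly_time <= 0:
            raise ValueError("assembly and disassembly times must be > 0")
        if self.peak_molecules <= 0:
            raise ValueError("peak_molecules must be > 0")

    @property
    def lifetime(self) -> float:
        return self.assembly_time + self.disassembly_time

    @property
    def peak_time(self) -> float:
        return self.birth_time + self.assembly_time

    @property
    def death_time(self) -> float:
        return self.birth_time + self.lifetime

    def amplitude(self, t: float, channel: int = REF_CHANNEL) -> float:
        """Molecules-equivalent amplitude at time ``t`` for ``channel``."""
        scale = 1.0 if channel == REF_CHANNEL else self.query_amplitude
        if scale == 0.0:
            return 0.0
        tt = t if channel == REF_CHANNEL else t + self.query_lead
        pad = self.support_pad
        t0 = self.birth_time - pad
        tp = self.peak_time
        t1 = self.death_time + pad
        if tt <= t0 or tt >= t1:
            return 0.0
        if tt <= tp:
            frac = (tt - t0) / (tp - t0)
        else:
            frac = (t1 - tt) / (t1 - tp)
        return scale * self.peak_molecules * frac

    def position(self, t: float) -> tuple[float, float]:
        """Patch centre at time ``t`` in um (both channels move together)."""
        if not self.internalizes or t <= self.peak_time:
            return self.cortex_position
        d = min(self.internalization_speed * (t - self.peak_time), self.max_depth)
        return (
            self.cortex_position[0] + d * self.inward_normal[0],
            self.cortex_position[1] + d * self.inward_normal[1],
        )


@dataclass
class EisosomeSegment:
    """Static linear cortical membrane domain.

    ``intensity_per_length`` is the photon line density (photons/um) at unit
    channel amplitude; ``channel_amplitudes`` scales it per channel.
    """

    p0: tuple[float, float]  # um
    p1: tuple[float, float]  # um
    intensity_per_length: float
    channel_amplitudes: tuple[float, float]

    @property
    def length(self) -> float:
        return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])

    @property
    def midpoint(self) -> tuple[float, float]:
        return ((self.p0[0] + self.p1[0]) / 2.0, (self.p0[1] + self.p1[1]) / 2.0)


@dataclass
class Punctum:
    """Static point source (e.g. cytoplasmic light-chain aggregate)."""

    position: tuple[float, float]  # um
    amplitude: float               # photons
    channel: int = QUERY_CHANNEL


@dataclass
class EventSet:
    """Simulator ground truth for one cell/movie."""

    cell: CellGeometry
    patches: list[PatchEvent]
    eisosomes: list[EisosomeSegment]
    puncta: list[Punctum]
    seed: int

    def truth_table(self) -> pd.DataFrame:
        """One row per patch event with all generative parameters."""
        rows = []
        for i, p in enumerate(self.patches):
            rows.append(
                {
                    "event_id": i,
                    "birth_time": p.birth_time,
                    "assembly_time": p.assembly_time,
                    "disassembly_time": p.disassembly_time,
                    "lifetime": p.lifetime,
                    "peak_molecules": p.peak_molecules,
                    "x_um": p.cortex_position[0],
                    "y_um": p.cortex_position[1],
                    "internalizes": p.internalizes,
                    "internalization_speed": p.internalization_speed,
                    "query_amplitude": p.query_amplitude,
                    "query_lead": p.query_lead,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "event_id", "birth_time", "assembly_time", "disassembly_time",
                "lifetime", "peak_molecules", "x_um", "y_um", "internalizes",
                "internalization_speed", "query_amplitude", "query_lead",
            ],
        )


@dataclass(frozen=True)
class GenotypePreset:
    """Generative parameters of one genotype.

    Means/SDs come from the published patch-dynamics measurements for this
    genotype; probabilities encode how often the query-channel marker decorates
    patches, how often patches internalize, and how strongly the query marker
    accumulates on eisosomes relative to the unstable-mutant baseline.
    """

    name: str
    patch_rate: float                      # patches per um of cortex per s
    lifetime_mean_sd: tuple[float, float]  # s
    assembly_mean_sd: tuple[float, float]  # s
    peak_molecules_mean_sd: tuple[float, float]
    internalization_prob: float
    query_channel_on_patches_prob: float
    eisosome_amplitude: float              # query channel, relative units
    eisosome_ref_amplitude: float = 0.0    # reference channel
    cytoplasmic_puncta_rate: float = 0.0   # expected puncta per cell
    puncta_channel: int = QUERY_CHANNEL

    def __post_init__(self) -> None:
        for p in (self.internalization_prob, self.query_channel_on_patches_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class Movie:
    """Multichannel time-lapse pixel data plus physical metadata.

    ``data`` is ``(T, C, Y, X)`` or ``(T, C, Z, Y, X)`` float32 in recorded
    camera units.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    z_step: float | None = None
    channel_names: tuple[str, ...] = ("ref_mCherry", "query_mGFP")

    def __post_init__(self) -> None:
        if self.data.ndim not in (4, 5):
            raise ValueError("movie data must be (T,C,Y,X) or (T,C,Z,Y,X)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def has_z(self) -> bool:
        return self.data.ndim == 5

    def frame(self, t: int, channel: int, z: int | None = None) -> np.ndarray:
        if self.has_z:
            return self.data[t, channel, 0 if z is None else z]
        return self.data[t, channel]


@dataclass
class SpotDetection:
    """Sub-pixel spot measurement in a single frame/channel."""

    frame: int
    channel: int
    x: float                    # pixels
    y: float                    # pixels
    integrated_intensity: float  # aperture sum minus annulus background
    local_background: float      # per-pixel annulus background estimate


@dataclass
class PatchTrack:
    """Time-ordered chain of detections for one patch (gaps allowed)."""

    track_id: int
    detections: list[SpotDetection]
    channel: int = REF_CHANNEL

    def __post_init__(self) -> None:
        frames = [d.frame for d in self.detections]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing")

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        return np.array([[d.x, d.y] for d in self.detections], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([d.integrated_intensity for d in self.detections])

    def __len__(self) -> int:
        return len(self.detections)


@dataclass
class RidgeSegment:
    """Skeletonised curvilinear structure on a projection image."""

    polyline: np.ndarray        # (N, 2) pixel coordinates (x, y), ordered
    length: float               # um
    mean_intensity: float       # background-subtracted units per um

    @property
    def midpoint(self) -> np.ndarray:
        return self.polyline[len(self.polyline) // 2]


@dataclass
class DynamicsSummary:
    """Per-track dynamics statistics (times in s)."""

    track_id: int
    lifetime: float
    assembly_time: float
    disassembly_time: float
    peak_intensity: float
    internalized: bool | None = None
    max_displacement: float | None = None   # um
    peak_molecules: float | None = None


@dataclass
class ColocalizationResult:
    """Object-based colocalization count for one object class."""

    n_reference_objects: int
    n_colocalized: int
    window_px: float
    rule: str  # "lifetime" or "static"

    @property
    def fraction(self) -> float | None:
        if self.n_reference_objects == 0:
            return None
        return self.n_colocalized / self.n_reference_objects


@dataclass
class EisosomeCensus:
    n_segments: int
    projected_area: float          # um^2
    total_query_intensity: float   # background-subtracted units

    @property
    def density(self) -> float:
        return self.n_segments / self.projected_area


@dataclass
class LaneProfileSpec:
    """Generative description of a 1-D gel lane.

    ``band_fractions`` apportion ``total_amount`` among bands; areas are in
    profile units integrated over the log10(kDa) axis.  ``baseline`` holds
    polynomial coefficients (numpy ``polyval`` order) evaluated on a [0, 1]
    normalised axis coordinate.
    """

    band_mws: tuple[float, ...] = (150.0, 40.0, 30.0)   # kDa
    band_fractions: tuple[float, ...] = (0.30, 0.60, 0.10)
    total_amount: float = 1.0
    band_width_sd: float = 3.0        # kDa, at each band centre
    baseline: tuple[float, ...] = (0.0,)
    noise_sd: float = 0.0             # profile units
    mw_range: tuple[float, float] = (15.0, 250.0)
    n_points: int = 1200
    label: str = ""

    def __post_init__(self) -> None:
        if self.total_amount < 0:
            raise ValueError("total_amount must be >= 0")
        if any(f < 0 for f in self.band_fractions):
            raise ValueError("band fractions must be >= 0")
        if abs(sum(self.band_fractions) - 1.0) > 1e-9:
            raise ValueError("band_fractions must sum to 1")

    def true_areas(self) -> dict[float, float]:
        return {mw: self.total_amount * f
                for mw, f in zip(self.band_mws, self.band_fractions)}


@dataclass
class LaneProfile:
    """Densitometry input: intensity over a log10-molecular-weight axis."""

    axis: np.ndarray       # log10(kDa), strictly monotone increasing
    intensity: np.ndarray
    lane_label: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    @property
    def mw(self) -> np.ndarray:
        return 10.0 ** self.axis


@dataclass
class Band:
    center_mw: float   # kDa
    area: float        # units * log10(kDa)
    left: int          # sample index of band extent
    right: int


@dataclass
class BandQuantification:
    lane_label: str
    bands: list[Band]
    total_intensity: float
    full_length_intensity: float
    normalized_total: float | None = None
    normalized_full_length: float | None = None

    @property
    def full_length_fraction(self) -> float | None:
        if self.total_intensity <= 0:
            return None
        return self.full_length_intensity / self.total_intensity
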