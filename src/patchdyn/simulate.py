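"""Synthetic-data generator.

Produces two-channel time-lapse movies of a rod-shaped cell with cortical
endocytic patches, static linear eisosomes and static cytoplasmic puncta,
plus 1-D gel lane profiles — each with an exported ground truth so that every
downstream measurement can be validated by parameter recovery.

Event model
-----------
Patch birth times are drawn on the frame grid, uniformly over
``[-max_lifetime, duration]``; lifetimes, assembly times and peak amplitudes
come from the genotype preset's normal distributions, quantised to the frame
grid (SDs are several frame intervals, so quantisation is nearly unbiased).
Intensities follow a triangular rise/fall; internalizing patches move inward
from the cortex after the peak.  Temporally overlapping patches are kept at
least ``min_spacing`` apart on the cortex so that nearby endocytic sites do
not merge into a single diffraction-limited spot.

Rendering sums, per frame and channel, a background level, an optional
uniform cytoplasmic level inside the cell, static layers (eisosome line
integrals, puncta) and the Gaussian-PSF footprints of the live patches; the
recorded image is ``gain * Poisson(ideal) + N(0, read_noise)`` clipped to the
camera bit depth.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .models import (
    CellGeometry,
    EisosomeSegment,
    EventSet,
    GenotypePreset,
    ImagingModel,
    LaneProfile,
    LaneProfileSpec,
    Movie,
    PatchEvent,
    Punctum,
)
from .presets import sim_globals

__all__ = [
    "simulate_events",
    "render_movie",
    "render_frame",
    "render_projection",
    "render_zstack",
    "simulate_lane",
]

#: axial weighting sd used for z-stack slices, um
Z_SIGMA = 0.30

MIN_PATCH_SPACING = 1.0  # um between temporally overlapping patches


def _quantize(value: float, dt: float, minimum: float) -> float:
    return max(minimum, round(value / dt) * dt)


def simulate_events(
    preset: GenotypePreset,
    cell: CellGeometry | None = None,
    imaging: ImagingModel | None = None,
    seed: int = 0,
    n_eisosomes: int | None = None,
) -> EventSet:
    """Draw a ground-truth event set for one cell and movie duration.

    Fully reproducible for a given ``seed``.  Eisosome segments are placed
    non-overlapping along the straight cortex sections; patches are uniform
    over the whole cortex, rejected against temporally overlapping neighbours
    closer than 1 um.
    """
    cell = cell or CellGeometry()
    imaging = imaging or ImagingModel()
    g = sim_globals()
    rng = np.random.default_rng(seed)
    # independent streams so the static scenery for a given seed is identical
    # across genotypes (pairs renders for between-genotype comparisons)
    rng_eis = np.random.default_rng([seed, 1])
    rng_pun = np.random.default_rng([seed, 2])
    dt = imaging.frame_interval
    duration = imaging.duration

    lt_mean, lt_sd = preset.lifetime_mean_sd
    as_mean, as_sd = preset.assembly_mean_sd
    pk_mean, pk_sd = preset.peak_molecules_mean_sd
    max_lifetime = lt_mean + 4.0 * lt_sd

    # --- patches ------------------------------------------------------
    window = duration + max_lifetime
    n_patches = rng.poisson(preset.patch_rate * cell.perimeter * window)
    first_frame = -int(math.ceil(max_lifetime / dt))
    patches: list[PatchEvent] = []
    for _ in range(n_patches):
        birth = rng.integers(first_frame, imaging.n_frames) * dt
        assembly = _quantize(rng.normal(as_mean, as_sd), dt, dt)
        lifetime = _quantize(rng.normal(lt_mean, lt_sd), dt, 2 * dt)
        if lifetime < assembly + dt:
            lifetime = assembly + dt
        disassembly = lifetime - assembly
        peak = max(rng.normal(pk_mean, pk_sd), 0.05 * pk_mean)
        internalizes = bool(rng.random() < preset.internalization_prob)
        has_query = rng.random() < preset.query_channel_on_patches_prob

        pos = norm = None
        for _try in range(200):
            s = rng.uniform(0.0, cell.perimeter)
            p, n = cell.point_at(s)
            ok = True
            margin = 3.0 * dt  # refractory period of an endocytic site
            for other in patches:
                if (other.birth_time - margin <= birth + lifetime
                        and birth <= other.death_time + margin):
                    d = math.hypot(p[0] - other.cortex_position[0],
                                   p[1] - other.cortex_position[1])
                    if d < MIN_PATCH_SPACING:
                        ok = False
                        break
            if ok:
                pos, norm = p, n
                break
        if pos is None:  # crowded cortex: accept the last draw
            pos, norm = p, n

        patches.append(
            PatchEvent(
                birth_time=float(birth),
                assembly_time=assembly,
                disassembly_time=disassembly,
                peak_molecules=float(peak),
                cortex_position=(float(pos[0]), float(pos[1])),
                inward_normal=(float(norm[0]), float(norm[1])),
                internalizes=internalizes,
                internalization_speed=float(g["internalization_speed_um_s"]),
                max_depth=float(g["internalization_max_depth_um"]),
                query_amplitude=float(g["query_amplitude_scale"]) if has_query else 0.0,
                query_lead=float(g["query_lead_s"]),
                support_pad=dt,
            )
        )

    # --- eisosomes ----------------------------------------------------
    # Non-overlapping placement along the two straight cortex sections:
    # each side is divided into equal slots and one segment is dropped into
    # each slot with a random length and offset.
    n_eis = int(g["eisosome_count"]) if n_eisosomes is None else n_eisosomes
    lmin, lmax = g["eisosome_length_um"]
    arcs = cell.side_arcs()
    eisosomes: list[EisosomeSegment] = []
    gap = 0.6  # um clearance inside each slot (PSF must not bridge segments)
    per_side = [n_eis // 2 + (1 if i < n_eis % 2 else 0) for i in range(2)]
    for (a0, a1), n_side in zip(arcs, per_side):
        if n_side == 0:
            continue
        slot = (a1 - a0) / n_side
        if slot - gap < min(lmin, 0.5):
            raise ValueError(
                "cell geometry too small to place the requested eisosomes"
            )
        for k in range(n_side):
            lo = min(lmin, slot - gap)
            hi = min(lmax, slot - gap)
            length = rng_eis.uniform(lo, hi) if hi > lo else hi
            start = (a0 + k * slot + gap / 2.0
                     + rng_eis.uniform(0.0, max(slot - length - gap, 0.0)))
            p0, _ = cell.point_at(start)
            p1, _ = cell.point_at(start + length)
            eisosomes.append(
                EisosomeSegment(
                    p0=(float(p0[0]), float(p0[1])),
                    p1=(float(p1[0]), float(p1[1])),
                    intensity_per_length=float(g["eisosome_photons_per_um"]),
                    channel_amplitudes=(
                        float(preset.eisosome_ref_amplitude),
                        float(preset.eisosome_amplitude),
                    ),
                )
            )

    # --- cytoplasmic puncta ------------------------------------------
    puncta: list[Punctum] = []
    n_puncta = rng_pun.poisson(preset.cytoplasmic_puncta_rate)
    interior = cell.half_length - cell.radius
    for _ in range(n_puncta):
        for _try in range(200):
            lx = rng_pun.uniform(-cell.half_length + 0.3, cell.half_length - 0.3)
            ly = rng_pun.uniform(-cell.radius + 0.3, cell.radius - 0.3)
            dx = max(abs(lx) - interior, 0.0)
            if dx**2 + ly**2 <= (cell.radius - 0.3) ** 2:
                break
        c, s = math.cos(cell.orientation), math.sin(cell.orientation)
        puncta.append(
            Punctum(
                position=(cell.center[0] + c * lx - s * ly,
                          cell.center[1] + s * lx + c * ly),
                amplitude=float(g["puncta_photons"]),
                channel=preset.puncta_channel,
            )
        )

    return EventSet(cell=cell, patches=patches, eisosomes=eisosomes,
                    puncta=puncta, seed=seed)


# ---------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------

def _add_gaussian(img: np.ndarray, x: float, y: float, amp: float,
                  sigma: float) -> None:
    """Add an integrated-amplitude Gaussian spot at pixel position (x, y)."""
    if amp <= 0:
        return
    ny, nx = img.shape
    r = int(math.ceil(5.0 * sigma)) + 1
    x0, x1 = int(math.floor(x)) - r, int(math.floor(x)) + r + 1
    y0, y1 = int(math.floor(y)) - r, int(math.floor(y)) + r + 1
    cx0, cx1 = max(x0, 0), min(x1, nx)
    cy0, cy1 = max(y0, 0), min(y1, ny)
    if cx0 >= cx1 or cy0 >= cy1:
        return
    xs = np.arange(cx0, cx1) - x
    ys = np.arange(cy0, cy1) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma**2))
    img[cy0:cy1, cx0:cx1] += amp / (2.0 * math.pi * sigma**2) * g


def _static_layers(events: EventSet, imaging: ImagingModel,
                   n_channels: int = 2) -> np.ndarray:
    """Noise-free photon images of the static structures, per channel."""
    ny, nx = imaging.fov_shape
    px = imaging.pixel_size
    sig = imaging.psf_sigma_px
    out = np.zeros((n_channels, ny, nx), dtype=float)
    step = 0.25  # px, line discretisation
    for e in events.eisosomes:
        length_px = e.length / px
        n_pts = max(int(math.ceil(length_px / step)), 2)
        ts = (np.arange(n_pts) + 0.5) / n_pts
        seg_amp = e.intensity_per_length * e.length / n_pts  # photons per point
        for c in range(n_channels):
            a = e.channel_amplitudes[c] if c < len(e.channel_amplitudes) else 0.0
            if a <= 0:
                continue
            for t in ts:
                xp = (e.p0[0] + t * (e.p1[0] - e.p0[0])) / px
                yp = (e.p0[1] + t * (e.p1[1] - e.p0[1])) / px
                _add_gaussian(out[c], xp, yp, a * seg_amp, sig)
    for p in events.puncta:
        _add_gaussian(out[p.channel], p.position[0] / px, p.position[1] / px,
                      p.amplitude, sig)
    return out


def _ideal_frame(events: EventSet, imaging: ImagingModel, t: float,
                 static: np.ndarray, cytoplasm: np.ndarray | None,
                 clip_warned: list[bool]) -> np.ndarray:
    ny, nx = imaging.fov_shape
    n_channels = static.shape[0]
    ideal = np.full((n_channels, ny, nx), imaging.background_level, dtype=float)
    ideal += static
    if cytoplasm is not None:
        ideal += cytoplasm
    sig = imaging.psf_sigma_px
    px = imaging.pixel_size
    for ev in events.patches:
        pos = ev.position(t)
        xp, yp = pos[0] / px, pos[1] / px
        if not (0 <= xp < nx and 0 <= yp < ny) and not clip_warned[0]:
            warnings.warn("patch event outside field of view; clipped")
            clip_warned[0] = True
        for c in range(n_channels):
            amp = ev.amplitude(t, c) * imaging.photons_per_molecule
            _add_gaussian(ideal[c], xp, yp, amp, sig)
    return ideal


def render_frame(events: EventSet, imaging: ImagingModel, t: float,
                 noise: bool = True, seed: int = 0,
                 cytoplasm_level: float | None = None) -> np.ndarray:
    """Render a single 2-channel frame at time ``t`` (C, Y, X)."""
    static = _static_layers(events, imaging)
    cyto = _cytoplasm(events, imaging, cytoplasm_level)
    ideal = _ideal_frame(events, imaging, t, static, cyto, [False])
    return _record(ideal, imaging, np.random.default_rng(seed), noise)


def _cytoplasm(events: EventSet, imaging: ImagingModel,
               level: float | None) -> np.ndarray | None:
    if level is None:
        level = float(sim_globals()["cytoplasm_photons"])
    if level <= 0:
        return None
    mask = events.cell.mask(imaging.fov_shape, imaging.pixel_size)
    return level * mask.astype(float)


def _record(ideal: np.ndarray, imaging: ImagingModel, rng: np.random.Generator,
            noise: bool) -> np.ndarray:
    if noise:
        img = imaging.camera_gain * rng.poisson(ideal).astype(float)
        if imaging.read_noise_sd > 0:
            img += rng.normal(0.0, imaging.read_noise_sd, size=img.shape)
    else:
        img = imaging.camera_gain * ideal
    return np.clip(img, 0.0, imaging.max_value).astype(np.float32)


def render_movie(events: EventSet, imaging: ImagingModel | None = None,
                 seed: int = 0, noise: bool = True,
                 cytoplasm_level: float | None = None) -> Movie:
    """Render the full (T, C, Y, X) movie for an event set.

    With ``noise=False`` the output is the ideal photon image times the
    camera gain — the photon-conservation oracle for the detector tests.
    """
    imaging = imaging or ImagingModel()
    rng = np.random.default_rng(seed)
    static = _static_layers(events, imaging)
    cyto = _cytoplasm(events, imaging, cytoplasm_level)
    clip_warned = [False]
    frames = []
    for t in imaging.frame_times:
        ideal = _ideal_frame(events, imaging, float(t), static, cyto, clip_warned)
        frames.append(_record(ideal, imaging, rng, noise))
    return Movie(
        data=np.stack(frames, axis=0),
        pixel_size=imaging.pixel_size,
        frame_interval=imaging.frame_interval,
    )


def render_zstack(events: EventSet, imaging: ImagingModel | None = None,
                  t: float = 0.0, n_slices: int = 3, seed: int = 0,
                  noise: bool = True,
                  cytoplasm_level: float | None = None) -> np.ndarray:
    """Render a (C, Z, Y, X) stack around the structure plane at time ``t``.

    Slices sit at ``z_step`` spacing; cortical structures live at z = 0 and
    are attenuated in the flanking slices by a Gaussian axial profile.
    """
    imaging = imaging or ImagingModel()
    rng = np.random.default_rng(seed)
    static = _static_layers(events, imaging)
    cyto = _cytoplasm(events, imaging, cytoplasm_level)
    base = _ideal_frame(events, imaging, t, static, cyto, [True])
    bg = imaging.background_level
    slices = []
    offsets = (np.arange(n_slices) - (n_slices - 1) / 2.0) * imaging.z_step
    for dz in offsets:
        w = math.exp(-(dz**2) / (2.0 * Z_SIGMA**2))
        ideal = bg + (base - bg) * w
        slices.append(_record(ideal, imaging, rng, noise))
    return np.stack(slices, axis=1)  # (C, Z, Y, X)


def render_projection(events: EventSet, imaging: ImagingModel | None = None,
                      t: float = 0.0, seed: int = 0,
                      noise: bool = True,
                      cytoplasm_level: float = 0.0) -> np.ndarray:
    """Top-surface projection emulation: a single (C, Y, X) snapshot.

    The generator lays all cortical structures out in one plane, so the
    projected top-surface view is rendered directly rather than by stacking.
    Top-surface sections graze the plasma membrane above most of the cytosol,
    so the diffuse cytoplasmic level defaults to zero here (mid-plane frames
    keep it).
    """
    imaging = imaging or ImagingModel()
    rng = np.random.default_rng(seed)
    static = _static_layers(events, imaging)
    cyto = _cytoplasm(events, imaging, cytoplasm_level)
    ideal = _ideal_frame(events, imaging, t, static, cyto, [True])
    return _record(ideal, imaging, rng, noise)


# ---------------------------------------------------------------------
# gel lanes
# ---------------------------------------------------------------------

def simulate_lane(spec: LaneProfileSpec, seed: int = 0) -> LaneProfile:
    """Generate a 1-D lane profile over a log10(kDa) axis.

    Each band is a Gaussian in log-molecular-weight whose *area* (integrated
    over the log axis) is ``total_amount * fraction``; the stated kDa band
    width is converted to log units at the band centre.
    """
    axis = np.linspace(math.log10(spec.mw_range[0]),
                       math.log10(spec.mw_range[1]), spec.n_points)
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    profile = np.polyval(spec.baseline, u).astype(float)
    for mw, frac in zip(spec.band_mws, spec.band_fractions):
        area = spec.total_amount * frac
        if area <= 0:
            continue
        sigma_log = spec.band_width_sd / (mw * math.log(10.0))
        mu = math.log10(mw)
        profile += area / (sigma_log * math.sqrt(2.0 * math.pi)) * np.exp(
            -((axis - mu) ** 2) / (2.0 * sigma_log**2)
        )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        profile = profile + rng.normal(0.0, spec.noise_sd, size=profile.shape)
    return LaneProfile(axis=axis, intensity=profile, lane_label=spec.label)
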