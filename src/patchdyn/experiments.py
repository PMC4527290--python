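"""End-to-end recovery experiments.

Each function here runs the full measurement chain — simulate movies from a
genotype preset, detect, link, measure — and reports ensemble statistics that
can be compared against the generative truth.  They are the building blocks
of the acceptance checks and of the genotype report.

Recovery runs use 120-s movies (61 frames at the standard 2-s interval)
rather than the 1-min acquisition default: long-lived mutant patches must fit
entirely inside the movie, and a short movie would preferentially sample
short-lived patches (length-biased censoring).  Only tracks that start after
the first frame and end before the last are pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .coloc import coloc_over_lifetime, coloc_static, eisosome_census
from .detect import detect_ridges, static_ridge_mask
from .dynamics import (
    classify_internalization,
    compute_dynamics,
    intensity_to_molecules,
    is_complete,
)
from .models import (
    QUERY_CHANNEL,
    REF_CHANNEL,
    EventSet,
    GenotypePreset,
    ImagingModel,
    LaneProfileSpec,
    Movie,
)
from .presets import make_genotype_preset
from .simulate import render_movie, render_projection, simulate_events, simulate_lane
from .densitometry import normalize_to_reference, quantify_profile
from .track import detect_movie, link_detections, measure_track_intensity

__all__ = [
    "recovery_imaging",
    "simulate_cells",
    "DynamicsRecovery",
    "recover_dynamics",
    "lifetime_colocalization",
    "static_eisosome_colocalization",
    "static_patch_colocalization",
    "eisosome_enrichment",
    "genotype_lane_spec",
    "densitometry_panel",
]


def recovery_imaging(n_frames: int = 61) -> ImagingModel:
    """Imaging model used for recovery experiments (2-min movies)."""
    return ImagingModel(n_frames=n_frames)


def simulate_cells(preset: GenotypePreset, imaging: ImagingModel,
                   n_cells: int, seed: int) -> list[tuple[EventSet, Movie]]:
    """Simulate and render ``n_cells`` independent cells of one genotype."""
    root = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(root.spawn(n_cells)):
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        events = simulate_events(preset, imaging=imaging, seed=s)
        movie = render_movie(events, imaging, seed=s + 1)
        out.append((events, movie))
    return out


@dataclass
class DynamicsRecovery:
    """Ensemble dynamics recovered by the full pipeline for one genotype."""

    genotype: str
    n_tracks: int
    mean_lifetime: float
    sd_lifetime: float
    mean_assembly: float
    sd_assembly: float
    mean_disassembly: float
    mean_peak_intensity: float
    mean_peak_molecules: float
    internalized_pct: float
    table: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "genotype": self.genotype,
            "n_tracks": self.n_tracks,
            "mean_lifetime_s": self.mean_lifetime,
            "sd_lifetime_s": self.sd_lifetime,
            "mean_assembly_s": self.mean_assembly,
            "sd_assembly_s": self.sd_assembly,
            "mean_disassembly_s": self.mean_disassembly,
            "mean_peak_intensity": self.mean_peak_intensity,
            "mean_peak_molecules": self.mean_peak_molecules,
            "internalized_pct": self.internalized_pct,
        }


def recover_dynamics(genotype: str, seed: int, n_tracks: int = 100,
                     imaging: ImagingModel | None = None,
                     max_cells: int = 40) -> DynamicsRecovery:
    """Recover patch dynamics for one genotype through the whole pipeline.

    Simulates cells until at least ``n_tracks`` complete reference-channel
    tracks are pooled, then reports ensemble means of lifetime, assembly and
    disassembly time, peak intensity (and its molecule count via the known
    imaging calibration) and the internalized percentage.
    """
    imaging = imaging or recovery_imaging()
    preset = make_genotype_preset(genotype)
    rows = []
    flags = []
    root = np.random.SeedSequence(seed)
    children = root.spawn(max_cells)
    for child in children:
        if len(rows) >= n_tracks:
            break
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        events = simulate_events(preset, imaging=imaging, seed=s)
        movie = render_movie(events, imaging, seed=s + 1)
        tracks = _reference_tracks(movie)
        for tr in tracks:
            if not is_complete(tr, movie.n_frames):
                continue
            tab = measure_track_intensity(tr, movie, channels=[REF_CHANNEL])
            series = tab[f"ch{REF_CHANNEL}"].to_numpy()
            summ = compute_dynamics(tr, series, imaging.frame_interval)
            summ.internalized = classify_internalization(
                tr, series, pixel_size=movie.pixel_size)
            flags.append(summ.internalized)
            rows.append({
                "track_id": len(rows),
                "lifetime": summ.lifetime,
                "assembly_time": summ.assembly_time,
                "disassembly_time": summ.disassembly_time,
                "peak_intensity": summ.peak_intensity,
                "internalized": summ.internalized,
            })
    if not rows:
        raise RuntimeError(f"no tracks recovered for {genotype}")
    df = pd.DataFrame(rows)
    mean_peak = float(df["peak_intensity"].mean())
    return DynamicsRecovery(
        genotype=genotype,
        n_tracks=len(df),
        mean_lifetime=float(df["lifetime"].mean()),
        sd_lifetime=float(df["lifetime"].std(ddof=1)),
        mean_assembly=float(df["assembly_time"].mean()),
        sd_assembly=float(df["assembly_time"].std(ddof=1)),
        mean_disassembly=float(df["disassembly_time"].mean()),
        mean_peak_intensity=mean_peak,
        mean_peak_molecules=float(
            intensity_to_molecules(mean_peak, imaging.calibration_factor)),
        internalized_pct=100.0 * float(np.mean(flags)),
        table=df,
    )


def _reference_tracks(movie: Movie):
    dets = detect_movie(movie, channel=REF_CHANNEL)
    return link_detections(dets)


def lifetime_colocalization(genotype: str, seed: int, n_cells: int = 3,
                            window_px: float = 10.0,
                            imaging: ImagingModel | None = None) -> dict:
    """Lifetime-rule colocalization between reference patches and the query.

    Pools all complete reference tracks from ``n_cells`` simulated cells.
    Query-channel detections are vetoed inside the static-ridge mask of the
    query channel (eisosome signal is curvilinear, not patch-like).
    """
    imaging = imaging or recovery_imaging()
    preset = make_genotype_preset(genotype)
    n_ref = n_hit = 0
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_cells):
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        events = simulate_events(preset, imaging=imaging, seed=s)
        movie = render_movie(events, imaging, seed=s + 1)
        tracks = [t for t in _reference_tracks(movie)
                  if is_complete(t, movie.n_frames)]
        if not tracks:
            continue
        qmask = None
        if preset.eisosome_amplitude > 0:
            qmask = static_ridge_mask(
                movie.data[:, QUERY_CHANNEL], sigma=imaging.psf_sigma,
                pixel_size=movie.pixel_size)
        qdets = detect_movie(movie, channel=QUERY_CHANNEL, exclude_mask=qmask)
        res = coloc_over_lifetime(tracks, qdets, window_px=window_px)
        n_ref += res.n_reference_objects
        n_hit += res.n_colocalized
    if n_ref == 0:
        raise RuntimeError("no reference tracks")
    return {"genotype": genotype, "n_reference": n_ref,
            "n_colocalized": n_hit, "fraction": n_hit / n_ref}


def static_eisosome_colocalization(genotype: str = "T140I", seed: int = 0,
                                   n_cells: int = 3,
                                   ref_eisosome_amplitude: float = 2.0) -> dict:
    """Static-rule colocalization of eisosome-localised query with a second
    marker decorating the same eisosomes (e.g. the light chain carried along
    by a mis-localised myosin).

    Eisosomes are detected as ridges on the query projection; the window test
    runs on the other channel, which is rendered with the marker on every
    eisosome at ``ref_eisosome_amplitude``.
    """
    preset = replace(make_genotype_preset(genotype),
                     eisosome_ref_amplitude=ref_eisosome_amplitude)
    imaging = ImagingModel(n_frames=1)
    n_ref = n_hit = 0
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_cells):
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        events = simulate_events(preset, imaging=imaging, seed=s)
        proj = render_projection(events, imaging, seed=s + 1)
        segments = detect_ridges(proj[QUERY_CHANNEL],
                                 sigma=imaging.psf_sigma,
                                 pixel_size=imaging.pixel_size)
        res = coloc_static(segments, proj[REF_CHANNEL])
        n_ref += res.n_reference_objects
        n_hit += res.n_colocalized
    return {"genotype": genotype, "class": "eisosome", "n_reference": n_ref,
            "n_colocalized": n_hit,
            "fraction": (n_hit / n_ref) if n_ref else None}


def static_patch_colocalization(genotype: str = "dIQ2", seed: int = 0,
                                n_cells: int = 6, frame_time: float = 20.0
                                ) -> dict:
    """Static-rule patch-class colocalization on projection snapshots.

    Reference objects are patch detections on the reference-channel snapshot;
    the query image is the other channel (for the IQ2-deletion preset the
    query marker sits on stray cytoplasmic puncta, so only fortuitous
    juxtaposition produces hits).
    """
    preset = make_genotype_preset(genotype)
    imaging = ImagingModel(n_frames=31)
    from .detect import detect_spots

    n_ref = n_hit = 0
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_cells):
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        events = simulate_events(preset, imaging=imaging, seed=s)
        proj = render_projection(events, imaging, t=frame_time, seed=s + 1)
        refs = detect_spots(proj[REF_CHANNEL], psf_sigma=imaging.psf_sigma,
                            pixel_size=imaging.pixel_size)
        if not refs:
            continue
        res = coloc_static(refs, proj[QUERY_CHANNEL])
        n_ref += res.n_reference_objects
        n_hit += res.n_colocalized
    return {"genotype": genotype, "class": "patch", "n_reference": n_ref,
            "n_colocalized": n_hit,
            "fraction": (n_hit / n_ref) if n_ref else None}


def eisosome_enrichment(genotype_a: str = "T140I", genotype_b: str = "A181P",
                        seed: int = 0, n_cells: int = 5) -> dict:
    """Per-cell eisosome query intensity and counts for two genotypes.

    Both genotypes are rendered on *identical* eisosome layouts (same
    placement seed) so the comparison is paired, mirroring the study design
    where eisosome numbers were unchanged across genotypes and only the
    myosin load on them differed.
    """
    imaging = ImagingModel(n_frames=1)
    totals = {genotype_a: 0.0, genotype_b: 0.0}
    counts = {genotype_a: 0, genotype_b: 0}
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_cells):
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        for g in (genotype_a, genotype_b):
            # measure the eisosome-bound pool only: stray cytoplasmic puncta
            # are a different compartment and would contaminate the ratio
            preset = replace(make_genotype_preset(g),
                             cytoplasmic_puncta_rate=0.0)
            events = simulate_events(preset, imaging=imaging, seed=s)
            proj = render_projection(events, imaging,
                                     seed=s + (1 if g == genotype_a else 2))
            segments = detect_ridges(proj[QUERY_CHANNEL],
                                     sigma=imaging.psf_sigma,
                                     pixel_size=imaging.pixel_size)
            census = eisosome_census(segments, events.cell,
                                     proj[QUERY_CHANNEL])
            totals[g] += census.total_query_intensity
            counts[g] += census.n_segments
    return {
        "genotypes": (genotype_a, genotype_b),
        "total_intensity": totals,
        "segment_counts": counts,
        "intensity_ratio": totals[genotype_a] / totals[genotype_b],
        "count_difference_per_cell":
            abs(counts[genotype_a] - counts[genotype_b]) / n_cells,
    }


# ---------------------------------------------------------------------
# densitometry panel
# ---------------------------------------------------------------------

#: per-genotype lane truth: (total relative to WT, band fractions 150/40/30)
LANE_TRUTH: dict[str, tuple[float, tuple[float, float, float]]] = {
    "WT": (1.0, (0.30, 0.60, 0.10)),
    "T140I": (1.0, (0.40, 0.50, 0.10)),
    "G483D": (1.0, (0.25, 0.65, 0.10)),
    "A181P": (0.6, (0.10, 0.15, 0.75)),
    "G308R": (0.4, (0.10, 0.15, 0.75)),
}


def genotype_lane_spec(genotype: str, noise_sd: float = 0.0,
                       baseline: tuple[float, ...] = (0.0,)) -> LaneProfileSpec:
    """Generative lane spec for a genotype's anti-GFP immunoblot lane."""
    if genotype not in LANE_TRUTH:
        raise KeyError(f"no lane truth for {genotype!r}; "
                       f"supported: {', '.join(LANE_TRUTH)}")
    total, fracs = LANE_TRUTH[genotype]
    return LaneProfileSpec(band_mws=(150.0, 40.0, 30.0),
                           band_fractions=fracs, total_amount=total,
                           noise_sd=noise_sd, baseline=baseline,
                           label=genotype)


def densitometry_panel(genotypes: tuple[str, ...] = ("WT", "A181P", "G308R"),
                       seed: int = 0, noise_sd: float = 0.0,
                       baseline: tuple[float, ...] = (0.0,)) -> pd.DataFrame:
    """Simulate one lane per genotype and run the densitometry pipeline.

    Returns a table with recovered totals normalised to WT and full-length
    fractions per lane.
    """
    quants = []
    for i, g in enumerate(genotypes):
        spec = genotype_lane_spec(g, noise_sd=noise_sd, baseline=baseline)
        lane = simulate_lane(spec, seed=seed + i)
        quants.append(quantify_profile(lane))
    quants = normalize_to_reference(quants, "WT")
    rows = []
    for q in quants:
        rows.append({
            "lane": q.lane_label,
            "n_bands": len(q.bands),
            "total": q.total_intensity,
            "normalized_total": q.normalized_total,
            "full_length_fraction": q.full_length_fraction,
        })
    return pd.DataFrame(rows).set_index("lane")
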