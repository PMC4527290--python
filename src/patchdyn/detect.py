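"""Spot and ridge detection on single frames and projections.

Spots (endocytic patches, puncta) are diffraction-limited maxima found on a
band-passed image with aperture-minus-annulus photometry and sub-pixel
centroiding.  Ridges (eisosomes) are curvilinear structures found by tubeness
filtering, thresholding and skeletonisation.  Because both classes live on
the cortex, each detector carries a shape gate: spot candidates are rejected
when their local second moments are elongated (or when they fall inside an
explicit static-ridge mask), and ridge components are rejected when they are
too short or too round.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import sato
from skimage.morphology import skeletonize

from .models import RidgeSegment, SpotDetection

__all__ = [
    "detect_spots",
    "detect_ridges",
    "measure_aperture",
    "robust_sigma",
    "static_ridge_mask",
]

APERTURE_RADIUS = 3.0      # px
ANNULUS_RADII = (4.0, 6.0)  # px
DEFAULT_THRESHOLD_K = 5.0
ELONGATION_MAX = 2.5       # sqrt eigenvalue ratio above which a spot is vetoed


def robust_sigma(image: np.ndarray) -> float:
    """Robust noise SD: 1.4826 * median absolute deviation."""
    med = np.median(image)
    return 1.4826 * float(np.median(np.abs(image - med)))


def _offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(math.ceil(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    m = dy**2 + dx**2 <= radius**2
    return dy[m], dx[m]


_AP_DY, _AP_DX = _offsets(APERTURE_RADIUS)


def _annulus_offsets() -> tuple[np.ndarray, np.ndarray]:
    r = int(math.ceil(ANNULUS_RADII[1]))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = dy**2 + dx**2
    m = (d2 >= ANNULUS_RADII[0] ** 2) & (d2 <= ANNULUS_RADII[1] ** 2)
    return dy[m], dx[m]


_AN_DY, _AN_DX = _annulus_offsets()


def measure_aperture(image: np.ndarray, x: float, y: float
                     ) -> tuple[float, float] | None:
    """Aperture-minus-annulus photometry at pixel position (x, y).

    Returns ``(integrated_intensity, local_background_per_px)`` or ``None``
    when the aperture or annulus crosses the image edge.
    """
    ny, nx = image.shape
    cy, cx = int(round(y)), int(round(x))
    r = int(math.ceil(ANNULUS_RADII[1]))
    if cy - r < 0 or cy + r >= ny or cx - r < 0 or cx + r >= nx:
        return None
    bg = float(np.median(image[cy + _AN_DY, cx + _AN_DX]))
    ap = image[cy + _AP_DY, cx + _AP_DX]
    return float(np.sum(ap) - bg * ap.size), bg


def _centroid(image: np.ndarray, x0: int, y0: int, bg: float
              ) -> tuple[float, float]:
    ys = y0 + _AP_DY
    xs = x0 + _AP_DX
    w = np.maximum(image[ys, xs] - bg, 0.0)
    tot = w.sum()
    if tot <= 0:
        return float(x0), float(y0)
    return float((w * xs).sum() / tot), float((w * ys).sum() / tot)


def _elongation(image: np.ndarray, x0: int, y0: int, bg: float) -> float:
    """sqrt ratio of intensity-weighted second-moment eigenvalues."""
    ys = y0 + _AP_DY
    xs = x0 + _AP_DX
    w = np.maximum(image[ys, xs] - bg, 0.0)
    tot = w.sum()
    if tot <= 0:
        return 1.0
    mx = (w * xs).sum() / tot
    my = (w * ys).sum() / tot
    cxx = (w * (xs - mx) ** 2).sum() / tot
    cyy = (w * (ys - my) ** 2).sum() / tot
    cxy = (w * (xs - mx) * (ys - my)).sum() / tot
    tr, det = cxx + cyy, cxx * cyy - cxy**2
    disc = max(tr * tr / 4.0 - det, 0.0)
    lam1 = tr / 2.0 + math.sqrt(disc)
    lam2 = max(tr / 2.0 - math.sqrt(disc), 1e-12)
    return math.sqrt(lam1 / lam2)


def detect_spots(
    image: np.ndarray,
    psf_sigma: float = 0.10,
    threshold_k: float = DEFAULT_THRESHOLD_K,
    pixel_size: float = 0.16,
    frame: int = 0,
    channel: int = 0,
    exclude_mask: np.ndarray | None = None,
    elongation_max: float = ELONGATION_MAX,
) -> list[SpotDetection]:
    """Detect diffraction-limited spots in one frame.

    Band-pass = difference of Gaussian blurs scaled to the PSF; candidates
    are local maxima above ``threshold_k`` robust noise SDs of the band-passed
    image.  Each candidate gets a sub-pixel centroid and aperture photometry
    (aperture radius 3 px, annulus 4-6 px).  Candidates inside
    ``exclude_mask`` (e.g. a static-ridge mask) or with elongated local
    second moments are vetoed — those are pieces of curvilinear structures,
    not patches.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2-D frame")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")

    sig1 = max(psf_sigma / pixel_size, 0.8)
    sig2 = 2.0 * sig1
    bp = ndimage.gaussian_filter(image, sig1) - ndimage.gaussian_filter(image, sig2)
    thr = threshold_k * robust_sigma(bp)
    thr = max(thr, 1e-6)
    peaks = peak_local_max(bp, min_distance=2, threshold_abs=thr,
                           exclude_border=False)

    out: list[SpotDetection] = []
    for py, px_ in peaks:
        if exclude_mask is not None and exclude_mask[py, px_]:
            continue
        phot = measure_aperture(image, px_, py)
        if phot is None:
            continue
        _, bg = phot
        if _elongation(image, px_, py, bg) > elongation_max:
            continue
        x, y = _centroid(image, px_, py, bg)
        phot2 = measure_aperture(image, x, y) or phot
        out.append(
            SpotDetection(frame=frame, channel=channel, x=x, y=y,
                          integrated_intensity=phot2[0],
                          local_background=phot2[1])
        )
    out.sort(key=lambda d: (d.y, d.x))
    return out


# ---------------------------------------------------------------------
# ridges
# ---------------------------------------------------------------------

def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(int), np.ones((3, 3), int),
                            mode="constant") - skel.astype(int)


def _prune_spurs(skel: np.ndarray, max_len: int = 3) -> np.ndarray:
    """Remove short side branches that skeletonisation grows on wide bands.

    An endpoint whose walk reaches a junction within ``max_len`` steps is a
    spur; its pixels are deleted (the junction survives).  Without pruning,
    splitting at branch points would fragment a bright, wide ridge.
    """
    skel = skel.copy()
    for _ in range(2):  # pruning can expose new spurs once
        nbr = _neighbor_count(skel)
        endpoints = np.argwhere(skel & (nbr == 1))
        changed = False
        for ey, ex in endpoints:
            path = [(ey, ex)]
            py, px_ = ey, ex
            prev = None
            for _step in range(max_len):
                ys = slice(max(py - 1, 0), py + 2)
                xs = slice(max(px_ - 1, 0), px_ + 2)
                cand = [
                    (yy, xx)
                    for yy in range(*ys.indices(skel.shape[0]))
                    for xx in range(*xs.indices(skel.shape[1]))
                    if skel[yy, xx] and (yy, xx) != (py, px_)
                    and (yy, xx) != prev
                ]
                if len(cand) != 1:
                    # hit a junction (or dead end): spur if junction
                    if len(cand) > 1:
                        for yy, xx in path:
                            skel[yy, xx] = False
                        changed = True
                    break
                prev = (py, px_)
                py, px_ = cand[0]
                path.append((py, px_))
        if not changed:
            break
    return skel


def _skeleton_paths(skel: np.ndarray) -> list[np.ndarray]:
    """Split a pruned skeleton at branch points; return ordered pixel paths."""
    skel = _prune_spurs(skel)
    nbr = _neighbor_count(skel)
    branch = skel & (nbr > 2)
    clean = skel & ~branch
    lbl, n = ndimage.label(clean, structure=np.ones((3, 3), int))
    paths = []
    for i in range(1, n + 1):
        ys, xs = np.nonzero(lbl == i)
        if len(ys) < 2:
            continue
        pts = np.stack([xs, ys], axis=1).astype(float)
        # order along the dominant principal axis (segments are near-straight)
        c = pts - pts.mean(axis=0)
        u, _, vt = np.linalg.svd(c, full_matrices=False)
        order = np.argsort(c @ vt[0])
        paths.append(pts[order])
    return paths


def detect_ridges(
    projection: np.ndarray,
    sigma: float = 0.10,
    min_length: float = 0.5,
    pixel_size: float = 0.16,
    threshold_k: float = 3.0,
    min_elongation: float = 1.8,
) -> list[RidgeSegment]:
    """Detect linear cortical structures on a top-surface projection.

    Tubeness (Hessian-based) enhancement, robust threshold, skeletonisation,
    branch-point splitting; components shorter than ``min_length`` (um) or
    rounder than ``min_elongation`` (skeleton length / PSF-convolved width)
    are discarded.  ``mean_intensity`` is the background-subtracted intensity
    summed along the skeleton divided by the skeleton length.
    """
    img = np.asarray(projection, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D projection")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")

    sig_px = max(sigma / pixel_size, 0.8)
    smoothed = ndimage.gaussian_filter(img, sig_px)
    # local background: median over a window much wider than a ridge, which
    # flattens the diffuse cytoplasmic pool and the camera offset
    local_bg = ndimage.median_filter(smoothed, size=21, mode="nearest")
    flat = smoothed - local_bg
    # noise floor from Poisson statistics of the background keeps the
    # threshold meaningful on noise-free synthetic input
    shot = math.sqrt(max(float(np.median(img)), 0.0)) / (2.0 * math.sqrt(math.pi) * sig_px)
    noise = max(robust_sigma(flat), shot, 1e-9)
    resp = sato(smoothed, sigmas=[sig_px], black_ridges=False)
    binary = (flat > threshold_k * noise) & (resp > 0)

    raw_bg = ndimage.median_filter(img, size=21, mode="nearest")
    bgsub = img - raw_bg
    labels, n_lab = ndimage.label(binary, structure=np.ones((3, 3), int))
    segments: list[RidgeSegment] = []
    for i in range(1, n_lab + 1):
        comp = labels == i
        if comp.sum() < 3:
            continue
        ys, xs = np.nonzero(comp)
        w = np.maximum(bgsub[ys, xs], 0.0)
        tot_w = w.sum()
        if tot_w <= 0:
            continue
        pts = np.stack([xs, ys], axis=1).astype(float)
        mean = (w[:, None] * pts).sum(axis=0) / tot_w
        c = pts - mean
        cov = (w[:, None, None] * (c[:, :, None] * c[:, None, :])).sum(axis=0) / tot_w
        evals, evecs = np.linalg.eigh(cov)
        var_minor, var_major = float(evals[0]), float(evals[1])
        var_minor = max(var_minor, 1e-3)
        # a uniform line of length L has along-axis variance L^2/12 on top of
        # the PSF cross-section variance, so the flux-weighted moments give
        # an amplitude-invariant length estimate
        length_px = math.sqrt(12.0 * max(var_major - var_minor, 0.0))
        length_um = length_px * pixel_size
        elong = math.sqrt(var_major / var_minor)
        if length_um < min_length or elong < min_elongation:
            continue
        comp_skel = skeletonize(comp)
        paths = _skeleton_paths(comp_skel)
        if paths:
            polyline = max(paths, key=len)
        else:  # tiny/degenerate skeleton: fall back to thresholded pixels
            order = np.argsort(c @ evecs[:, 1])
            polyline = pts[order]
        total = float(np.sum(bgsub[comp]))
        segments.append(
            RidgeSegment(polyline=polyline, length=length_um,
                         mean_intensity=total / max(length_um, 1e-9))
        )
    segments.sort(key=lambda s: (s.polyline[0, 1], s.polyline[0, 0]))
    return segments


def static_ridge_mask(movie_channel: np.ndarray, sigma: float = 0.10,
                      pixel_size: float = 0.16, dilate: int = 2) -> np.ndarray:
    """Mask of static curvilinear structures from a (T, Y, X) channel stack.

    Averaging over time boosts the SNR of immobile structures (eisosomes do
    not move over a movie) while transient patches blur away; the detected
    ridges, dilated by ``dilate`` px, can then veto spot candidates.
    """
    mean_img = np.asarray(movie_channel, dtype=float).mean(axis=0)
    segments = detect_ridges(mean_img, sigma=sigma, pixel_size=pixel_size)
    mask = np.zeros(mean_img.shape, dtype=bool)
    for seg in segments:
        xs = seg.polyline[:, 0].astype(int)
        ys = seg.polyline[:, 1].astype(int)
        mask[ys, xs] = True
    if dilate > 0:
        mask = ndimage.binary_dilation(mask, iterations=dilate)
    return mask
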