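"""1-D gel lane densitometry.

Baseline subtraction (rolling minimum followed by smoothing), band detection
by peak prominence with extent by descent to local minima, trapezoidal area
integration over the log10(kDa) axis, molecular-weight-gated full-length
quantification, and normalisation of lane totals to a reference lane.
"""

from __future__ import annotations

import copy

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .models import Band, BandQuantification, LaneProfile

__all__ = [
    "subtract_baseline",
    "detect_bands",
    "quantify_lane",
    "normalize_to_reference",
    "quantify_profile",
]

FULL_LENGTH_WINDOW = (135.0, 165.0)  # kDa


def subtract_baseline(profile: LaneProfile, window: int = 451,
                      smooth: int = 101) -> LaneProfile:
    """Remove a slowly varying baseline from a lane profile.

    Rolling minimum over ``window`` samples, smoothed with a uniform filter
    of ``smooth`` samples and subtracted; because the rolling minimum of a
    noisy profile is biased low by the extreme-value statistics of the noise,
    the result is re-centred on its off-band level before clipping at zero.
    ``window`` must be wide relative to the widest band complex and narrower
    than the profile.
    """
    n = len(profile.intensity)
    if window >= n:
        raise ValueError("baseline window larger than profile")
    base = ndimage.minimum_filter1d(profile.intensity, size=window,
                                    mode="nearest")
    base = ndimage.uniform_filter1d(base, size=smooth, mode="nearest")
    out = profile.intensity - base
    # re-centre on a low quantile: band samples contaminate upwards, so the
    # 25th percentile tracks the off-band level while bands cover < ~70%
    out = np.clip(out - np.percentile(out, 25), 0.0, None)
    return LaneProfile(axis=profile.axis.copy(), intensity=out,
                       lane_label=profile.lane_label)


def detect_bands(profile: LaneProfile, min_prominence: float | None = None,
                 smooth_sigma: float = 8.0) -> list[Band]:
    """Find bands in a baseline-subtracted profile.

    The profile is lightly smoothed (``smooth_sigma`` samples, well below a
    band width, mass-preserving) before peak finding and integration.  Local
    maxima above ``min_prominence`` (default: 2% of the profile maximum or
    5 robust noise SDs, whichever is larger); each band's extent descends to
    the neighbouring local minima (or the valley shared with the adjacent
    band), and its area is the trapezoidal integral over that extent.
    Returns bands in axis order; an empty list when nothing is found.
    """
    y = ndimage.gaussian_filter1d(profile.intensity, smooth_sigma) \
        if smooth_sigma > 0 else profile.intensity.copy()
    med = float(np.median(y))
    noise = 1.4826 * float(np.median(np.abs(y - med)))
    if min_prominence is None:
        min_prominence = max(0.02 * float(y.max()), 5.0 * noise) \
            if y.max() > 0 else 1.0
    peaks, _props = find_peaks(y, prominence=min_prominence)
    if len(peaks) == 0:
        return []

    # band boundaries: minima between adjacent peaks, profile ends outside
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(int(a + np.argmin(y[a:b + 1])))
    bounds.append(len(y) - 1)

    bands = []
    for i, pk in enumerate(peaks):
        # trim the extent to where the profile has genuinely descended, so
        # long empty stretches (whose clipped noise floor is positive) are
        # not integrated into the band
        cut = max(0.02 * float(y[pk]), 2.0 * noise)
        left = pk
        while left > bounds[i] and y[left - 1] >= cut:
            left -= 1
        right = pk
        while right < bounds[i + 1] and y[right + 1] >= cut:
            right += 1
        area = float(np.trapezoid(y[left:right + 1],
                                  profile.axis[left:right + 1]))
        bands.append(Band(center_mw=float(10.0 ** profile.axis[pk]),
                          area=area, left=left, right=right))
    return bands


def quantify_lane(bands: list[Band], lane_label: str = "",
                  full_length_window: tuple[float, float] = FULL_LENGTH_WINDOW
                  ) -> BandQuantification:
    """Total and full-length band intensity for one lane.

    ``full_length_window`` gates which detected bands count as the intact
    protein (default 150 +/- 15 kDa); ``full_length_fraction`` is None when
    the lane is empty.
    """
    total = sum(b.area for b in bands)
    lo, hi = full_length_window
    full = sum(b.area for b in bands if lo <= b.center_mw <= hi)
    return BandQuantification(lane_label=lane_label, bands=list(bands),
                              total_intensity=total,
                              full_length_intensity=full)


def normalize_to_reference(quantifications: list[BandQuantification],
                           reference_label: str) -> list[BandQuantification]:
    """Normalize lane totals and full-length intensities to a reference lane.

    Returns a new list; the reference lane gets 1.0 for both normalized
    values.  Raises when the reference is missing or empty.
    """
    ref = next((q for q in quantifications
                if q.lane_label == reference_label), None)
    if ref is None:
        raise ValueError(f"reference lane {reference_label!r} not present")
    if ref.total_intensity <= 0:
        raise ValueError("reference lane has zero total intensity")
    out = []
    for q in quantifications:
        q2 = copy.copy(q)
        q2.normalized_total = q.total_intensity / ref.total_intensity
        q2.normalized_full_length = (
            q.full_length_intensity / ref.full_length_intensity
            if ref.full_length_intensity > 0 else None
        )
        out.append(q2)
    return out


def quantify_profile(profile: LaneProfile,
                     full_length_window: tuple[float, float] = FULL_LENGTH_WINDOW,
                     baseline_window: int = 451) -> BandQuantification:
    """Convenience: baseline-subtract, detect bands and quantify one lane."""
    flat = subtract_baseline(profile, window=baseline_window)
    bands = detect_bands(flat)
    return quantify_lane(bands, lane_label=profile.lane_label,
                         full_length_window=full_length_window)
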