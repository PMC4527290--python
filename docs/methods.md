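# Methods

## What the simulator emulates

The generator reproduces the statistical structure of two-channel
spinning-disc confocal time-lapse imaging of fission-yeast cells in which a
red reference marker (fimbrin on endocytic actin patches) is imaged together
with a green query marker (a tagged myosin-1 variant or its light chain).
A rod-shaped cell (half-length 5.5 µm, radius 1.8 µm, rectangle capped by
semicircles) carries three object classes:

* **Endocytic patches** on the cortex outline.  Each patch has a triangular
  intensity time course: zero at birth, linear rise to a peak over the
  assembly time, linear fall over the disassembly time.  Lifetimes, assembly
  times and peak amplitudes are drawn from per-genotype normal
  distributions; birth times are uniform on the frame grid over
  `[-max_lifetime, duration]`.  A Bernoulli flag decides whether the patch
  internalizes, i.e. moves from the cortex along the inward normal after its
  peak.  In query-positive genotypes the query channel shows the same patch
  with its whole course shifted *earlier* by 1.5 s (the marker appears and
  peaks before the reference) at 0.8× amplitude.
* **Eisosomes**: static line segments along the straight cortex sections,
  rendered as Gaussian line integrals.  Their photon line density scales
  with a per-genotype amplitude (see below).
* **Cytoplasmic puncta**: static point sources inside the cell, used for
  genotypes whose light chain re-localises to stray aggregates.

Rendering per frame and channel: ideal photons = background (100/px) +
uniform cytoplasmic pool inside the cell (10/px in mid-plane frames, absent
from top-surface projections, which graze the membrane above the cytosol) +
static layers + Σ patch amplitudes × a normalised Gaussian PSF
(σ = 0.10 µm) at the patch's current position.  Recorded counts =
`gain · Poisson(ideal) + N(0, read_noise)`, clipped to the camera bit depth.
Optional 3-slice z-stacks attenuate the structure plane with a Gaussian
axial profile (σ_z = 0.3 µm) at 0.4-µm steps.

### Generative parameters (presets.yaml)

Times in seconds; [mean, sd].

| genotype | lifetime | assembly | peak (molecules) | internalize | query on patches | eisosome amp. | puncta/cell |
|----------|----------|----------|------------------|-------------|------------------|---------------|-------------|
| WT, G483D | 16.0, 2.3 | 7.0, 1.4 | 900, 180 | 0.98 | 1.0 | 0 | 0 |
| T140I | 32.8, 5.8 | 13.8, 1.8 | 900, 180 | 0.5 | 0 | 3.0 | 0 |
| A181P | 28.0, 8.4 | 12.6, 4.3 | 900, 180 | 0.5 | 0 | 1.0 | 2 |
| G308R | 36.0, 6.3 | 15.4, 4.3 | 900, 180 | 0.5 | 0 | 1.0 | 2 |
| Δmyo1 | 33.0, 6.6 | 14.0, 2.8 | 900, 180 | 0.5 | 0 | 0 | 0 |
| ΔIQ2, 2xIQ1IQ2 | 16.0, 2.3 | 7.0, 1.4 | 900, 180 | 0.98 | 0 | 0 / 1.0 | 1 / 0 |

Mutant lifetime/assembly distributions and the WT 7 s / 9 s / 900-molecule
values are the published per-genotype measurements; SDs that were never
printed (WT, deletion strain, disassembly spread) use sd = 0.2 × mean, a
plausible spread that leaves the means untouched.  Disassembly is drawn as
lifetime − assembly.  Where the published account is only qualitative, the
presets quantify it once: "nearly all" internalize → 0.98; "approximately
threefold more" on eisosomes → amplitude 3.0 vs 1.0.

Times are quantised to the frame grid and the triangle is padded by one
frame interval on each side (zero exactly one frame before the first and
after the last visible frame).  This makes the generative convention
identical to the measurement convention — lifetime = (last − first
visible frame) × Δt — so parameter recovery is well-posed; the quantisation
bias on a mean is ≪ 0.1 s because the SDs span several frame intervals.

Other one-time generator choices:

* **Internalization movement**: 0.10 µm/s along the inward normal from the
  peak time, capped at 1.2 µm of travel — within the range reported for
  endocytic vesicle movement, and large enough that a patch with the
  shortest quantised disassembly still crosses the 0.32-µm classification
  threshold before it disappears.
* **Site exclusion**: temporally overlapping patches (±3 frames) keep
  ≥1 µm cortical separation — endocytic sites have a refractory footprint —
  which also prevents the linker from fusing two diffraction-limited spots.
* **Eisosomes**: 6 segments per cell of 0.9–1.4 µm placed in per-side slots
  with ≥0.6 µm clearance (closer segments are bridged by the PSF into one
  ridge), photon line density 800 photons/µm at unit amplitude.  Eisosome
  and puncta placement use RNG streams keyed only on the seed, so two
  genotypes simulated with the same seed share identical static scenery —
  between-genotype enrichment comparisons are paired, mirroring the
  observation that eisosome numbers do not change across genotypes.
* **Calibration**: 10 photons per fluorophore at gain 1.0, so recorded
  units/molecule = 10; `intensity_to_molecules` recovers the 900-molecule
  peak from this known constant, standing in for the literature calibration
  a real experiment would cite.

### What the generator does *not* model

No photobleaching, stage drift, 3-D PSF, actin cables or contractile rings;
cells are isolated (one per field); eisosomes are straight and never cross;
channel registration is perfect; patch motion before the peak is zero.
Passing the recovery tests therefore demonstrates that the measurement code
is correct under the stated imaging model — not that it is robust to every
artefact of real microscopy (drift, bleaching, touching cells would all
require additional handling).

## Measurement pipeline

**Spot detection.** Difference-of-Gaussians band-pass (σ₁ = PSF in pixels,
floored at 0.8 px; σ₂ = 2σ₁); candidates are local maxima above
`threshold_k = 5` robust SDs (1.4826·MAD) of the band-passed frame.
Photometry: aperture radius 3 px minus the median of a 4–6-px annulus;
sub-pixel position by intensity-weighted centroid.  Two vetoes separate
patch-like from eisosome-like signal: candidates whose local second-moment
elongation exceeds 2.5 are rejected, and an optional exclusion mask —
ridges detected on the movie's temporal mean, where static structures gain
√T in SNR, dilated by 2 px — removes detections on static filaments.

**Linking.** Greedy gated nearest neighbour per frame transition
(gate 4 px/frame, scaled by the gap length; gaps ≤ 1 frame; minimum 3
detections).  Ties break by distance, then track id, then detection index,
so linking is deterministic and independent of detection order.  Patch
densities are low; greedy assignment matches optimal assignment in this
regime and the no-split/no-merge limitation is accepted.

**Dynamics.** Peak frame = first maximum of the re-measured
aperture-minus-annulus series (earliest on ties, for determinism).
Ensembles pool only tracks that neither start in the first frame nor end in
the last (their birth or death would be censored).  Recovery experiments
use 61-frame (2-min) movies instead of the 31-frame acquisition default:
with a 1-min movie, a 33-s mutant patch rarely fits entirely inside, and
conditioning on fitting would preferentially sample short-lived patches
(length-biased censoring of order σ²/(T−µ) ≈ 1.2 s); at 2 min the residual
bias is < 0.4 s.  Internalization = distance from the track origin
> 0.32 µm (2 px, ~10 localisation SDs) on at least one post-peak frame.
Peak alignment shifts each track so its reference-channel peak is t = 0 and
averages per aligned time point without interpolation, reporting n.

**Ridges.** Gaussian smoothing, local-background removal by a 21-px median
(flattens the cytoplasmic pool and camera offset), tubeness (Sato) gating,
thresholding at 3 robust SDs with a Poisson shot-noise floor (keeps the
threshold meaningful on noise-free input), then per-component flux-weighted
moment analysis: length = √(12·(var∥ − var⊥)) — amplitude-invariant, since
a uniform line of length L has along-axis variance L²/12 on top of the PSF
cross-section — and elongation = √(var∥/var⊥) ≥ 1.8.  Skeletons (spur-pruned,
split at branch points) provide the reported polyline.  The census sums
background-subtracted intensity over a rectangle around each segment's
fitted axis (fitted length + 3 px margin, ±3 px across); because the fitted
length does not grow with brightness, between-genotype intensity ratios are
not inflated by threshold-dependent footprints.  Residual bias on a 3×
amplitude ratio is ≈ +4%, within the ±10% acceptance band.

**Colocalization.** Lifetime rule: a reference track is colocalized if any
query detection falls within a circle of *diameter* `window_px` (default
10 px) centred on the patch in any frame of its lifetime — the window
shape/size interpretation is this package's convention, exposed as a
parameter.  Static rule: the query projection is PSF-smoothed and
21-px-median flattened; an object is colocalized when that matched-filtered
image reaches `presence_k = 5` robust noise SDs (lower-side MAD, since real
structures contaminate only upwards) anywhere inside its window.  A
window-mean statistic was rejected during design: a dim extended eisosome
raises the 79-pixel window mean by well under one per-pixel noise SD, and
null calibration from random windows collapses when most windows touch real
signal.  No chance-overlap correction is applied (fractions are reported
raw); the chance level is characterised by a property test with randomly
placed static query objects.

**Densitometry.** Axis is log₁₀(kDa) (SDS-PAGE migration; ladder
calibration assumed already applied).  Baseline: rolling minimum (451 of
1200 samples — wider than the 30/40-kDa band complex) smoothed over 101
samples; the subtraction is re-centred on the 25th percentile of the
residual because the rolling minimum of a noisy profile is biased low by
extreme-value statistics, and clipped at zero.  Bands: light Gaussian
smoothing (8 samples, mass-preserving), peaks by prominence (≥ 2% of the
profile maximum or 5 robust noise SDs), extents by descent to the shared
valley, trimmed where the profile falls below 2% of the peak (so empty
stretches with a clipped-noise floor are not integrated), trapezoidal
areas.  Full-length = bands within 150 ± 15 kDa.  Lane specs for the
genotypes put 30% (WT) or 10% (unstable mutants) of the total in the
150-kDa band, with the degradation mass at 40 kDa for WT-like lanes and
shifted to 30 kDa for the unstable mutants, at totals 1.0 / 0.6 / 0.4;
the 40/30 split within the degradation products is this package's choice —
only the full-length fractions and lane totals are published quantities.
Equal-loading control is represented by generating lanes at the stated
totals rather than by quantifying a second gel.

## Problem sizes

Recovery experiments pool ≥100 complete tracks per genotype from 61-frame
two-channel movies (~7 cells); the wild-type run for molecule calibration
uses 200 tracks to tighten the sampling error of the 900-molecule mean.
Colocalization pools 3 cells (~50–120 reference tracks); enrichment uses 5
paired cells per genotype; lanes have 1200 samples over 15–250 kDa.  The
full test suite runs in well under a minute on one CPU; the acceptance
script in a few seconds.

## Known limitations

* Greedy linking has no split/merge handling; very high patch densities
  would need global assignment.
* Ridge lengths are moment-based estimates; strongly curved or crossing
  filaments would be mis-measured (the generator never produces them).
* The static presence test assumes an approximately uniform noise level
  across the projection.
* Aperture photometry near the cell edge mixes intra- and extracellular
  background in the annulus; with the default dim cytoplasmic pool this
  biases peak intensities by ~+1–2%.
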