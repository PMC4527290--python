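# patchdyn

Quantification of clathrin-mediated endocytosis readouts in fission-yeast
(*Schizosaccharomyces pombe*) fluorescence imaging, built for studies that
compare wild-type myosin-1 (Myo1) against motor-domain point mutants — for
example the FSGS-equivalent substitutions T140I and A181P.  It is aimed at
cell biologists who need the standard measurements of that literature as
reproducible, scriptable code rather than interactive ImageJ sessions:

* **Patch detection and tracking** — band-pass spot detection with sub-pixel
  centroiding and aperture-minus-annulus photometry, linked frame-to-frame by
  greedy gated nearest-neighbour assignment with gap closing.
* **Patch dynamics** — per-track lifetime, assembly and disassembly times,
  peak intensity with molecule-count calibration, distance-from-origin
  traces, internalization classification, and peak-aligned two-channel
  ensemble averages (reference-marker peak = time zero).
* **Object-based colocalization** — the lifetime rule (query signal within a
  10-pixel window centred on a reference patch at any point of its lifetime)
  and the static rule on top-surface projections, scored per patch, punctum
  or eisosome.
* **Eisosome analysis** — ridge detection of the static linear membrane
  domains, counts per projected cell area, and per-cell query-intensity
  enrichment.
* **Gel densitometry** — 1-D lane profiles over a log₁₀(kDa) axis: baseline
  subtraction, band detection and integration, full-length (~150 kDa)
  fraction, and normalisation to a wild-type reference lane.
* **A synthetic-data generator** whose genotype presets *are* the published
  per-genotype measurements (WT: 7 s assembly + 9 s disassembly to ~900
  molecules, ~100% internalization; T140I: 32.8 ± 5.8 s lifetime, 13.8 ±
  1.8 s assembly, 50% internalization, 3× eisosome enrichment; …), so every
  stage of the pipeline is validated by recovering known truth from rendered
  movies and lanes — no downloads required.

## The measurements in brief

For a track with background-subtracted intensity series *I(t)* sampled at
frame interval Δt, the peak frame *t*ₚ is the first maximum of *I*;
assembly = *t*ₚ − *t*_first, disassembly = *t*_last − *t*ₚ, and
lifetime = assembly + disassembly exactly.  Molecule counts are
*I*(*t*ₚ)/κ with κ the units-per-fluorophore calibration.  A patch counts as
internalized when its distance from the origin exceeds 0.32 µm (2 px) after
the peak.  The lifetime colocalization fraction is
*n*(patches with a query detection within a 10-px-diameter window in ≥1
frame) / *n*(patches).  Lane quantities are trapezoidal band areas over
log₁₀(kDa); the full-length fraction is the 150 ± 15 kDa band area over the
lane total.

## Worked example

```bash
python examples/02_patch_dynamics.py
```

prints (seed 7, 100+ tracks per genotype through the full
simulate → detect → link → measure chain):

```
WT     n=129 lifetime  16.3 +/-  2.9 s  assembly   7.3 s  peak    894 molecules  internalized  96.1 %
T140I  n=100 lifetime  33.2 +/-  8.0 s  assembly  14.5 s  peak    906 molecules  internalized  53.0 %
A181P  n=104 lifetime  27.6 +/-  8.7 s  assembly  12.9 s  peak    894 molecules  internalized  42.3 %
```

Each recovered mean sits within one frame interval (2 s) of its generative
value; peak counts recover the 900-molecule calibration; internalization
collapses from ~100% in wild type to ~50% in the motor mutants — the
functional signature of a dead motor.  The other examples cover tracking
(`01`), peak-aligned ensembles showing the ~1.5-s query-channel lead (`03`),
colocalization and eisosome enrichment (`04`), and blot densitometry (`05`).

A thin CLI wraps the same calls:

```bash
patchdyn simulate movie --genotype WT --seed 7 --out wt.ome.tif --truth wt_truth.csv
patchdyn track wt.ome.tif --out tracks.csv
patchdyn report --genotype T140I --seed 4 --out-dir report/
patchdyn simulate lanes --out lanes.csv && patchdyn blot lanes.csv --reference WT
```

## Layout

```
src/patchdyn/      models, presets (YAML), simulate, detect, track,
                   dynamics, coloc, densitometry, io, experiments,
                   pipeline, cli
examples/          one narrative script per capability
tests/             pytest suite incl. full-pipeline recovery tests
docs/methods.md    model, parameters and design notes
```
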