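"""Recover per-genotype patch dynamics (lifetime, assembly time, peak
molecules, internalization) through the full pipeline.

The genotype presets carry the published means: WT assembles in ~7 s to
~900 molecules and nearly always internalizes; the motor-domain mutants
take twice as long and internalize only half the time.  The pipeline should
hand those numbers back from rendered movies.
"""

from patchdyn.experiments import recover_dynamics

for genotype in ("WT", "T140I", "A181P"):
    rec = recover_dynamics(genotype, seed=7, n_tracks=100)
    print(f"{genotype:6s} n={rec.n_tracks:3d} "
          f"lifetime {rec.mean_lifetime:5.1f} +/- {rec.sd_lifetime:4.1f} s  "
          f"assembly {rec.mean_assembly:5.1f} s  "
          f"peak {rec.mean_peak_molecules:6.0f} molecules  "
          f"internalized {rec.internalized_pct:5.1f} %")
# Each row should sit within ~1 frame interval (2 s) of the preset means:
# WT 16/7 s, T140I 32.8/13.8 s, A181P 28.0/12.6 s — and internalization
# should drop from ~98% (WT) to ~50% (mutants).
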