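"""Quantify synthetic anti-GFP immunoblot lanes: totals normalised to the
wild type and full-length band fractions.

Even wild-type tagged myosin degrades during lysis (only ~30% runs as the
full-length ~150-kDa band); the unstable mutants lose most of their signal
(totals 0.6 and 0.4 of WT, only ~10% full-length) and shift their
degradation product from ~40 kDa to ~30 kDa.
"""

from patchdyn.experiments import densitometry_panel

panel = densitometry_panel(("WT", "A181P", "G308R"), seed=0)
print(panel.round(3).to_string())
print()
print("normalized_total should read ~1.00 / 0.60 / 0.40 and")
print("full_length_fraction ~0.30 for WT vs ~0.10 for the unstable mutants.")
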