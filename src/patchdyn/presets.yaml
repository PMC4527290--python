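# Genotype presets for the synthetic-data generator.
#
# lifetime / assembly / peak_molecules are [mean, sd] of the generative normal
# distributions (times in seconds).  Values for WT, T140I, A181P and G308R are
# the published patch-dynamics measurements for these strains; SDs that were
# not printed (WT and deletion strains, disassembly spread) use sd = 0.2*mean.
# patch_rate is patches per um of cortex per second; long-lived genotypes use
# a lower rate so that the number of simultaneously visible patches stays
# comparable to WT.
version: 1
globals:
  query_lead_s: 1.5               # query marker precedes reference (birth & peak)
  query_amplitude_scale: 0.8      # query peak relative to reference peak
  internalization_speed_um_s: 0.10
  internalization_max_depth_um: 1.2
  eisosome_photons_per_um: 800.0  # line density at unit eisosome amplitude
  eisosome_count: 6
  eisosome_length_um: [0.9, 1.4]
  puncta_photons: 2000.0
  cytoplasm_photons: 10.0         # uniform interior level, both channels
presets:
  WT:
    patch_rate: 0.016
    lifetime: [16.0, 2.3]
    assembly: [7.0, 1.4]
    peak_molecules: [900.0, 180.0]
    internalization_prob: 0.98
    query_on_patches_prob: 1.0
    eisosome_amplitude: 0.0
    puncta_rate: 0.0
  G483D:
    patch_rate: 0.016
    lifetime: [16.0, 2.3]
    assembly: [7.0, 1.4]
    peak_molecules: [900.0, 180.0]
    internalization_prob: 0.98
    query_on_patches_prob: 1.0
    eisosome_amplitude: 0.0
    puncta_rate: 0.0
  T140I:
    patch_rate: 0.008
    lifetime: [32.8, 5.8]
    assembly: [13.8, 1.8]
    peak_molecules: [900.0, 180.0]
    internalization_prob: 0.5
    query_on_patches_prob: 0.0
    eisosome_amplitude: 3.0
    puncta_rate: 0.0
  A181P:
    patch_rate: 0.008
    lifetime: [28.0, 8.4]
    assembly: [12.6, 4.3]
    peak_molecules: [900.0, 180.0]
    internalization_prob: 0.5
    query_on_patches_prob: 0.0
    eisosome_amplitude: 1.0
    puncta_rate: 2.0
  G308R:
    patch_rate: 0.008
    lifetime: [36.0, 6.3]
    assembly: [15.4, 4.3]
    peak_molecules: [900.0, 180.0]
    internalization_prob: 0.5
    query_on_patches_prob: 0.0
    eisosome_amplitude: 1.0
    puncta_rate: 2.0
  dmyo1:
    patch_rate: 0.008
    lifetime: [33.0, 6.6]
    assembly: [14.0, 2.8]
    peak_molecules: [900.0, 180.0]
    internalization_prob: 0.5
    query_on_patches_prob: 0.0
    eisosome_amplitude: 0.0
    puncta_rate: 0.0
  dIQ2:
    patch_rate: 0.016
    lifetime: [16.0, 2.3]
    assembly: [7.0, 1.4]
    peak_molecules: [900.0, 180.0]
    internalization_prob: 0.98
    query_on_patches_prob: 0.0
    eisosome_amplitude: 0.0
    puncta_rate: 1.0
  2xIQ1IQ2:
    patch_rate: 0.016
    lifetime: [16.0, 2.3]
    assembly: [7.0, 1.4]
    peak_molecules: [900.0, 180.0]
    internalization_prob: 0.98
    query_on_patches_prob: 0.0
    eisosome_amplitude: 1.0
    puncta_rate: 0.0
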