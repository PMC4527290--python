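"""Build the peak-aligned two-channel ensemble: reference peak at time zero,
query channel leading by ~1.5 s.

Individual patches are born at random times, so their traces only become
comparable after shifting each one so its reference-channel (fimbrin) peak
sits at t = 0.  In wild-type cells the myosin marker both appears and peaks
1-2 s before fimbrin.
"""

from patchdyn import (
    ImagingModel,
    align_to_peak,
    link_detections,
    make_genotype_preset,
    measure_track_intensity,
    render_movie,
    simulate_events,
)
from patchdyn.dynamics import is_complete
from patchdyn.track import detect_movie

imaging = ImagingModel(n_frames=61)
events = simulate_events(make_genotype_preset("WT"), imaging=imaging, seed=5)
movie = render_movie(events, imaging, seed=6)

tracks = [t for t in link_detections(detect_movie(movie, channel=0))
          if is_complete(t, movie.n_frames)]
tables = [measure_track_intensity(t, movie) for t in tracks]
ens = align_to_peak(tables, frame_interval=imaging.frame_interval,
                    reference_channel=0)

print(f"{len(tracks)} aligned tracks")
print(f"reference channel peaks at t = {ens.peak_time(0):+.0f} s (by construction)")
print(f"query channel peaks at     t = {ens.peak_time(1):+.0f} s")
print(ens.table[["ch0_mean", "ch1_mean", "ch0_n"]].round(0).to_string())
# The query peak lands on the frame before zero: the simulated 1.5-s lead,
# sampled on the 2-s frame grid.
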