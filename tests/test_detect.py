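"""Detector and linker contracts, checked against generative ground truth."""

import numpy as np
import pytest
from dataclasses import replace

from patchdyn import (
    CellGeometry,
    ImagingModel,
    SpotDetection,
    detect_ridges,
    detect_spots,
    link_detections,
    make_genotype_preset,
    measure_track_intensity,
    render_movie,
    render_projection,
    simulate_events,
)
from patchdyn.track import detect_movie
from conftest import manual_events, manual_patch


def det(frame, x, y):
    return SpotDetection(frame=frame, channel=0, x=x, y=y,
                         integrated_intensity=1.0, local_background=0.0)


class TestDetectSpots:
    def test_isolated_patches_found_at_subpixel_accuracy(self):
        im = ImagingModel(n_frames=1)
        truth = [(15.0, 12.0), (40.3, 30.7), (70.6, 15.2), (25.0, 38.0),
                 (85.0, 35.5)]
        ev = manual_events([manual_patch(x, y, birth=-8.0) for x, y in truth])
        frame = render_movie(ev, im, noise=False, cytoplasm_level=0.0).data[0, 0]
        dets = detect_spots(frame)
        assert len(dets) == len(truth)
        for tx, ty in truth:
            d = min(np.hypot(s.x - tx, s.y - ty) for s in dets)
            assert d < 0.5

    def test_blank_frame_has_no_detections(self):
        im = ImagingModel(n_frames=1)
        frame = render_movie(manual_events([]), im, seed=4).data[0, 0]
        assert detect_spots(frame) == []

    def test_close_pair_not_merged(self):
        im = ImagingModel(n_frames=1)
        ev = manual_events([manual_patch(40, 24, birth=-8.0),
                            manual_patch(50, 24, birth=-8.0)])
        frame = render_movie(ev, im, noise=False, cytoplasm_level=0.0).data[0, 0]
        assert len(detect_spots(frame)) == 2

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(np.full((32, 32), np.nan))
        with pytest.raises(ValueError):
            detect_spots(np.zeros((0, 5)))

    def test_noise_free_recall_and_precision_are_perfect(self):
        # all patches above 10% of the WT peak amplitude, no false positives
        im = ImagingModel(n_frames=1)
        ev = manual_events(
            [manual_patch(15 + 14 * i, 14 + (i % 3) * 10, birth=-8.0,
                          molecules=900.0 * frac)
             for i, frac in enumerate([1.0, 0.5, 0.25, 0.1, 0.8, 0.35])])
        frame = render_movie(ev, im, noise=False, cytoplasm_level=0.0).data[0, 0]
        assert len(detect_spots(frame)) == 6


class TestDetectRidges:
    @pytest.fixture()
    def long_cell(self):
        return CellGeometry(center=(8.0, 3.84), half_length=7.0, radius=1.8)

    @pytest.fixture()
    def eisosome_scene(self, long_cell):
        im = ImagingModel(n_frames=1, fov_shape=(48, 112))
        preset = replace(make_genotype_preset("A181P"),
                         cytoplasmic_puncta_rate=0.0)
        ev = simulate_events(preset, cell=long_cell, imaging=im, seed=4,
                             n_eisosomes=12)
        return ev, im

    def test_segment_count_recovered(self, eisosome_scene):
        ev, im = eisosome_scene
        proj = render_projection(ev, im, seed=5)
        segs = detect_ridges(proj[1], pixel_size=im.pixel_size)
        assert abs(len(segs) - len(ev.eisosomes)) <= 1

    def test_diffraction_limited_spots_are_not_ridges(self):
        im = ImagingModel(n_frames=31)
        ev = simulate_events(make_genotype_preset("WT"), imaging=im, seed=11)
        proj = render_projection(ev, im, t=20.0, seed=12)
        assert detect_ridges(proj[0], pixel_size=im.pixel_size) == []

    def test_intensity_doubling_is_linear(self, eisosome_scene, long_cell):
        ev, im = eisosome_scene
        p2 = replace(make_genotype_preset("A181P"), eisosome_amplitude=2.0,
                     cytoplasmic_puncta_rate=0.0)
        ev2 = simulate_events(p2, cell=long_cell, imaging=im, seed=4,
                              n_eisosomes=12)
        s1 = detect_ridges(render_projection(ev, im, noise=False)[1])
        s2 = detect_ridges(render_projection(ev2, im, noise=False)[1])
        assert len(s1) == len(s2)
        ratio = (np.mean([s.mean_intensity for s in s2])
                 / np.mean([s.mean_intensity for s in s1]))
        assert ratio == pytest.approx(2.0, rel=0.02)


class TestLinkDetections:
    def test_stationary_spot_gives_single_track(self):
        frames = [[] for _ in range(12)]
        for f in range(2, 11):
            frames[f] = [det(f, 30.0, 20.0)]
        tracks = link_detections(frames)
        assert len(tracks) == 1
        assert len(tracks[0]) == 9

    def test_two_separated_spots_keep_identity(self):
        # oracle: exhaustive assignment of 2 objects -> nearest must win
        frames = []
        for f in range(6):
            frames.append([det(f, 10.0 + 0.3 * f, 20.0),
                           det(f, 30.0, 20.0 + 0.2 * f)])
        tracks = link_detections(frames, max_disp=5.0)
        assert len(tracks) == 2
        for tr in tracks:
            xs = tr.positions[:, 0]
            assert xs.max() - xs.min() < 3.0  # no identity swap across 20 px

    def test_gap_closing_bridges_one_missing_frame(self):
        frames = [[det(f, 30.0, 20.0)] if f != 5 else []
                  for f in range(10)]
        tracks = link_detections(frames, max_gap=1)
        assert len(tracks) == 1
        assert tracks[0].frames.tolist() == [0, 1, 2, 3, 4, 6, 7, 8, 9]

    def test_gap_longer_than_max_gap_terminates_track(self):
        frames = [[det(f, 30.0, 20.0)] if f not in (4, 5) else []
                  for f in range(10)]
        tracks = link_detections(frames, max_gap=1, min_track_len=3)
        assert len(tracks) == 2

    def test_invalid_gate_rejected(self):
        with pytest.raises(ValueError):
            link_detections([], max_disp=0.0)

    def test_permutation_invariance(self, wt_scene):
        _, movie = wt_scene
        dets = detect_movie(movie, channel=0)
        rng = np.random.default_rng(0)
        shuffled = [list(rng.permutation(np.array(d, dtype=object)))
                    if d else [] for d in dets]
        a = link_detections(dets)
        b = link_detections(shuffled)
        key = lambda trs: sorted(
            tuple((d.frame, round(d.x, 6), round(d.y, 6)) for d in tr.detections)
            for tr in trs)
        assert key(a) == key(b)


class TestMeasureTrackIntensity:
    def test_triangular_time_course_recovered(self):
        im = ImagingModel(n_frames=11)
        ev = manual_events([manual_patch(40, 24, birth=2.0, assembly=8.0,
                                         disassembly=8.0)])
        movie = render_movie(ev, im, noise=False, cytoplasm_level=0.0)
        tracks = link_detections(detect_movie(movie, channel=0))
        assert len(tracks) == 1
        tab = measure_track_intensity(tracks[0], movie, channels=[0])
        series = tab["ch0"].to_numpy()
        expected = np.array([ev.patches[0].amplitude(2.0 * f, 0) * 10.0
                             for f in tab.index])
        assert int(np.argmax(series)) == int(np.argmax(expected))
        ok = expected > 0
        assert np.allclose(series[ok], expected[ok], rtol=0.03, atol=20.0)

    def test_blank_channel_measures_noise_around_zero(self, wt_scene,
                                                      imaging_long):
        events, _ = wt_scene
        from dataclasses import replace as drep
        from patchdyn import EventSet

        blankq = EventSet(cell=events.cell, patches=[
            drep_patch(e) for e in events.patches], eisosomes=[], puncta=[],
            seed=0)
        movie = render_movie(blankq, imaging_long, seed=77,
                             cytoplasm_level=0.0)
        tracks = link_detections(detect_movie(movie, channel=0))
        tab = measure_track_intensity(tracks[0], movie, channels=[1])
        vals = tab["ch1"].dropna().to_numpy()
        noise_sd = np.sqrt(imaging_long.background_level) * 6  # aperture scale
        assert abs(vals.mean()) < noise_sd

    def test_gain_doubling_doubles_intensity(self):
        ev = manual_events([manual_patch(40, 24, birth=2.0)])
        series = []
        for gain in (1.0, 2.0):
            im = ImagingModel(n_frames=10, camera_gain=gain)
            movie = render_movie(ev, im, noise=False, cytoplasm_level=0.0)
            tracks = link_detections(detect_movie(movie, channel=0))
            tab = measure_track_intensity(tracks[0], movie, channels=[0])
            series.append(tab["ch0"].to_numpy())
        ok = series[0] > 100
        assert np.allclose(series[1][ok] / series[0][ok], 2.0, rtol=0.01)


def drep_patch(e):
    from dataclasses import replace

    return replace(e, query_amplitude=0.0)
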