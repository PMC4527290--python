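"""Dynamics statistics: per-track times, alignment, internalization,
calibration and whole-cell intensity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from patchdyn import (
    CellGeometry,
    ImagingModel,
    PatchTrack,
    SpotDetection,
    align_to_peak,
    classify_internalization,
    compute_dynamics,
    distance_from_origin,
    intensity_to_molecules,
    link_detections,
    make_genotype_preset,
    measure_track_intensity,
    render_movie,
    simulate_events,
    whole_cell_intensity,
)
from patchdyn.dynamics import is_complete
from patchdyn.track import detect_movie
from conftest import manual_events, manual_patch


def make_track(positions, first_frame=0):
    dets = [
        SpotDetection(frame=first_frame + i, channel=0, x=x, y=y,
                      integrated_intensity=1.0, local_background=0.0)
        for i, (x, y) in enumerate(positions)
    ]
    return PatchTrack(track_id=0, detections=dets)


class TestComputeDynamics:
    def test_three_point_example(self):
        tr = make_track([(0, 0)] * 3)
        d = compute_dynamics(tr, [1.0, 3.0, 2.0], frame_interval=2.0)
        assert (d.assembly_time, d.disassembly_time, d.lifetime) == (2.0, 2.0, 4.0)
        assert d.peak_intensity == 3.0

    def test_monotonically_rising_track_has_zero_disassembly(self):
        tr = make_track([(0, 0)] * 5)
        d = compute_dynamics(tr, [1, 2, 3, 4, 5], frame_interval=2.0)
        assert d.disassembly_time == 0.0
        assert d.lifetime == d.assembly_time == 8.0

    def test_short_track_rejected(self):
        tr = make_track([(0, 0)] * 2)
        with pytest.raises(ValueError):
            compute_dynamics(tr, [1, 2], frame_interval=2.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1e4), min_size=3, max_size=40),
           st.floats(0.5, 5.0))
    def test_lifetime_identity_holds_for_any_series(self, series, dt):
        tr = make_track([(0, 0)] * len(series))
        d = compute_dynamics(tr, series, frame_interval=dt)
        assert d.lifetime == pytest.approx(d.assembly_time + d.disassembly_time)
        assert d.lifetime == pytest.approx((len(series) - 1) * dt)


class TestDistanceAndInternalization:
    def test_stationary_track_distances_are_zero(self):
        tr = make_track([(10.0, 10.0)] * 6)
        assert np.all(distance_from_origin(tr) == 0.0)
        assert not classify_internalization(tr, [1, 2, 3, 2, 1, 0.5])

    def test_distances_are_non_negative(self):
        rng = np.random.default_rng(1)
        tr = make_track(rng.uniform(0, 50, size=(10, 2)))
        assert np.all(distance_from_origin(tr) >= 0.0)

    def test_internalizing_patch_travels_speed_times_disassembly(self):
        im = ImagingModel(n_frames=13)
        ev = manual_events([manual_patch(40, 12, birth=2.0, assembly=8.0,
                                         disassembly=10.0, internalizes=True)])
        speed = ev.patches[0].internalization_speed
        movie = render_movie(ev, im, noise=False, cytoplasm_level=0.0)
        tracks = link_detections(detect_movie(movie, channel=0))
        assert len(tracks) == 1
        dist = distance_from_origin(tracks[0], im.pixel_size)
        expected = min(speed * 10.0, ev.patches[0].max_depth)
        assert abs(dist[-1] - expected) <= im.pixel_size  # within 1 px

    def test_threshold_monotonicity(self, wt_scene, imaging_long):
        _, movie = wt_scene
        tracks = [t for t in link_detections(detect_movie(movie, channel=0))
                  if is_complete(t, movie.n_frames)]
        fractions = []
        for thr in (0.16, 0.32, 0.64, 1.28):
            flags = []
            for tr in tracks:
                tab = measure_track_intensity(tr, movie, channels=[0])
                flags.append(classify_internalization(
                    tr, tab["ch0"].to_numpy(), displacement_threshold=thr))
            fractions.append(np.mean(flags))
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_invalid_threshold_rejected(self):
        tr = make_track([(0, 0)] * 4)
        with pytest.raises(ValueError):
            classify_internalization(tr, [1, 2, 1, 0.5],
                                     displacement_threshold=0.0)


class TestAlignToPeak:
    def _table(self, intensities, x=10.0, first=0):
        n = len(intensities)
        return pd.DataFrame(
            {"x": [x] * n, "y": [5.0] * n, "ch0": intensities},
            index=pd.Index(range(first, first + n), name="frame"))

    def test_single_track_ensemble_is_the_track(self):
        ens = align_to_peak([self._table([1, 5, 2])], frame_interval=2.0)
        assert ens.peak_time(0) == 0.0
        assert ens.table["ch0_mean"].tolist() == [1, 5, 2]
        assert ens.table.index.tolist() == [-2.0, 0.0, 2.0]

    def test_reference_mean_is_maximal_at_time_zero(self):
        rng = np.random.default_rng(0)
        tables = []
        course = np.array([0.5, 2.0, 6.0, 4.0, 1.0])
        for _ in range(30):
            shift = rng.integers(0, 10)
            tables.append(self._table(course + rng.normal(0, 0.1, 5),
                                      first=shift))
        ens = align_to_peak(tables, frame_interval=2.0)
        assert ens.peak_time(0) == 0.0

    def test_random_birth_times_average_to_single_course(self):
        # identical triangular courses, arbitrary shifts: aligned mean must
        # reproduce the course exactly (noise-free)
        course = [1.0, 3.0, 5.0, 3.5, 2.0, 0.5]
        rng = np.random.default_rng(3)
        tables = [self._table(course, first=int(rng.integers(0, 20)))
                  for _ in range(12)]
        ens = align_to_peak(tables, frame_interval=2.0)
        assert np.allclose(ens.table["ch0_mean"].to_numpy(), course)
        assert np.all(ens.table["ch0_n"] == 12)

    def test_empty_track_set_rejected(self):
        with pytest.raises(ValueError):
            align_to_peak([], frame_interval=2.0)

    def test_query_channel_peaks_before_reference(self, wt_scene,
                                                  imaging_long):
        _, movie = wt_scene
        tracks = [t for t in link_detections(detect_movie(movie, channel=0))
                  if is_complete(t, movie.n_frames)]
        tables = [measure_track_intensity(t, movie) for t in tracks]
        ens = align_to_peak(tables, frame_interval=imaging_long.frame_interval,
                            reference_channel=0)
        assert ens.peak_time(0) == 0.0
        assert ens.peak_time(1) < 0.0  # green marker leads the red reference


class TestCalibrationAndWholeCell:
    def test_zero_intensity_is_zero_molecules(self):
        assert intensity_to_molecules(0.0, 10.0) == 0.0

    def test_halving_calibration_doubles_counts(self):
        assert intensity_to_molecules(900.0, 5.0) == \
            2.0 * intensity_to_molecules(900.0, 10.0)

    def test_missing_calibration_rejected(self):
        with pytest.raises(ValueError):
            intensity_to_molecules(1.0, 0.0)

    def test_uniform_image_measures_zero(self):
        img = np.full((40, 60), 7.0)
        mask = np.zeros((40, 60), bool)
        mask[10:30, 10:50] = True
        assert whole_cell_intensity(img, mask) == pytest.approx(0.0)

    def test_interior_level_recovered(self):
        # synthetic cell with known interior level over background
        im = ImagingModel(n_frames=1)
        cell = CellGeometry()
        ev = manual_events([], cell=cell)
        level = 30.0
        movie = render_movie(ev, im, seed=5, cytoplasm_level=level)
        mask = cell.mask(im.fov_shape, im.pixel_size)
        got = whole_cell_intensity(movie.data[0, 0], mask)
        se = 3 * np.sqrt(im.background_level + level) / np.sqrt(mask.sum())
        assert got == pytest.approx(level, abs=max(5 * se, 1.0))

    def test_expression_level_equal_across_degradation_presets(self):
        # the two unstable mutants have very different blot totals (0.6 vs
        # 0.4 of WT) but identical in-cell fluorescence; whole-cell intensity
        # must agree within sampling error
        im = ImagingModel(n_frames=1)
        vals = {}
        for g, seed in (("A181P", 2), ("G308R", 2)):
            preset = make_genotype_preset(g)
            ev = simulate_events(preset, imaging=im, seed=seed)
            movie = render_movie(ev, im, seed=seed + 10 + hash(g) % 7)
            mask = ev.cell.mask(im.fov_shape, im.pixel_size)
            vals[g] = whole_cell_intensity(movie.data[0, 1], mask)
        se = np.sqrt(110.0) / np.sqrt(1000)
        assert vals["A181P"] == pytest.approx(vals["G308R"],
                                              abs=max(6 * se, 3.0))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            whole_cell_intensity(np.zeros((5, 5)), np.zeros((5, 5), bool))
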