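"""Generator contracts: determinism, ground-truth statistics, photometry."""

import numpy as np
import pytest
from dataclasses import replace

from patchdyn import (
    CellGeometry,
    ImagingModel,
    LaneProfileSpec,
    make_genotype_preset,
    render_movie,
    simulate_events,
    simulate_lane,
)
from conftest import manual_events, manual_patch


class TestPresets:
    def test_wild_type_internalizes_nearly_all_patches(self):
        assert make_genotype_preset("WT").internalization_prob >= 0.95
        assert make_genotype_preset("WT").query_channel_on_patches_prob == 1.0

    def test_deletion_strain_internalizes_half(self):
        assert make_genotype_preset("dmyo1").internalization_prob == 0.5

    def test_stable_mutant_threefold_eisosome_amplitude(self):
        t140i = make_genotype_preset("T140I")
        a181p = make_genotype_preset("A181P")
        assert t140i.eisosome_amplitude == pytest.approx(
            3.0 * a181p.eisosome_amplitude)

    @pytest.mark.parametrize("name,lifetime,assembly", [
        ("T140I", 32.8, 13.8), ("A181P", 28.0, 12.6), ("G308R", 36.0, 15.4),
    ])
    def test_mutant_dynamics_parameters(self, name, lifetime, assembly):
        p = make_genotype_preset(name)
        assert p.lifetime_mean_sd[0] == lifetime
        assert p.assembly_mean_sd[0] == assembly

    def test_unknown_genotype_lists_supported_labels(self):
        with pytest.raises(KeyError, match="WT"):
            make_genotype_preset("nosuch")


class TestSimulateEvents:
    def test_deterministic_under_fixed_seed(self, imaging):
        p = make_genotype_preset("WT")
        a = simulate_events(p, imaging=imaging, seed=5)
        b = simulate_events(p, imaging=imaging, seed=5)
        assert a.truth_table().equals(b.truth_table())

    def test_zero_internalization_probability(self, imaging_long):
        p = replace(make_genotype_preset("WT"), internalization_prob=0.0)
        ev = simulate_events(p, imaging=imaging_long, seed=9)
        assert len(ev.patches) > 10
        assert not any(e.internalizes for e in ev.patches)

    def test_truth_statistics_match_preset_within_three_se(self):
        # oracle: direct statistics on the exported ground-truth table
        p = make_genotype_preset("WT")
        imaging = ImagingModel(n_frames=301)
        tables = [
            simulate_events(p, imaging=imaging, seed=s).truth_table()
            for s in range(4)
        ]
        import pandas as pd

        t = pd.concat(tables)
        assert len(t) >= 200
        mean, sd = p.lifetime_mean_sd
        se = sd / np.sqrt(len(t))
        # quantisation to the 2-s frame grid keeps the mean within ~0.3 s
        assert abs(t["lifetime"].mean() - mean) < 3 * se + 0.35

    def test_events_lie_within_field_of_view(self, wt_scene, imaging_long):
        events, _ = wt_scene
        ny, nx = imaging_long.fov_shape
        for e in events.patches:
            x, y = e.cortex_position
            assert 0 <= x / imaging_long.pixel_size < nx
            assert 0 <= y / imaging_long.pixel_size < ny

    def test_query_channel_leads_reference(self, wt_scene):
        # green marker appears and peaks before the red reference on every patch
        events, _ = wt_scene
        for e in events.patches:
            assert e.query_amplitude > 0
            tq = e.peak_time - e.query_lead
            assert e.amplitude(tq, channel=1) == pytest.approx(
                e.query_amplitude * e.peak_molecules)
            assert e.amplitude(tq, channel=0) < e.peak_molecules


class TestRenderMovie:
    def test_empty_scene_noise_free_is_flat_background(self, imaging):
        ev = manual_events([])
        im = ImagingModel(n_frames=3, camera_gain=2.0)
        movie = render_movie(ev, im, noise=False, cytoplasm_level=0.0)
        assert np.all(movie.data == 2.0 * im.background_level)

    def test_photon_conservation_noise_free(self):
        # summed above-background intensity equals the analytic amplitude sum
        im = ImagingModel(n_frames=9)
        ev = manual_events([
            manual_patch(20, 24), manual_patch(50, 20, birth=2.0),
            manual_patch(75, 28, assembly=6.0),
        ])
        movie = render_movie(ev, im, noise=False, cytoplasm_level=0.0)
        for t in im.frame_times:
            total = movie.data[int(t / 2), 0].sum() \
                - im.background_level * movie.data[int(t / 2), 0].size
            expected = sum(
                e.amplitude(t, 0) * im.photons_per_molecule for e in ev.patches)
            assert total == pytest.approx(expected, rel=0.01, abs=1.0)

    def test_single_patch_total_matches_gaussian_integral(self):
        im = ImagingModel(n_frames=1)
        ev = manual_events([manual_patch(48, 24, birth=-8.0)])  # at peak at t=0
        movie = render_movie(ev, im, noise=False, cytoplasm_level=0.0)
        total = movie.data[0, 0].sum() - im.background_level * movie.data[0, 0].size
        assert total == pytest.approx(900.0 * im.photons_per_molecule, rel=0.005)

    def test_noise_reproducibility_contract(self, imaging):
        p = make_genotype_preset("WT")
        im = ImagingModel(n_frames=5)
        ev = simulate_events(p, imaging=im, seed=3)
        m1 = render_movie(ev, im, seed=1)
        m2 = render_movie(ev, im, seed=2)
        m1b = render_movie(ev, im, seed=1)
        assert np.array_equal(m1.data, m1b.data)
        assert not np.array_equal(m1.data, m2.data)


class TestSimulateLane:
    def test_single_band_area_equals_total(self):
        spec = LaneProfileSpec(band_mws=(150.0,), band_fractions=(1.0,),
                               total_amount=2.5)
        lane = simulate_lane(spec)
        area = np.trapezoid(lane.intensity, lane.axis)
        assert area == pytest.approx(2.5, rel=1e-3)
        assert len(np.flatnonzero(np.diff(np.sign(np.diff(lane.intensity))) < 0)) == 1

    def test_wild_type_truth_fraction(self):
        from patchdyn.experiments import genotype_lane_spec

        spec = genotype_lane_spec("WT")
        areas = spec.true_areas()
        assert areas[150.0] / sum(areas.values()) == pytest.approx(0.30)

    def test_two_lane_total_ratio(self):
        from patchdyn.experiments import genotype_lane_spec

        wt = genotype_lane_spec("WT")
        mut = genotype_lane_spec("A181P")
        assert mut.total_amount / wt.total_amount == pytest.approx(0.6)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            LaneProfileSpec(band_fractions=(0.5, 0.4, 0.2))  # sums to 1.1
        with pytest.raises(ValueError):
            LaneProfileSpec(total_amount=-1.0)


def test_geometry_invariants():
    cell = CellGeometry()
    # perimeter point + inward normal stay consistent around the outline
    s = np.linspace(0, cell.perimeter, 200, endpoint=False)
    pos, normal = cell.point_at(s)
    assert np.allclose(np.hypot(normal[:, 0], normal[:, 1]), 1.0)
    inside = pos + 0.2 * normal
    mask = cell.mask((48, 96), 0.16)
    iy = np.clip((inside[:, 1] / 0.16).round().astype(int), 0, 47)
    ix = np.clip((inside[:, 0] / 0.16).round().astype(int), 0, 95)
    assert mask[iy, ix].mean() > 0.95
    with pytest.raises(ValueError):
        CellGeometry(half_length=1.0, radius=2.0)
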