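"""Ground-truth scenes, blinking movies, carryover, and camera model."""

import numpy as np
import pytest

from sdstorm.kinetics import KineticsModel
from sdstorm.simulate import (
    CameraModel,
    ClusterSpec,
    FilamentSpec,
    MovieStack,
    PhotophysicsParams,
    RoundSpec,
    adu_to_photons,
    make_scene,
    photons_to_adu,
    simulate_round,
    simulate_timecourse_movie,
)


class TestMakeScene:
    def test_horizontal_filament_site_arithmetic(self):
        spec = FilamentSpec(target_id="t", length_um=2.0, site_spacing_um=0.02,
                            start_um=(1.0, 3.0), angle_deg=0.0)
        scene = make_scene([spec], field_size_um=(6.8, 6.8), seed=0)
        assert scene.n_sites == 101
        assert np.allclose(scene.sites[:, 1], 3.0)  # collinear
        assert np.allclose(np.diff(scene.sites[:, 0]), 0.02)

    def test_empty_structure_list(self):
        scene = make_scene([], field_size_um=(5, 5), seed=0)
        assert scene.n_sites == 0

    def test_deterministic_for_fixed_seed(self):
        specs = [ClusterSpec(target_id="c", n=5), FilamentSpec(target_id="f")]
        s1 = make_scene(specs, (6.8, 6.8), seed=42)
        s2 = make_scene(specs, (6.8, 6.8), seed=42)
        assert np.array_equal(s1.sites, s2.sites)
        assert np.array_equal(s1.target_ids, s2.target_ids)

    def test_sites_inside_field(self):
        specs = [ClusterSpec(target_id="c", n=20), FilamentSpec(target_id="f", n=5)]
        scene = make_scene(specs, (6.8, 6.8), seed=3)
        assert scene.sites.min() >= 0
        assert scene.sites.max() <= 6.8


class TestSimulateRound:
    def test_background_only_when_no_sites(self, desk_camera, blinking):
        scene = make_scene([], field_size_um=(6.8, 6.8), seed=0)
        spec = RoundSpec(round_index=1, target_id="none")
        sim = simulate_round(scene, spec, blinking, desk_camera,
                             n_frames=50, seed=1, background=5.0)
        mean = sim.movie.frames.mean()
        # Poisson mean of 5 per pixel, 50*64*64 samples
        assert mean == pytest.approx(5.0, abs=3 * np.sqrt(5.0 / (50 * 64 * 64)))
        assert len(sim.truth) == 0

    def test_photon_conservation_single_emitter(self, desk_camera):
        # one permanently-on emitter at field center, zero background
        scene = make_scene(
            [FilamentSpec(target_id="t", length_um=0.0, site_spacing_um=1.0,
                          start_um=(3.4, 3.4), angle_deg=0.0)],
            field_size_um=(6.8, 6.8), seed=0)
        assert scene.n_sites == 1
        ph = PhotophysicsParams(p_on=1.0, mean_on_frames=1e9,
                                photons_per_frame=1000.0)
        spec = RoundSpec(round_index=1, target_id="t", label_prob=1.0)
        sim = simulate_round(scene, spec, ph, desk_camera,
                             n_frames=200, seed=2, background=0.0)
        sums = sim.movie.frames.sum(axis=(1, 2))
        se = np.sqrt(1000.0 / 200)
        assert sums.mean() == pytest.approx(1000.0, abs=3 * se)

    def test_carryover_is_binomial_on_previous_labels(self, two_target_scene,
                                                      desk_camera, blinking):
        spec1 = RoundSpec(round_index=1, target_id="clathrin", label_prob=0.9)
        sim1 = simulate_round(two_target_scene, spec1, blinking, desk_camera,
                              n_frames=1, seed=3)
        n_prev = len(sim1.labeled_sites)
        r = 0.1
        spec2 = RoundSpec(round_index=2, target_id="tubulin", label_prob=0.0,
                          carryover_residual=r)
        sim2 = simulate_round(two_target_scene, spec2, blinking, desk_camera,
                              n_frames=1, seed=4,
                              previous_labeled=sim1.labeled_sites)
        k = len(sim2.carryover_sites)
        sd = np.sqrt(n_prev * r * (1 - r))
        assert abs(k - n_prev * r) < 4 * sd
        assert set(sim2.carryover_sites) <= set(sim1.labeled_sites)

    def test_bit_exact_reproducibility(self, two_target_scene, desk_camera, blinking):
        spec = RoundSpec(round_index=1, target_id="clathrin")
        a = simulate_round(two_target_scene, spec, blinking, desk_camera,
                           n_frames=20, seed=9)
        b = simulate_round(two_target_scene, spec, blinking, desk_camera,
                           n_frames=20, seed=9)
        assert np.array_equal(a.movie.frames, b.movie.frames)
        assert a.truth.equals(b.truth)

    def test_truth_rows_mark_elevated_pixels(self, two_target_scene,
                                             desk_camera, blinking):
        spec = RoundSpec(round_index=1, target_id="clathrin")
        sim = simulate_round(two_target_scene, spec, blinking, desk_camera,
                             n_frames=100, seed=5, background=5.0)
        assert len(sim.truth) > 0
        vals = [
            sim.movie.frames[f, int(round(y)), int(round(x))]
            for f, x, y in sim.truth[["frame", "x_px", "y_px"]].itertuples(index=False)
            if 0 <= int(round(y)) < 64 and 0 <= int(round(x)) < 64
        ]
        # at the true position the expected value is ~background + N*peak >> 5
        assert np.mean(vals) > 25.0

    def test_undersampled_psf_warns(self, two_target_scene, desk_camera, blinking):
        spec = RoundSpec(round_index=1, target_id="clathrin")
        with pytest.warns(UserWarning, match="undersampled"):
            simulate_round(two_target_scene, spec, blinking, desk_camera,
                           n_frames=1, seed=0, psf_sigma_px=0.3)


class TestCameraModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            CameraModel(pixel_size_um=-1)
        with pytest.raises(ValueError):
            CameraModel(em_gain=0.5)

    def test_adu_round_trip_preserves_mean(self, rng):
        cam = CameraModel(frame_shape=(32, 32))
        photons = np.full((50, 32, 32), 40.0)
        movie = MovieStack(frames=photons, camera=cam, units="photons")
        adu = photons_to_adu(movie, rng)
        assert adu.units == "adu"
        back = adu_to_photons(adu)
        # EM gain adds excess noise but the mean photon flux is preserved
        assert back.frames.mean() == pytest.approx(40.0, rel=0.02)

    def test_tiff_round_trip_with_metadata(self, tmp_path, rng):
        cam = CameraModel(frame_shape=(16, 16), frame_rate_hz=30.0)
        frames = rng.poisson(20, (5, 16, 16)).astype(float)
        movie = MovieStack(frames=frames, camera=cam, units="photons")
        path = tmp_path / "movie.tif"
        movie.to_tiff(str(path))
        loaded = MovieStack.from_tiff(str(path))
        assert np.array_equal(loaded.frames, frames)
        assert loaded.camera == cam
        assert loaded.units == "photons"


class TestTimecourseMovie:
    def test_plateau_matches_residual(self, desk_camera):
        scene = make_scene([ClusterSpec(target_id="c", n=25, mean_sites=40)],
                           field_size_um=(6.8, 6.8), seed=3)
        m = KineticsModel(k_disp=0.05, invader_conc=1.0, bleach_rate=0.0,
                          residual_fraction=0.05, t_invader=20.0)
        mv = simulate_timecourse_movie(scene, m, desk_camera, duration_s=400,
                                       photons_per_frame=30.0, background=5.0,
                                       seed=11)
        sums = mv.frames.sum(axis=(1, 2))
        bg = 5.0 * 64 * 64
        early = sums[:40].mean() - bg
        late = sums[-100:].mean() - bg
        assert late / early == pytest.approx(0.05, abs=0.02)

    def test_flat_before_invader_without_bleaching(self, desk_camera):
        scene = make_scene([ClusterSpec(target_id="c", n=10)],
                           field_size_um=(6.8, 6.8), seed=4)
        m = KineticsModel(bleach_rate=0.0, t_invader=50.0)
        mv = simulate_timecourse_movie(scene, m, desk_camera, duration_s=60,
                                       seed=12)
        sums = mv.frames.sum(axis=(1, 2))
        pre = sums[mv.times_s() < 50.0]
        assert pre.std() / pre.mean() < 0.02

    def test_duration_must_cover_invader(self, desk_camera):
        scene = make_scene([ClusterSpec(target_id="c", n=5)], (6.8, 6.8), seed=0)
        m = KineticsModel(t_invader=100.0)
        with pytest.raises(ValueError, match="t_invader"):
            simulate_timecourse_movie(scene, m, desk_camera, duration_s=50,
                                      seed=0)
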