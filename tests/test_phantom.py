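"""Phantom generator: speckle statistics, vessel-fraction control, determinism."""

import numpy as np
import pytest

from endooct import (
    RAYLEIGH_MEAN_SD_RATIO,
    PhantomGeometry,
    make_tissue_scene,
    render_frame_sequence,
)


class TestGeometry:
    @pytest.mark.parametrize("kwargs", [
        {"n_depth": 4}, {"n_fast": 2}, {"axial_pixel_um": 0.0},
        {"lateral_pixel_um": -1}, {"n_repeats": 1},
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomGeometry(**kwargs)

    def test_default_depth(self):
        assert PhantomGeometry().depth_um == pytest.approx(256 * 14.0)

    def test_dict_roundtrip(self):
        g = PhantomGeometry(n_depth=32, n_fast=16, n_slow=8)
        assert PhantomGeometry.from_dict(g.to_dict()) == g


class TestTissueScene:
    def test_zero_fraction_gives_empty_mask(self, small_geometry):
        scene = make_tissue_scene(small_geometry, vessel_fraction=0.0, seed=0)
        assert not scene.vessel_mask.any()

    def test_thickness_rasterization(self, small_geometry):
        # 150 um at 14 um/px rounds to 11 px in every column
        scene = make_tissue_scene(small_geometry, thickness_um=150.0,
                                  vessel_fraction=0.0, seed=0)
        assert np.all(scene.thickness_px == 11)

    @pytest.mark.parametrize("target", [0.1, 0.25])
    def test_enface_fraction_hits_target(self, small_geometry, target):
        scene = make_tissue_scene(small_geometry, vessel_fraction=target, seed=7)
        assert scene.enface_vessel_fraction == pytest.approx(target, abs=0.02)

    def test_fraction_out_of_range_rejected(self, small_geometry):
        with pytest.raises(ValueError, match="vessel_fraction"):
            make_tissue_scene(small_geometry, vessel_fraction=0.95)

    def test_excess_thickness_names_maximum(self, small_geometry):
        with pytest.raises(ValueError, match="maximum representable"):
            make_tissue_scene(small_geometry, thickness_um=5000.0,
                              vessel_fraction=0.0)

    def test_vessels_lie_below_epithelium(self, small_geometry):
        scene = make_tissue_scene(small_geometry, thickness_um=100,
                                  vessel_fraction=0.2, seed=3)
        zs = np.where(scene.vessel_mask)[2]
        bottom_of_epithelium = (scene.surface_index + scene.thickness_px).max()
        assert zs.min() >= bottom_of_epithelium

    def test_scene_carries_generating_parameters(self, small_geometry):
        scene = make_tissue_scene(small_geometry, thickness_um=120,
                                  vessel_fraction=0.15, seed=9)
        assert scene.params["vessel_fraction_target"] == 0.15
        assert scene.params["seed"] == 9

    def test_deterministic_under_seed(self, small_geometry):
        a = make_tissue_scene(small_geometry, vessel_fraction=0.2, seed=5)
        b = make_tissue_scene(small_geometry, vessel_fraction=0.2, seed=5)
        np.testing.assert_array_equal(a.vessel_mask, b.vessel_mask)
        np.testing.assert_array_equal(a.surface_depth, b.surface_depth)

    def test_ablation_grid_pattern(self, small_geometry):
        scene = make_tissue_scene(small_geometry, vessel_fraction=0.0,
                                  seed=0, ablation_grid_pitch_px=16)
        assert scene.ablation_grid is not None
        assert 0 < scene.ablation_grid.mean() < 0.5


class TestRenderer:
    def test_static_noiseless_frames_identical(self, small_geometry):
        scene = make_tissue_scene(small_geometry, vessel_fraction=0.2, seed=0)
        vol = render_frame_sequence(scene, decorrelation=0.0, noise_floor=0.0, seed=1)
        for j in range(1, small_geometry.n_repeats):
            np.testing.assert_array_equal(vol.frames[:, j], vol.frames[:, 0])

    def test_air_stays_at_noise_floor(self, small_geometry):
        scene = make_tissue_scene(small_geometry, vessel_fraction=0.0, seed=0,
                                  surface_depth_px=20.0)
        nf = 0.05
        vol = render_frame_sequence(scene, decorrelation=0.0, noise_floor=nf, seed=1)
        air = vol.frames[:, :, :, :10]  # well above the shallowest surface
        # Rayleigh mean amplitude of pure noise is noise_floor * sqrt(pi)/2
        assert air.mean() == pytest.approx(nf * np.sqrt(np.pi) / 2, rel=0.05)
        assert np.quantile(air, 0.99) < 4 * nf

    def test_rayleigh_speckle_statistics(self, small_geometry):
        # uniform static tissue block: amplitude mean/SD = sqrt(pi/(4-pi))
        scene = make_tissue_scene(small_geometry, thickness_um=0.0,
                                  vessel_fraction=0.0, seed=0, surface_depth_px=10.0)
        vol = render_frame_sequence(scene, decorrelation=0.0, noise_floor=0.0, seed=3)
        block = vol.frames[:, 0, :, 30:60]  # deep lamina, one frame
        ratio = block.mean() / block.std()
        assert ratio == pytest.approx(RAYLEIGH_MEAN_SD_RATIO, rel=0.02)

    def test_full_decorrelation_independent_vessel_speckle(self, vessel_phantom):
        scene, vol = vessel_phantom  # rendered with decorrelation=1
        mask_yxz = np.moveaxis(scene.vessel_mask, 1, 0)  # (y, x, z)
        f0 = vol.frames[:, 0][mask_yxz]
        f1 = vol.frames[:, 1][mask_yxz]
        assert len(f0) >= 10_000
        r = np.corrcoef(f0, f1)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(f0))

    def test_partial_decorrelation_is_intermediate(self, small_geometry):
        scene = make_tissue_scene(small_geometry, thickness_um=100,
                                  vessel_fraction=0.4, seed=2)
        vol = render_frame_sequence(scene, decorrelation=0.5, noise_floor=0.0, seed=5)
        mask_yxz = np.moveaxis(scene.vessel_mask, 1, 0)  # (y, x, z)
        f0 = vol.frames[:, 0][mask_yxz]
        f1 = vol.frames[:, 1][mask_yxz]
        r = np.corrcoef(f0, f1)[0, 1]
        assert 0.1 < r < 0.9

    def test_decorrelation_out_of_range_rejected(self, small_geometry):
        scene = make_tissue_scene(small_geometry, vessel_fraction=0.0, seed=0)
        with pytest.raises(ValueError, match="decorrelation"):
            render_frame_sequence(scene, decorrelation=1.5)

    def test_deterministic_under_seed(self, small_geometry):
        scene = make_tissue_scene(small_geometry, vessel_fraction=0.2, seed=0)
        a = render_frame_sequence(scene, decorrelation=1.0, noise_floor=0.05, seed=9)
        b = render_frame_sequence(scene, decorrelation=1.0, noise_floor=0.05, seed=9)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_ablation_grid_decorrelates(self, small_geometry):
        scene = make_tissue_scene(small_geometry, thickness_um=0.0,
                                  vessel_fraction=0.0, seed=0,
                                  ablation_grid_pitch_px=16)
        vol = render_frame_sequence(scene, decorrelation=1.0, noise_floor=0.0, seed=1)
        d0, d1 = vol.frames[:, 0], vol.frames[:, 1]
        changed = np.moveaxis(np.abs(d0 - d1) > 1e-9, 0, 1)  # (x, y, z)
        grid_cols = changed.any(axis=2)
        np.testing.assert_array_equal(grid_cols, scene.ablation_grid)
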