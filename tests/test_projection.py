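"""Ray tracer analytics, photon noise statistics, node projection."""

import numpy as np
import pytest

from livertrack.grid import GridSpec
from livertrack.projection import (PhotonNoiseConfig, ProjectionGeometry,
                                   XRayProjection, add_photon_noise,
                                   project_nodes, raytrace)


def _cube_volume(grid, mu=0.01, half=48.0):
    c = grid.voxel_centers()
    vol = np.zeros(grid.shape)
    vol[np.all(np.abs(c) < half, axis=-1)] = mu
    return vol


class TestRaytrace:
    def test_central_ray_through_homogeneous_cube_is_exact(self):
        # voxel-aligned cube: the central AP ray chord is exactly its side
        g = GridSpec.centered(50, 4.0)
        vol = _cube_volume(g, mu=0.01, half=48.0)   # 96 mm of mu = 0.01
        geom = ProjectionGeometry(det_shape=(15, 11))
        proj = raytrace(vol, g, geom)
        assert abs(proj.line_integrals[5, 7] - 0.96) < 1e-9

    def test_empty_volume_warns_and_is_zero(self):
        g = GridSpec.centered(16, 4.0)
        with pytest.warns(UserWarning):
            proj = raytrace(np.zeros(g.shape), g,
                            ProjectionGeometry(det_shape=(8, 6)))
        assert np.all(proj.line_integrals == 0.0)

    def test_linearity_in_attenuation(self, rng):
        g = GridSpec.centered(16, 6.0)
        vol = rng.uniform(0, 0.02, size=g.shape)
        geom = ProjectionGeometry(det_shape=(12, 10), gantry_deg=40.0)
        a = raytrace(vol, g, geom).line_integrals
        b = raytrace(3.0 * vol, g, geom).line_integrals
        assert np.allclose(b, 3.0 * a, rtol=1e-12)

    def test_oblique_rays_match_fine_stepping_integrator(self, rng):
        g = GridSpec.centered(16, 6.0)
        vol = rng.uniform(0, 0.02, size=g.shape)
        geom = ProjectionGeometry(det_shape=(6, 5), gantry_deg=30.0,
                                  pixel_pitch=12.0)
        proj = raytrace(vol, g, geom).line_integrals
        src = geom.source
        pix = geom.pixel_positions()
        lo, hi = g.bounds()
        step = 0.005   # fine enough that the stepping error is << 1e-3
        for iv in range(pix.shape[0]):
            for iu in range(pix.shape[1]):
                d = pix[iv, iu] - src
                with np.errstate(divide="ignore"):
                    t1, t2 = (lo - src) / d, (hi - src) / d
                a0 = max(np.minimum(t1, t2).max(), 0.0) - 1e-6
                a1 = min(np.maximum(t1, t2).min(), 1.0) + 1e-6
                if a1 <= a0:
                    assert proj[iv, iu] == 0.0
                    continue
                L = np.linalg.norm(d)
                ts = np.arange(a0, a1, step / L)
                pts = src + (ts[:, None] + 0.5 * step / L) * d
                idx = np.floor((pts - lo) / np.asarray(g.spacing)).astype(int)
                ok = np.all((idx >= 0) & (idx < np.array(g.shape)), axis=1)
                idx = np.clip(idx, 0, np.array(g.shape) - 1)
                mu = np.where(ok, vol[idx[:, 0], idx[:, 1], idx[:, 2]], 0.0)
                oracle = mu.sum() * step
                assert abs(proj[iv, iu] - oracle) <= max(1e-3 * oracle, 1e-4)

    def test_gantry_and_volume_rotate_together(self):
        # rotating a voxel-symmetric volume by 90 deg with the gantry leaves
        # the projection invariant
        g = GridSpec.centered(20, 5.0)
        vol = np.zeros(g.shape)
        vol[7:13, 7:13, 8:12] = 0.01
        p0 = raytrace(vol, g, ProjectionGeometry(det_shape=(10, 8)))
        vol90 = np.rot90(vol, k=1, axes=(0, 1))   # rotate about SI
        p90 = raytrace(vol90, g, ProjectionGeometry(det_shape=(10, 8),
                                                    gantry_deg=90.0))
        assert np.allclose(p0.line_integrals, p90.line_integrals, atol=1e-9)


class TestPhotonNoise:
    def _flat(self, n=100_000):
        geom = ProjectionGeometry(det_shape=(500, 200))
        return XRayProjection(np.zeros((200, 500)), geom)

    def test_mean_and_variance_match_compound_model(self):
        proj = self._flat()
        cfg = PhotonNoiseConfig()
        noisy = add_photon_noise(proj, cfg, np.random.default_rng(0))
        counts = noisy.noisy_counts
        assert abs(counts.mean() - 1e5) / 1e5 < 0.005
        assert abs(counts.var() - (1e5 + 100.0)) / (1e5 + 100.0) < 0.05

    def test_noise_free_limit_recovers_line_integrals(self, rng):
        geom = ProjectionGeometry(det_shape=(16, 12))
        li = rng.uniform(0, 2, size=(12, 16))
        proj = XRayProjection(li, geom)
        noisy = add_photon_noise(proj, PhotonNoiseConfig(1e9, 0.0), rng)
        assert np.allclose(noisy.line_integrals, li, atol=1e-3)

    def test_same_seed_is_bit_reproducible(self):
        proj = self._flat()
        cfg = PhotonNoiseConfig()
        a = add_photon_noise(proj, cfg, 42).noisy_counts
        b = add_photon_noise(proj, cfg, 42).noisy_counts
        assert np.array_equal(a, b)

    def test_counts_are_nonnegative_integers(self, rng):
        geom = ProjectionGeometry(det_shape=(16, 12))
        proj = XRayProjection(np.full((12, 16), 5.0), geom)
        noisy = add_photon_noise(proj, PhotonNoiseConfig(10.0, 50.0), rng)
        c = noisy.noisy_counts
        assert np.all(c >= 0) and np.all(c == np.rint(c))


class TestProjectNodes:
    def test_isocenter_maps_to_detector_center(self):
        geom = ProjectionGeometry()
        uv, fov = project_nodes(np.zeros((1, 3)), geom)
        assert np.allclose(uv, 0.0) and fov[0]

    def test_lateral_offset_magnified_by_sdd_over_sad(self):
        geom = ProjectionGeometry()
        uv, _ = project_nodes(np.array([[10.0, 0.0, 0.0]]), geom)
        assert abs(uv[0, 0] - 10.0 * geom.sdd / geom.sad) < 1e-9

    def test_far_lateral_node_out_of_fov(self):
        geom = ProjectionGeometry()   # half-width ~ 199 mm
        _, fov = project_nodes(np.array([[400.0, 0.0, 0.0]]), geom)
        assert not fov[0]

    def test_node_behind_source_flagged(self):
        geom = ProjectionGeometry()
        _, fov = project_nodes(np.array([[0.0, 1500.0, 0.0]]), geom)
        assert not fov[0]
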