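"""Anatomy phantom: voxelization, containment, breathing motion, warping."""

import numpy as np
import pytest

from livertrack.grid import GridSpec, VolumetricDVF
from livertrack.mesh import MeshError, TriMesh, icosphere
from livertrack.phantom import (ConfigurationError, MotionParams,
                                PhantomConfig, invert_dvf,
                                make_breathing_phases, make_phantom,
                                voxelize, warp_mask)


class TestMesh:
    def test_icosphere_node_count_follows_subdivision_order(self):
        for order, n in [(1, 42), (2, 162), (3, 642)]:
            assert icosphere(order).n_nodes == n

    def test_adjacency_is_symmetric_and_faces_nondegenerate(self):
        m = icosphere(2, 40.0)
        m.validate()  # raises on violation

    def test_subdivision_operator_is_linear_in_nodes(self):
        m = icosphere(1, 30.0)
        S, _ = m.subdivision_operator(10.0)
        t = np.array([3.0, -2.0, 5.0])
        fine = S @ m.nodes
        fine_t = S @ (m.nodes + t)
        assert np.allclose(fine_t, fine + t)


class TestVoxelize:
    def test_sphere_voxel_volume_matches_mesh_volume(self):
        mesh = icosphere(3, 20.0)
        mask = voxelize(mesh, GridSpec.centered(32, 2.0))
        vox = mask.sum() * 8.0
        assert abs(vox - mesh.to_trimesh().volume) / vox < 0.05
        assert abs(vox - 4.0 / 3.0 * np.pi * 20.0 ** 3) / vox < 0.05

    def test_mesh_outside_grid_gives_empty_mask(self):
        mesh = icosphere(2, 10.0, center=(500.0, 0.0, 0.0))
        assert voxelize(mesh, GridSpec.centered(16, 4.0)).sum() == 0

    def test_open_mesh_rejected(self):
        m = icosphere(1, 10.0)
        open_mesh = TriMesh(m.nodes, m.faces[:-3])
        with pytest.raises(MeshError):
            voxelize(open_mesh, GridSpec.centered(16, 4.0))

    def test_nested_meshes_give_nested_masks(self, phantom):
        liver = voxelize(phantom.liver_mesh, phantom.grid)
        tumor = voxelize(phantom.tumor_mesh, phantom.grid)
        assert not np.any(tumor & ~liver)


class TestMakePhantom:
    def test_deterministic_and_invariants(self):
        cfg = PhantomConfig(grid=GridSpec.centered(32, 8.0))
        a = make_phantom(cfg, seed=7)
        b = make_phantom(cfg, seed=7)
        assert np.array_equal(a.liver_mesh.nodes, b.liver_mesh.nodes)
        assert a.liver_mesh.n_nodes == 162
        # containment chain on the label volume
        assert not np.any((a.label_volume == 3) & ~(a.label_volume >= 2))
        # low tumor contrast
        assert abs(a.config.mu_tumor - a.config.mu_liver) <= \
            0.02 * a.config.mu_liver + 1e-12

    def test_small_tumor_volume_matches_sphere(self):
        cfg = PhantomConfig(grid=GridSpec.centered(64, 2.0),
                            tumor_diameter=8.0, tumor_subdivisions=2)
        ph = make_phantom(cfg, seed=1)
        vox = (ph.label_volume == 3).sum() * ph.grid.voxel_volume()
        analytic = np.pi / 6.0 * 8.0 ** 3
        # within one voxel shell of the analytic ball volume
        shell = 4.0 * np.pi * 4.0 ** 2 * 2.0
        assert abs(vox - analytic) < shell

    def test_tumor_outside_liver_rejected(self):
        cfg = PhantomConfig(tumor_offset=(100.0, 0.0, 0.0))
        with pytest.raises(ConfigurationError):
            make_phantom(cfg, seed=0)


class TestBreathingPhases:
    def test_zero_amplitudes_give_zero_fields(self, phantom):
        ps = make_breathing_phases(
            phantom, 4, MotionParams(0.0, 0.0, 0.0), seed=0)
        for v in ps.volumetric_dvfs:
            assert np.all(v.field == 0.0)

    def test_negative_amplitude_rejected(self, phantom):
        with pytest.raises(ConfigurationError):
            make_breathing_phases(phantom, 4, MotionParams(amplitude_si=-1.0))

    def test_si_peak_reached_and_phase0_zero(self, phases):
        d = np.stack([b.d for b in phases.boundary_dvfs])
        assert np.all(d[0] == 0.0)
        assert abs(np.abs(d[..., 2]).max() - 15.0) < 1e-6
        # respiratory dominance SI >= AP >= LR
        mean_amp = np.abs(d).max(axis=(0, 1))
        assert mean_amp[2] >= mean_amp[1] >= mean_amp[0]

    def test_seed_contract(self, phantom):
        a = make_breathing_phases(phantom, 6, seed=1)
        b = make_breathing_phases(phantom, 6, seed=1)
        c = make_breathing_phases(phantom, 6, seed=2)
        assert np.array_equal(a.volumetric_dvfs[3].field,
                              b.volumetric_dvfs[3].field)
        assert not np.array_equal(a.volumetric_dvfs[3].field,
                                  c.volumetric_dvfs[3].field)

    def test_containment_preserved_under_warping(self, phantom, phases):
        liver = phantom.mask(2)
        tumor = phantom.mask(3)
        w_l = warp_mask(liver, phases.volumetric_dvfs[5])
        w_t = warp_mask(tumor, phases.volumetric_dvfs[5])
        assert not np.any(w_t & ~w_l)


class TestWarpMask:
    def test_zero_dvf_is_identity(self, phantom):
        mask = phantom.mask(2)
        dvf = VolumetricDVF(np.zeros(phantom.grid.shape + (3,)), phantom.grid)
        assert np.array_equal(warp_mask(mask, dvf), mask)

    def test_integer_translation_is_exact_shift(self, phantom):
        mask = phantom.mask(2)
        g = phantom.grid
        dvf = VolumetricDVF(np.broadcast_to([8.0, 0.0, 0.0],
                                            g.shape + (3,)).copy(), g)
        out = warp_mask(mask, dvf)
        assert np.array_equal(out[1:], mask[:-1])

    def test_grid_mismatch_rejected(self, phantom):
        g2 = GridSpec.centered(16, 8.0)
        dvf = VolumetricDVF(np.zeros(g2.shape + (3,)), g2)
        with pytest.raises(Exception):
            warp_mask(phantom.mask(2), dvf)

    def test_radial_field_volume_change_matches_jacobian(self):
        # smooth radial expansion of a sphere mask: compare the voxel-count
        # change with the integral of the warp Jacobian over the mask
        g = GridSpec.centered(48, 2.0)
        mask = voxelize(icosphere(3, 25.0), g)
        pts = g.voxel_centers()
        field = 0.08 * pts * np.exp(-((pts ** 2).sum(-1, keepdims=True)) / (2 * 40.0 ** 2))
        dvf = VolumetricDVF(field, g)
        out = warp_mask(mask, dvf)
        grads = np.stack(
            [np.stack(np.gradient(field[..., c], *g.spacing), axis=-1)
             for c in range(3)], axis=-2)
        jac = np.linalg.det(np.eye(3) + grads)
        predicted = jac[mask].sum()
        assert abs(out.sum() - predicted) / predicted < 0.05

    def test_roundtrip_recovers_mask_up_to_boundary_shell(self, phantom, phases):
        from scipy import ndimage

        mask = phantom.mask(2)
        dvf = phases.volumetric_dvfs[4]
        back = VolumetricDVF(-dvf.field, phantom.grid)
        rt = warp_mask(warp_mask(mask, dvf), back)
        diff = rt ^ mask
        shell = ndimage.binary_dilation(mask) & ~ndimage.binary_erosion(mask)
        assert not np.any(diff & ~shell)
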