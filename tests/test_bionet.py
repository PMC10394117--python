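"""DC/AC decomposition, gridding, the reference elastic solver, U-Net."""

import numpy as np
import pytest

from livertrack.bionet import (BioUNetConfig, build_bio_unet, decompose_dc_ac,
                               grid_ac, liver_band, predict_intra_dvf)
from livertrack.elastic import (rasterize_boundary, shell_and_interior,
                                solve_dirichlet, solve_reference_biomechanics)
from livertrack.grid import BoundaryDVF, GridSpec
from livertrack.mesh import icosphere
from livertrack.nn import autodiff as ad
from livertrack.phantom import voxelize


class TestDecompose:
    def test_uniform_field(self):
        d = np.tile([1.0, 2.0, 3.0], (30, 1))
        dec = decompose_dc_ac(BoundaryDVF(d))
        assert np.allclose(dec.dc, [1, 2, 3])
        assert np.allclose(dec.ac.d, 0.0)

    def test_zero_mean_field_passes_through(self, rng):
        d = rng.normal(size=(25, 3))
        d -= d.mean(axis=0)
        dec = decompose_dc_ac(BoundaryDVF(d))
        assert np.allclose(dec.dc, 0.0, atol=1e-12)
        assert np.allclose(dec.ac.d, d)

    def test_reconstruction_exact_and_ac_zero_mean(self, rng):
        d = rng.normal(size=(20, 3)) + [5, -2, 8]
        dec = decompose_dc_ac(BoundaryDVF(d))
        assert np.allclose(dec.dc, d.mean(axis=0), rtol=1e-14)
        assert np.abs(dec.ac.d.mean(axis=0)).max() < 1e-9
        assert np.allclose(dec.reconstruct().d, d, rtol=0, atol=1e-12)


class TestGridAC:
    def test_single_node_fills_band(self):
        g = GridSpec.centered(8, 4.0)
        mesh = icosphere(0, 1.0)
        single = mesh.with_nodes(np.zeros_like(mesh.nodes))  # all at origin
        band = np.zeros(g.shape, bool)
        band[2:6, 2:6, 2:6] = True
        ac = BoundaryDVF(np.tile([1.0, -1.0, 2.0], (mesh.n_nodes, 1)))
        vol = grid_ac(ac, single, g, band=band)
        assert np.allclose(vol[band], [1.0, -1.0, 2.0])
        assert np.all(vol[~band] == 0.0)

    def test_matches_exhaustive_nearest_node_search(self, rng):
        g = GridSpec.centered(10, 5.0)
        mesh = icosphere(1, 18.0)
        # jitter the nodes so no voxel center is exactly equidistant to two
        # nodes (ties would make the nearest-node choice ambiguous)
        mesh = mesh.with_nodes(mesh.nodes + rng.normal(0, 0.01,
                                                       mesh.nodes.shape))
        ac = BoundaryDVF(rng.normal(size=(mesh.n_nodes, 3)))
        band = rng.uniform(size=g.shape) < 0.3
        vol = grid_ac(ac, mesh, g, band=band)
        centers = g.voxel_centers()
        for ijk in np.argwhere(band):
            p = centers[tuple(ijk)]
            nearest = np.argmin(((mesh.nodes - p) ** 2).sum(axis=1))
            assert np.allclose(vol[tuple(ijk)], ac.d[nearest])

    def test_output_shape_and_channels(self):
        g = GridSpec.centered(8, 4.0)
        mesh = icosphere(1, 10.0)
        mask = voxelize(mesh, g)
        vol = grid_ac(BoundaryDVF(np.zeros((mesh.n_nodes, 3))), mesh, g,
                      liver_mask=mask)
        assert vol.shape == tuple(g.shape) + (3,)


class TestLiverBand:
    def test_dilation_is_metric(self):
        g = GridSpec.centered(16, 5.0)
        mask = np.zeros(g.shape, bool)
        mask[8, 8, 8] = True
        band = liver_band(mask, g, margin_mm=10.0)
        idx = np.argwhere(band)
        dist = np.linalg.norm((idx - [8, 8, 8]) * 5.0, axis=1)
        assert dist.max() <= 10.0 + 1e-9
        # all voxel offsets with norm <= 10 mm at 5 mm spacing: 33 voxels
        assert band.sum() == 33


class TestReferenceSolver:
    def _liver(self, n=16, spacing=7.0, r=45.0):
        g = GridSpec.centered(n, spacing)
        mesh = icosphere(2, r)
        return g, mesh, voxelize(mesh, g)

    def test_uniform_translation_is_exact(self):
        g, mesh, mask = self._liver()
        t = np.array([2.0, -1.0, 4.0])
        bdvf = BoundaryDVF(np.tile(t, (mesh.n_nodes, 1)))
        out = solve_reference_biomechanics(mask, bdvf, mesh, g)
        assert np.allclose(out[mask], t, atol=1e-10)
        assert np.all(out[~mask] == 0.0)

    def test_affine_field_is_exact(self):
        g, mesh, mask = self._liver()
        shell, interior = shell_and_interior(mask)
        A = np.array([[0.02, 0.01, 0.0], [0.0, 0.03, 0.01],
                      [0.01, 0.0, -0.02]])
        b = np.array([1.0, 0.0, 2.0])
        aff = g.voxel_centers() @ A.T + b
        vals = np.where(shell[..., None], aff, 0.0)
        out = solve_dirichlet(mask, vals, g)
        assert np.abs(out[interior] - aff[interior]).max() < 1e-9

    def test_matches_dense_direct_solve_on_8cube(self, rng):
        # 8^3 fully-masked block with random Dirichlet values on the shell
        mask = np.ones((8, 8, 8), bool)
        g = GridSpec.centered(8, 5.0)
        shell, interior = shell_and_interior(mask)
        vals = np.where(shell[..., None], rng.normal(size=(8, 8, 8, 3)), 0.0)
        out = solve_dirichlet(mask, vals, g, nu=0.45)
        # dense oracle: assemble the same equations with explicit loops
        idx = {tuple(v): i for i, v in enumerate(np.argwhere(interior))}
        n = len(idx)
        lam = 2 * 0.45 / (1 - 2 * 0.45)
        gd = lam + 1.0
        A = np.zeros((3 * n, 3 * n))
        rhs = np.zeros(3 * n)

        def acc(r, vox, comp, coeff):
            if vox in idx:
                A[r, 3 * idx[vox] + comp] += coeff
            else:
                rhs[r] -= coeff * vals[vox][comp]

        for vox, i in idx.items():
            x, y, z = vox
            for c in range(3):
                r = 3 * i + c
                acc(r, vox, c, -6.0 - 2.0 * gd)
                for ax, e in enumerate(np.eye(3, dtype=int)):
                    cd = 1.0 + (gd if ax == c else 0.0)
                    acc(r, tuple(np.array(vox) + e), c, cd)
                    acc(r, tuple(np.array(vox) - e), c, cd)
                for o in range(3):
                    if o == c:
                        continue
                    e1, e2 = np.eye(3, dtype=int)[c], np.eye(3, dtype=int)[o]
                    for s1 in (1, -1):
                        for s2 in (1, -1):
                            acc(r, tuple(np.array(vox) + s1 * e1 + s2 * e2),
                                o, gd * 0.25 * s1 * s2)
        dense = np.linalg.solve(A, rhs).reshape(n, 3)
        ours = out[interior]
        assert np.abs(dense - ours).max() < 1e-8

    def test_harmonic_mode_satisfies_maximum_principle(self, rng):
        g, mesh, mask = self._liver()
        shell, interior = shell_and_interior(mask)
        vals = np.where(shell[..., None],
                        rng.normal(size=mask.shape + (3,)), 0.0)
        out = solve_dirichlet(mask, vals, g, mode="harmonic")
        for c in range(3):
            assert out[interior][:, c].max() <= vals[shell][:, c].max() + 1e-9
            assert out[interior][:, c].min() >= vals[shell][:, c].min() - 1e-9

    def test_linearity_in_boundary_condition(self, rng):
        g, mesh, mask = self._liver(n=12, spacing=8.0, r=40.0)
        d = rng.normal(size=(mesh.n_nodes, 3))
        a = solve_reference_biomechanics(mask, BoundaryDVF(d), mesh, g)
        b = solve_reference_biomechanics(mask, BoundaryDVF(2 * d), mesh, g)
        assert np.allclose(b, 2 * a, rtol=1e-9, atol=1e-10)

    def test_empty_interior_returns_shell_only(self):
        g = GridSpec.centered(6, 10.0)
        mask = np.zeros(g.shape, bool)
        mask[2:4, 2:4, 2:4] = True   # too thin for any interior voxel
        mesh = icosphere(0, 12.0)
        out = solve_reference_biomechanics(
            mask, BoundaryDVF(np.ones((mesh.n_nodes, 3))), mesh, g)
        assert np.allclose(out[mask], 1.0)


class TestBioUNet:
    def test_contraction_features_double_from_8(self):
        cfg = BioUNetConfig(grid_shape=(32, 32, 32), depth=5,
                            entrance_features=8)
        net = build_bio_unet(cfg)
        assert net.contraction_feature_counts() == [8, 16, 32, 64, 128, 256]

    def test_output_shape_matches_input(self, rng):
        net = build_bio_unet(BioUNetConfig(grid_shape=(16, 16, 16), depth=3))
        x = ad.constant(rng.normal(size=(1, 3, 16, 16, 16)))
        assert net(x).shape == (1, 3, 16, 16, 16)

    def test_indivisible_grid_rejected(self):
        with pytest.raises(ValueError):
            build_bio_unet(BioUNetConfig(grid_shape=(20, 20, 20), depth=3))

    def test_dc_passthrough_with_zero_network(self, rng):
        # a freshly built net has a zero-initialized output layer, so a pure
        # rigid boundary translation must come out exactly as DC everywhere
        g = GridSpec.centered(16, 7.0)
        mesh = icosphere(2, 45.0)
        mask = voxelize(mesh, g)
        band = liver_band(mask, g, 10.0)
        net = build_bio_unet(BioUNetConfig(grid_shape=(16, 16, 16), depth=3))
        t = np.array([3.0, -2.0, 5.0])
        bdvf = BoundaryDVF(np.tile(t, (mesh.n_nodes, 1)))
        out = predict_intra_dvf(net, bdvf, mesh, g, band)
        assert np.allclose(out.field, t)

    def test_inference_deterministic(self, rng):
        g = GridSpec.centered(16, 7.0)
        mesh = icosphere(2, 45.0)
        band = liver_band(voxelize(mesh, g), g, 10.0)
        net = build_bio_unet(BioUNetConfig(grid_shape=(16, 16, 16), depth=3))
        bdvf = BoundaryDVF(rng.normal(size=(mesh.n_nodes, 3)))
        a = predict_intra_dvf(net, bdvf, mesh, g, band)
        b = predict_intra_dvf(net, bdvf, mesh, g, band)
        assert np.array_equal(a.field, b.field)

    def test_leaky_slope_is_02(self):
        assert BioUNetConfig().leaky_slope == 0.2


class TestBioTraining:
    def test_same_seed_retrain_reproduces_loss_curve(self, rng):
        from livertrack.bionet import train_bio
        from livertrack.surfnet import TrainSchedule

        g = GridSpec.centered(8, 10.0)
        band = np.zeros(g.shape, bool)
        band[2:6, 2:6, 2:6] = True
        cases = [(rng.normal(size=g.shape + (3,)),
                  rng.normal(size=g.shape + (3,)), band) for _ in range(6)]
        sched = TrainSchedule(epochs=2, batch_size=3)

        def run():
            net = build_bio_unet(BioUNetConfig(grid_shape=(8, 8, 8), depth=2,
                                               entrance_features=4, seed=5))
            _, hist = train_bio(net, cases[:4], cases[4:], sched, seed=9,
                                boundary_noise_mm=0.5)
            return hist

        assert run() == run()

    def test_train_test_phantom_overlap_rejected(self):
        from livertrack.bionet import train_bio

        with pytest.raises(ValueError):
            train_bio(None, [], [], train_ids=[1, 2], test_ids=[2])
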