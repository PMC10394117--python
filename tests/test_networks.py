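"""Architecture contracts and small learnability checks of the networks."""

import numpy as np
import pytest

from livertrack.grid import BoundaryDVF
from livertrack.mesh import icosphere
from livertrack.nn import autodiff as ad
from livertrack.projection import ProjectionGeometry, XRayProjection
from livertrack.surface import SurfaceImage
from livertrack.surfnet import (SurfNetConfig, TrainSchedule, build_surf_net,
                                predict_boundary_dvf, surf_loss, train_surf)
from livertrack.xnet import XNet, XNetConfig, x_forward


class TestSurfNetArchitecture:
    def test_output_shape_is_nodes_by_3(self, rng):
        cfg = SurfNetConfig(input_shape=(32, 32), n_nodes=42,
                            n_residual_modules=3)
        net = build_surf_net(cfg)
        out = net(ad.constant(rng.normal(size=(2, 1, 32, 32))))
        assert out.shape == (2, 42, 3)

    def test_feature_counts_double_per_module(self):
        cfg = SurfNetConfig(input_shape=(64, 64), entrance_features=12,
                            n_residual_modules=5, n_nodes=10)
        net = build_surf_net(cfg)
        assert net.feature_counts() == [12, 24, 48, 96, 192, 384]

    def test_incompatible_input_shape_rejected(self):
        with pytest.raises(ValueError):
            build_surf_net(SurfNetConfig(input_shape=(50, 50),
                                         n_residual_modules=5))

    def test_frozen_weights_are_deterministic(self, rng):
        net = build_surf_net(SurfNetConfig(input_shape=(32, 32), n_nodes=42,
                                           n_residual_modules=3))
        net.eval()
        x = ad.constant(rng.normal(size=(1, 1, 32, 32)))
        assert np.array_equal(net(x).data, net(x).data)

    def test_predict_checks_image_shape(self, rng):
        net = build_surf_net(SurfNetConfig(input_shape=(32, 32), n_nodes=42,
                                           n_residual_modules=3))
        net.set_normalization(SurfaceImage(np.full((32, 32), 20.0)))
        with pytest.raises(ValueError):
            predict_boundary_dvf(net, SurfaceImage(np.full((16, 16), 20.0)))


class TestSurfTraining:
    def test_tiny_model_beats_zero_predictor(self, rng):
        # toy problem: target displacement is a linear readout of the image
        # height offset; a few epochs must beat the zero-DVF predictor
        n_nodes, shape = 42, (16, 16)
        base = 30.0 + 2.0 * rng.normal(size=shape)
        readout = rng.normal(size=(n_nodes, 3))

        def make_case(amp):
            img = base + amp
            tgt = amp * readout * 0.5
            return (img - 30.0) / 2.0, tgt

        train = [make_case(a) for a in rng.uniform(-10, 10, 50)]
        val = [make_case(a) for a in rng.uniform(-10, 10, 12)]
        net = build_surf_net(SurfNetConfig(input_shape=shape, n_nodes=n_nodes,
                                           entrance_features=4,
                                           n_residual_modules=2, seed=0))
        net, history = train_surf(net, train, val,
                                  TrainSchedule(epochs=30, lr=1e-3,
                                                batch_size=10), seed=0)
        zero_loss = np.mean([surf_loss(np.zeros_like(t), t) for _, t in val])
        final_val = min(h[1] for h in history)
        assert final_val < zero_loss
        # sanity property: training loss decreases over the first epochs
        assert history[-1][0] < history[0][0]

    def test_divergence_aborts_with_diagnostic(self, rng):
        net = build_surf_net(SurfNetConfig(input_shape=(16, 16), n_nodes=10,
                                           n_residual_modules=2))
        bad = [(np.full((16, 16), np.nan), np.zeros((10, 3)))]
        with pytest.raises(FloatingPointError):
            train_surf(net, bad, bad, TrainSchedule(epochs=1), seed=0)


class TestXNet:
    def _setup(self, rng):
        mesh = icosphere(1, 40.0)
        geom = ProjectionGeometry(det_shape=(32, 24), pixel_pitch=12.0)
        model = XNet(XNetConfig(stage_widths=(4, 8), pool_stages=(0, 1),
                                gcn_hidden=16, seed=1),
                     mesh.neighbor_mean_matrix(), geom)
        proj = XRayProjection(rng.uniform(0, 2, size=(24, 32)), geom)
        return mesh, model, proj

    def test_zero_initialized_head_returns_init_mesh(self, rng):
        mesh, model, proj = self._setup(rng)
        dvf, out = x_forward(model, proj, mesh)
        assert np.allclose(dvf.d, 0.0)
        assert np.allclose(out.nodes, mesh.nodes)

    def test_refinement_shape_and_determinism(self, rng):
        mesh, model, proj = self._setup(rng)
        for p in model.head.parameters():
            p.data[...] = rng.normal(size=p.data.shape) * 0.01
        d1, m1 = x_forward(model, proj, mesh)
        d2, m2 = x_forward(model, proj, mesh)
        assert d1.d.shape == (mesh.n_nodes, 3)
        assert np.array_equal(m1.nodes, m2.nodes)
        assert np.allclose(m1.nodes, mesh.nodes + d1.d)

    def test_geometry_mismatch_rejected(self, rng):
        mesh, model, _ = self._setup(rng)
        other = ProjectionGeometry(det_shape=(16, 12), gantry_deg=90.0)
        proj = XRayProjection(np.zeros((12, 16)), other)
        with pytest.raises(ValueError):
            model(proj, mesh.nodes)

    def test_node_count_mismatch_rejected(self, rng):
        mesh, model, proj = self._setup(rng)
        with pytest.raises(ValueError):
            model(proj, mesh.nodes[:10])

    def test_whole_mesh_outside_fov_pools_zero_features(self, rng):
        mesh, model, proj = self._setup(rng)
        far = mesh.translated([5000.0, 0.0, 0.0])
        from livertrack.projection import detector_mm_to_pixels, project_nodes
        from livertrack.xnet import perceptual_feature_pool

        uv, fov = project_nodes(far.nodes, proj.geometry)
        assert not fov.any()
        maps = model.stage_maps(model.normalize_projection(proj))
        pooled = perceptual_feature_pool(maps, [2, 4],
                                         detector_mm_to_pixels(uv, proj.geometry),
                                         fov)
        assert np.all(pooled.data == 0.0)
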