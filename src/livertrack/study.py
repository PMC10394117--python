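"""Desk-scale study harness: one synthetic "patient" phantom, its simulated
imaging, the three trained models, and scenario-level evaluation.

This module wires every stage of the framework together the way the full
study is run: build the phantom and its breathing cycle, fit the PCA motion
model, augment motion cases and simulate surface images and cone-beam
projections for them, train the patient-specific surface and x-ray models
and the population biomechanical model, then evaluate tumor localization on
the four held-out test scenario types.  The default :meth:`StudyConfig.small`
configuration is sized to run end to end on a single CPU.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .bionet import (BioRegionWeights, BioUNetConfig, build_bio_unet,
                     decompose_dc_ac, grid_ac, liver_band, train_bio)
from .cascade import VARIANTS, CascadeModels, CascadeResult, run_cascade
from .grid import BoundaryDVF, GridSpec, VolumetricDVF
from .mesh import TriMesh
from .metrics import come, dsc, hd95, mask_surface_points, rmse
from .motion import (TEST_PHASES, TRAIN_PHASES, VALIDATION_PHASES,
                     AugmentedCase, ScenarioSpec, augment_training_set,
                     fit_pca, make_test_scenarios, scenario_field,
                     synthesize_volumetric)
from .phantom import (AnatomyPhantom, MotionParams, PhantomConfig,
                      make_breathing_phases, make_phantom, voxelize,
                      warp_mask, warp_volume)
from .projection import (PhotonNoiseConfig, ProjectionGeometry,
                         XRayProjection, add_photon_noise, raytrace)
from .surface import (BACKGROUND, SurfaceImage, SurfaceNoiseConfig,
                      corrupt_surface, render_surface_image)
from .surfnet import (SurfNet, SurfNetConfig, TrainSchedule, build_surf_net,
                      predict_boundary_dvf, train_surf)
from .elastic import solve_reference_biomechanics
from .xnet import XLossWeights, XNet, XNetConfig, train_x, x_forward

__all__ = ["StudyConfig", "Study"]


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of one end-to-end study."""

    phantom: PhantomConfig = field(default_factory=lambda: PhantomConfig(
        grid=GridSpec.centered(32, 8.0)))
    motion: MotionParams = field(default_factory=MotionParams)
    n_phases: int = 10

    surface_shape: tuple = (64, 64)
    surface_fov: float = 256.0
    surface_noise: SurfaceNoiseConfig = field(default_factory=SurfaceNoiseConfig)

    geometry: ProjectionGeometry = field(default_factory=lambda: ProjectionGeometry(
        det_shape=(96, 72), pixel_pitch=4.139))
    angles: tuple = (0.0,)
    photon: PhotonNoiseConfig = field(default_factory=PhotonNoiseConfig)

    n_train_cases: int = 120
    n_val_cases: int = 40
    onthefly_translation_mm: float = 6.0

    surf_net: SurfNetConfig = field(default_factory=SurfNetConfig)
    surf_epochs: int = 45
    x_net: XNetConfig = field(default_factory=XNetConfig)
    x_epochs: int = 35
    x_weights: XLossWeights = field(default_factory=XLossWeights)

    bio_grid_shape: int = 16
    bio_spacing: float = 7.0
    bio_net: BioUNetConfig = None
    bio_epochs: int = 30
    bio_n_phantoms: int = 4
    bio_cases_per_phantom: int = 28
    bio_boundary_noise_mm: float = 1.0

    n_type1_per_phase: int = 5

    def resolved_bio_net(self) -> BioUNetConfig:
        if self.bio_net is not None:
            return self.bio_net
        return BioUNetConfig(grid_shape=(self.bio_grid_shape,) * 3, depth=3)

    @classmethod
    def small(cls) -> "StudyConfig":
        """The CPU-scale configuration used by the test suite."""
        return cls()

    @classmethod
    def tiny(cls) -> "StudyConfig":
        """A minutes-scale smoke configuration (for examples and quick runs)."""
        return cls(n_train_cases=48, n_val_cases=16, surf_epochs=12,
                   x_epochs=8, bio_epochs=8, bio_n_phantoms=2,
                   bio_cases_per_phantom=12, n_type1_per_phase=2)


@dataclass
class _SurfCase:
    """One simulated motion case, with everything the loaders need."""

    case: AugmentedCase
    translation: np.ndarray          # baked rigid setup translation, mm
    image: SurfaceImage              # clean current-phase surface image
    target: np.ndarray               # (N, 3) liver boundary DVF, mm
    target_prev: np.ndarray          # targets of the +-1 phase neighbors
    target_next: np.ndarray
    projections: dict = None         # angle -> clean XRayProjection


class Study:
    """Builds, trains, and evaluates one end-to-end desk-scale study.

    Every stage draws from its own child of a single seed sequence, so the
    whole study is reproducible from (config, seed).  Expensive artifacts
    are cached on the instance and built lazily.
    """

    def __init__(self, config: StudyConfig = None, seed: int = 0,
                 verbose: bool = False):
        self.config = config or StudyConfig.small()
        self.seed = int(seed)
        ss = np.random.SeedSequence(self.seed)
        names = ["phantom", "motion", "augment", "surf", "x", "xzero",
                 "bio", "evalnoise", "robust"]
        self._seeds = {n: s for n, s in zip(names, ss.spawn(len(names)))}
        self.verbose = verbose
        self._cache = {}
        self.timings = {}

    def _rng(self, name) -> np.random.Generator:
        return np.random.default_rng(self._seeds[name])

    def _int_seed(self, name) -> int:
        return int(self._seeds[name].generate_state(1)[0] % (2 ** 31))

    def _log(self, msg):
        if self.verbose:
            print(f"[study] {msg}", flush=True)

    def _timed(self, key, fn):
        t0 = time.time()
        out = fn()
        self.timings[key] = time.time() - t0
        self._log(f"{key}: {self.timings[key]:.1f} s")
        return out

    # -- anatomy and motion ----------------------------------------------
    @property
    def phantom(self) -> AnatomyPhantom:
        if "phantom" not in self._cache:
            self._cache["phantom"] = make_phantom(self.config.phantom,
                                                  seed=self._int_seed("phantom"))
        return self._cache["phantom"]

    @property
    def phases(self):
        if "phases" not in self._cache:
            self._cache["phases"] = make_breathing_phases(
                self.phantom, self.config.n_phases, self.config.motion,
                seed=self._int_seed("motion"))
        return self._cache["phases"]

    @property
    def pca(self):
        if "pca" not in self._cache:
            ps = self.phases
            self._cache["pca"] = fit_pca(ps.volumetric_dvfs, ps.phases)
        return self._cache["pca"]

    @property
    def prior_surface(self) -> SurfaceImage:
        if "prior_surface" not in self._cache:
            self._cache["prior_surface"] = self._render(np.zeros((1, 3)))
        return self._cache["prior_surface"]

    def _render(self, body_displacement) -> SurfaceImage:
        nodes = self.phantom.body_mesh.nodes + body_displacement
        return render_surface_image(self.phantom.body_mesh.with_nodes(nodes),
                                    shape=self.config.surface_shape,
                                    fov_mm=self.config.surface_fov)

    # -- bio grid ---------------------------------------------------------
    @property
    def bio_grid(self) -> GridSpec:
        if "bio_grid" not in self._cache:
            c = self.phantom.liver_mesh.nodes.mean(axis=0)
            n = self.config.bio_grid_shape
            s = self.config.bio_spacing
            origin = tuple(c - (n - 1) * s / 2.0)
            self._cache["bio_grid"] = GridSpec(origin, (s, s, s), (n, n, n))
        return self._cache["bio_grid"]

    @property
    def bio_band(self) -> np.ndarray:
        if "bio_band" not in self._cache:
            mask = voxelize(self.phantom.liver_mesh, self.bio_grid)
            self._cache["liver_mask_bio"] = mask
            self._cache["bio_band"] = liver_band(mask, self.bio_grid, 10.0)
        return self._cache["bio_band"]

    @property
    def prior_tumor_mask(self) -> np.ndarray:
        if "tumor_mask_bio" not in self._cache:
            self._cache["tumor_mask_bio"] = voxelize(self.phantom.tumor_mesh,
                                                     self.bio_grid)
        return self._cache["tumor_mask_bio"]

    # -- case simulation ---------------------------------------------------
    def _simulate_case(self, case: AugmentedCase, translation, rng,
                       with_projection=True) -> _SurfCase:
        ph = self.phantom
        w = np.asarray(case.coefficients)
        dvf = synthesize_volumetric(self.pca, w, translation=translation)
        body_d = dvf.sample(ph.body_mesh.nodes)
        image = self._render(body_d)
        liver_nodes = ph.liver_mesh.nodes
        target = dvf.sample(liver_nodes)
        # neighbor-phase targets for the internal-external phase mismatch
        labels = self.phases.phases
        i = labels.index(case.phase)
        nbrs = []
        for j in (i - 1, i + 1):
            wp = self.pca.phase_coefficients(labels[j % len(labels)]) * \
                np.asarray(case.scalings)
            nbrs.append(synthesize_volumetric(
                self.pca, wp, translation=translation).sample(liver_nodes))
        projections = None
        if with_projection:
            density = warp_volume(ph.density_volume, dvf)
            projections = {
                a: raytrace(density, ph.grid,
                            replace(self.config.geometry, gantry_deg=a))
                for a in self.config.angles
            }
        return _SurfCase(case, np.asarray(translation, float), image, target,
                         nbrs[0], nbrs[1], projections)

    @property
    def cases(self):
        """(train_cases, val_cases) of simulated :class:`_SurfCase`."""
        if "cases" not in self._cache:
            self._cache["cases"] = self._timed("simulate_cases", self._build_cases)
        return self._cache["cases"]

    def _build_cases(self):
        cfg = self.config
        rng = self._rng("augment")
        seed_aug = self._int_seed("augment")
        train_manifest = augment_training_set(self.pca, TRAIN_PHASES, seed_aug)
        val_manifest = augment_training_set(self.pca, VALIDATION_PHASES,
                                            seed_aug + 1)
        pick_t = rng.choice(len(train_manifest), cfg.n_train_cases, replace=False)
        pick_v = rng.choice(len(val_manifest), cfg.n_val_cases, replace=False)
        a = cfg.onthefly_translation_mm
        train = [self._simulate_case(train_manifest[i],
                                     rng.uniform(-a, a, 3), rng)
                 for i in sorted(pick_t)]
        val = [self._simulate_case(val_manifest[i], rng.uniform(-a, a, 3), rng)
               for i in sorted(pick_v)]
        return train, val

    # -- surface model -----------------------------------------------------
    @property
    def surf_model(self) -> SurfNet:
        if "surf" not in self._cache:
            self._cache["surf"] = self._timed("train_surf", self._train_surf)[0]
        return self._cache["surf"]

    def _shift_image(self, img: SurfaceImage, t3) -> SurfaceImage:
        """Apply a rigid anatomy translation to a heightmap: in-plane shift
        of (LR, SI) and an additive AP offset (exact for the orthographic
        camera)."""
        from .surface import _fill_nearest

        ps = img.pixel_spacing
        filled = np.where(img.foreground, img.heights, np.nan)
        filled = _fill_nearest(filled)
        shift_px = (t3[2] / ps, t3[0] / ps)      # rows = SI, cols = LR
        shifted = ndimage.shift(filled, shift_px, order=1, mode="nearest")
        m = ndimage.shift(img.foreground.astype(float), shift_px, order=1,
                          mode="constant", cval=0.0)
        heights = np.where(m > 0.5, shifted + t3[1], BACKGROUND)
        return SurfaceImage(heights, fov_mm=img.fov_mm, center=img.center)

    def _train_surf(self):
        cfg = self.config
        model = build_surf_net(replace(cfg.surf_net,
                                       input_shape=cfg.surface_shape,
                                       n_nodes=self.phantom.liver_mesh.n_nodes,
                                       seed=self._int_seed("surf")))
        model.set_normalization(self.prior_surface)
        train, val = self.cases
        prior = self.prior_surface
        ncfg = cfg.surface_noise
        extra = cfg.onthefly_translation_mm / 2.0

        def augment(case: _SurfCase, rng):
            img, idx = corrupt_surface((prior, case.image), 1, 3, ncfg, rng)
            tgt = (case.target_prev, case.target, case.target_next)[idx]
            t2 = rng.uniform(-extra, extra, 3)
            img = self._shift_image(img, t2)
            return model.normalize(img), tgt + t2

        val_pairs = [(model.normalize(c.image), c.target) for c in val]
        sched = TrainSchedule(epochs=cfg.surf_epochs)
        return train_surf(model, train, val_pairs, sched,
                          seed=self._int_seed("surf"), augment=augment,
                          verbose=self.verbose)

    # -- x-ray model -------------------------------------------------------
    def x_model(self, angle: float, init: str = "surf") -> XNet:
        key = ("x", angle, init)
        if key not in self._cache:
            self._cache[key] = self._timed(
                f"train_x[{angle}deg,{init}]",
                lambda: self._train_x(angle, init))[0]
        return self._cache[key]

    def _train_x(self, angle, init):
        cfg = self.config
        geom = replace(cfg.geometry, gantry_deg=angle)
        nbm = self.phantom.liver_mesh.neighbor_mean_matrix()
        seed_name = "x" if init == "surf" else "xzero"
        model = XNet(replace(cfg.x_net, seed=self._int_seed(seed_name)),
                     nbm, geom)
        train, val = self.cases
        prior_nodes = self.phantom.liver_mesh.nodes

        def init_nodes(case):
            if init == "zero":
                return prior_nodes
            pred = predict_boundary_dvf(self.surf_model, case.image)
            return prior_nodes + pred.d

        def pack(case):
            return (case.projections[angle], init_nodes(case),
                    prior_nodes + case.target)

        train_cases = [pack(c) for c in train]
        val_cases = [pack(c) for c in val]
        noise = lambda proj, rng: add_photon_noise(proj, cfg.photon, rng)
        sched = TrainSchedule(epochs=cfg.x_epochs, step_size=30,
                              weight_decay=0.0, batch_size=8)
        return train_x(model, train_cases, val_cases, sched,
                       seed=self._int_seed(seed_name), weights=cfg.x_weights,
                       noise_fn=noise, verbose=self.verbose)

    # -- biomechanical model -------------------------------------------------
    @property
    def bio_model(self):
        if "bio" not in self._cache:
            self._cache["bio"] = self._timed("train_bio", self._train_bio)[0]
        return self._cache["bio"]

    def _train_bio(self):
        cfg = self.config
        rng = self._rng("bio")
        seed0 = self._int_seed("bio")
        cases, ids = [], []
        for k in range(cfg.bio_n_phantoms):
            pid = seed0 + 1 + k          # distinct from this study's phantom
            phantom = make_phantom(cfg.phantom, seed=pid)
            phases = make_breathing_phases(phantom, cfg.n_phases, cfg.motion,
                                           seed=pid)
            liver = phantom.liver_mesh
            center = liver.nodes.mean(axis=0)
            n, s = cfg.bio_grid_shape, cfg.bio_spacing
            grid = GridSpec(tuple(center - (n - 1) * s / 2.0),
                            (s, s, s), (n, n, n))
            mask = voxelize(liver, grid)
            band = liver_band(mask, grid, 10.0)
            pca = fit_pca(phases.volumetric_dvfs, phases.phases)
            for _ in range(cfg.bio_cases_per_phantom):
                phase = rng.choice(TRAIN_PHASES + VALIDATION_PHASES)
                s4 = np.array([rng.uniform(*r) for r in
                               ((0.95, 1.05), (-1.5, 3.0), (-1.5, 3.0),
                                (-1.5, 1.5))])
                w = pca.phase_coefficients(phase) * s4
                t = rng.uniform(-cfg.onthefly_translation_mm,
                                cfg.onthefly_translation_mm, 3)
                bdvf = BoundaryDVF(
                    synthesize_volumetric(pca, w, translation=t).sample(liver.nodes))
                dec = decompose_dc_ac(bdvf)
                ac_vol = grid_ac(dec.ac, liver, grid, band=band)
                target = solve_reference_biomechanics(mask, dec.ac, liver, grid)
                cases.append((ac_vol, target, band))
                ids.append(pid)
        n_val = max(len(cases) // 5, 1)
        order = rng.permutation(len(cases))
        val = [cases[i] for i in order[:n_val]]
        train = [cases[i] for i in order[n_val:]]
        model = build_bio_unet(replace(self.config.resolved_bio_net(),
                                       seed=seed0))
        sched = TrainSchedule(epochs=cfg.bio_epochs, plateau_factor=0.9,
                              plateau_patience=10, weight_decay=0.0,
                              batch_size=8)
        return train_bio(model, train, val, sched, seed=seed0,
                         boundary_noise_mm=cfg.bio_boundary_noise_mm,
                         train_ids=ids, test_ids=[self._int_seed("phantom")],
                         verbose=self.verbose)

    # -- assembled cascade ---------------------------------------------------
    def models(self, angles=None, with_zero=True) -> CascadeModels:
        angles = tuple(angles) if angles is not None else self.config.angles
        return CascadeModels(
            surf=self.surf_model,
            x_models={a: self.x_model(a, "surf") for a in angles},
            x_zero_models={a: self.x_model(a, "zero") for a in angles} if with_zero else {},
            bio=self.bio_model,
            prior_liver=self.phantom.liver_mesh,
            bio_grid=self.bio_grid,
            bio_band=self.bio_band,
            prior_tumor_mask=self.prior_tumor_mask,
        )

    # -- evaluation ------------------------------------------------------------
    def test_scenarios(self, types=(1, 2, 3, 4)):
        if ("scenarios", types) not in self._cache:
            seed = self._int_seed("augment") + 7
            out = []
            for t in types:
                out.extend(make_test_scenarios(
                    self.pca, t, seed + t,
                    n_type1_per_phase=self.config.n_type1_per_phase))
            self._cache[("scenarios", types)] = out
        return self._cache[("scenarios", types)]

    def _scenario_inputs(self, spec: ScenarioSpec, i: int):
        """Simulated on-board inputs and ground truth for one scenario."""
        key = ("scen_in", i)
        if key not in self._cache:
            ph = self.phantom
            dvf = scenario_field(self.pca, spec)
            gt_liver = ph.liver_mesh.nodes + dvf.sample(ph.liver_mesh.nodes)
            image = self._render(dvf.sample(ph.body_mesh.nodes))
            density = warp_volume(ph.density_volume, dvf)
            rng = np.random.default_rng(self._int_seed("evalnoise") + i)
            projections = {}
            for a in self.config.angles:
                clean = raytrace(density, ph.grid,
                                 replace(self.config.geometry, gantry_deg=a))
                projections[a] = add_photon_noise(clean, self.config.photon, rng)
            # ground-truth tumor contour on the bio grid
            crop_field = VolumetricDVF(
                dvf.sample(self.bio_grid.voxel_centers()), self.bio_grid)
            gt_tumor = warp_mask(self.prior_tumor_mask, crop_field)
            self._cache[key] = dict(dvf=dvf, gt_liver=gt_liver, image=image,
                                    projections=projections, gt_tumor=gt_tumor)
        return self._cache[key]

    def _metrics_row(self, spec, inputs, result: CascadeResult, variant,
                     angle) -> dict:
        ph = self.phantom
        gt_mesh = ph.liver_mesh.with_nodes(inputs["gt_liver"])
        pred_mesh = result.deformed_mesh
        S, _ = ph.liver_mesh.subdivision_operator(2.0)
        prior_come = come(self.prior_tumor_mask, inputs["gt_tumor"], self.bio_grid)
        row = dict(
            scenario_type=spec.scenario_type, phase=spec.phase,
            translation_mm=float(np.linalg.norm(spec.translation)),
            variant=variant, angle=angle,
            liver_rmse=rmse(pred_mesh, gt_mesh),
            liver_hd95=hd95(S @ pred_mesh.nodes, S @ gt_mesh.nodes),
            tumor_come=come(result.tumor_mask, inputs["gt_tumor"], self.bio_grid),
            tumor_dsc=dsc(result.tumor_mask, inputs["gt_tumor"]),
            tumor_hd95=hd95(mask_surface_points(result.tumor_mask, self.bio_grid),
                            mask_surface_points(inputs["gt_tumor"], self.bio_grid)),
            prior_come=prior_come,
            large_motion=prior_come > 10.0,
        )
        return row

    def evaluate(self, variants=VARIANTS, types=(1, 2, 3, 4), angles=None,
                 isocenter_offset_mm: float = 0.0,
                 offset_rng=None) -> pd.DataFrame:
        """Run the cascade variants over the test scenarios.

        Returns a tidy table with one row per (scenario, angle, variant),
        including the no-registration prior row and the prior-COME
        stratification flag (the 10 mm small/large-motion split).  A nonzero
        ``isocenter_offset_mm`` applies the miscalibration protocol: a
        random fixed-norm shift added to the surface prediction before the
        x-ray stage.
        """
        angles = tuple(angles) if angles is not None else self.config.angles
        if isocenter_offset_mm < 0:
            raise ValueError("iso-center offset magnitude must be >= 0")
        models = self.models(angles,
                             with_zero=("x-bio" in variants))
        rows = []
        scen = self.test_scenarios(types)
        for i, spec in enumerate(scen):
            inputs = self._scenario_inputs(spec, i)
            for a in angles:
                for variant in variants:
                    offset = None
                    if isocenter_offset_mm > 0 and variant == "surf-x-bio":
                        v = offset_rng.normal(size=3)
                        offset = v / np.linalg.norm(v) * isocenter_offset_mm
                    result = run_cascade(inputs["image"],
                                         inputs["projections"][a],
                                         self.phantom.liver_mesh, models,
                                         variant=variant,
                                         isocenter_offset=offset)
                    row = self._metrics_row(spec, inputs, result, variant, a)
                    row["isocenter_offset_mm"] = isocenter_offset_mm
                    row["offset_norm"] = (float(np.linalg.norm(offset))
                                          if offset is not None else 0.0)
                    rows.append(row)
        return pd.DataFrame(rows)

    def robustness(self, offsets=(0.0, 1.0, 2.0), types=(2, 3, 4),
                   angles=None) -> pd.DataFrame:
        """Iso-center miscalibration test of the full cascade.

        For each test case a random 3-D unit direction scaled to the fixed
        offset magnitude is added to the surface-predicted displacement
        before the x-ray refiner; returns the concatenated metric tables.
        """
        out = []
        for mag in offsets:
            rng = np.random.default_rng(self._int_seed("robust") + int(mag * 100))
            out.append(self.evaluate(("surf-x-bio",), types=types,
                                     angles=angles,
                                     isocenter_offset_mm=float(mag),
                                     offset_rng=rng))
        return pd.concat(out, ignore_index=True)
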