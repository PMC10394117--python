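"""Synthetic deformable liver anatomy and its breathing phases.

A desk-scale stand-in for a respiration-resolved patient CT study: an
ellipsoidal torso with a seeded, slightly irregular surface, an embedded
ellipsoidal liver carrying a low-contrast tumor, and a smooth cyclic motion
model whose superior-inferior component dominates, as respiratory liver motion
does.  The liver and tumor meshes keep fixed node counts so deformed phases
stay in one-to-one node correspondence with the reference phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .grid import BoundaryDVF, GridError, GridSpec, VolumetricDVF
from .mesh import MeshError, TriMesh, icosphere

__all__ = [
    "ConfigurationError",
    "PhantomConfig",
    "MotionParams",
    "AnatomyPhantom",
    "PhaseSet",
    "make_phantom",
    "make_breathing_phases",
    "voxelize",
    "warp_mask",
    "invert_dvf",
]

LABEL_BACKGROUND, LABEL_BODY, LABEL_LIVER, LABEL_TUMOR = 0, 1, 2, 3


class ConfigurationError(ValueError):
    """Raised for physically impossible phantom or motion configurations."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and attenuation of the synthetic anatomy.

    Lengths in mm; attenuation coefficients in 1/mm (a water-like stand-in,
    not calibrated Hounsfield units).  The tumor attenuation stays within 2 %
    of the liver's: the tumor is deliberately near-invisible in projections.
    """

    body_half_axes: tuple = (110.0, 85.0, 120.0)
    body_subdivisions: int = 3
    body_shape_jitter: float = 0.03       # relative radial irregularity
    liver_center: tuple = (-30.0, 0.0, 10.0)
    liver_radius: float = 40.0
    liver_scale: tuple = (1.15, 0.9, 1.0)
    liver_subdivisions: int = 2           # 162 nodes; 3 -> 642
    tumor_diameter: float = 20.0
    tumor_offset: tuple = (8.0, 4.0, -4.0)  # relative to liver center
    tumor_subdivisions: int = 1
    mu_body: float = 0.020
    mu_liver: float = 0.024
    mu_tumor: float = 0.0244              # +1.7 % vs liver: low contrast
    grid: GridSpec = field(default_factory=lambda: GridSpec.centered(64, 4.0))


@dataclass(frozen=True)
class MotionParams:
    """Peak breathing amplitudes (mm) and surface-liver coupling.

    Defaults follow reported liver-tumor motion ranges: SI ~15 mm dominates,
    AP ~7 mm, LR ~3 mm.  ``correlation`` < 1 mixes an independent mode into
    the body-surface motion only, weakening the internal-external coupling
    the surface regressor has to learn.
    """

    amplitude_lr: float = 3.0
    amplitude_ap: float = 7.0
    amplitude_si: float = 15.0
    correlation: float = 1.0
    phase_jitter: float = 0.05


@dataclass
class AnatomyPhantom:
    body_mesh: TriMesh
    liver_mesh: TriMesh
    tumor_mesh: TriMesh
    density_volume: np.ndarray   # attenuation, 1/mm
    label_volume: np.ndarray     # {0 bg, 1 body, 2 liver, 3 tumor}
    grid: GridSpec
    config: PhantomConfig = None

    def mask(self, label: int) -> np.ndarray:
        """Binary mask of a label *and* everything nested inside it."""
        return self.label_volume >= label


@dataclass
class PhaseSet:
    """Breathing phases: labels plus displacement fields relative to phase 0%.

    Phase 0% is the reference (end-of-inhale) phase; its fields are exactly
    zero.  ``volumetric_dvfs`` are the ground truth used for mask warping;
    boundary fields are the same motion sampled at mesh nodes.
    """

    phases: list                      # e.g. ['0%', '10%', ..., '90%']
    boundary_dvfs: list               # liver BoundaryDVF per phase
    body_dvfs: list                   # body-surface BoundaryDVF per phase
    volumetric_dvfs: list             # VolumetricDVF per phase

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def index(self, phase: str) -> int:
        return self.phases.index(phase)


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def _bumpy_icosphere(subdivisions, radius, center, scale, jitter, rng):
    """Icosphere with a smooth seeded radial perturbation (distinct 'patients')."""
    mesh = icosphere(subdivisions, radius=1.0)
    nodes = mesh.nodes  # unit sphere
    if jitter > 0:
        # superpose a few random low-frequency cosine waves over directions
        r = np.ones(len(nodes))
        for _ in range(4):
            k = rng.normal(size=3)
            k *= rng.uniform(1.0, 2.5) / np.linalg.norm(k)
            phase = rng.uniform(0, 2 * np.pi)
            r += jitter * rng.uniform(0.3, 1.0) * np.cos(nodes @ k * np.pi + phase)
        nodes = nodes * r[:, None]
    nodes = nodes * (np.asarray(scale, float) * radius) + np.asarray(center, float)
    return TriMesh(nodes, mesh.faces)


def make_phantom(config: PhantomConfig = None, seed: int = 0) -> AnatomyPhantom:
    """Build the deformable anatomy phantom (body, liver, embedded tumor).

    Deterministic given ``seed``; the seed perturbs the body and liver shapes
    so a population of distinct phantoms can be generated for the
    population-trained interior-motion model.
    """
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(seed)

    body = _bumpy_icosphere(cfg.body_subdivisions, 1.0, (0, 0, 0),
                            cfg.body_half_axes, cfg.body_shape_jitter, rng)
    liver = _bumpy_icosphere(cfg.liver_subdivisions, cfg.liver_radius,
                             cfg.liver_center, cfg.liver_scale,
                             0.4 * cfg.body_shape_jitter, rng)
    if cfg.tumor_diameter <= 0:
        raise ConfigurationError("tumor_diameter must be positive")
    tumor = icosphere(cfg.tumor_subdivisions, radius=cfg.tumor_diameter / 2.0,
                      center=np.asarray(cfg.liver_center) + np.asarray(cfg.tumor_offset))

    # containment checks on the analytic shapes (strict, with a small margin)
    semi = np.asarray(cfg.liver_scale) * cfg.liver_radius
    rel = (tumor.nodes - np.asarray(cfg.liver_center)) / (0.97 * semi)
    if np.any((rel ** 2).sum(axis=1) >= 1.0):
        raise ConfigurationError("tumor placement is not strictly inside the liver")
    rel_l = liver.nodes / (0.97 * np.asarray(cfg.body_half_axes))
    if np.any((rel_l ** 2).sum(axis=1) >= 1.0):
        raise ConfigurationError("liver is not strictly inside the body")
    if abs(cfg.mu_tumor - cfg.mu_liver) > 0.02 * cfg.mu_liver + 1e-12:
        raise ConfigurationError("tumor attenuation must be within 2% of liver")

    body_mask = voxelize(body, cfg.grid)
    liver_mask = voxelize(liver, cfg.grid)
    tumor_mask = voxelize(tumor, cfg.grid)

    label = np.zeros(cfg.grid.shape, dtype=np.uint8)
    label[body_mask] = LABEL_BODY
    label[liver_mask] = LABEL_LIVER
    label[tumor_mask] = LABEL_TUMOR
    density = np.zeros(cfg.grid.shape, dtype=np.float64)
    density[body_mask] = cfg.mu_body
    density[liver_mask] = cfg.mu_liver
    density[tumor_mask] = cfg.mu_tumor

    return AnatomyPhantom(body, liver, tumor, density, label, cfg.grid, cfg)


# ---------------------------------------------------------------------------
# voxelization: parity rasterization along the SI axis
# ---------------------------------------------------------------------------

def voxelize(mesh: TriMesh, grid: GridSpec) -> np.ndarray:
    """Binary mask: voxel is 1 iff its center lies inside the closed mesh.

    Crossing-parity rasterization: every triangle deposits its SI-axis
    intersection into per-pixel crossing counters; a voxel center is inside
    when an odd number of surface crossings lies below it.
    """
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise MeshError("voxelize requires a watertight (closed) mesh")
    ax_x, ax_y, ax_z = grid.axes()
    nx, ny, nz = grid.shape
    # tiny irrational offset avoids rays hitting mesh edges/vertices exactly
    eps = 1.2345678e-6 * max(grid.spacing)
    sx, sy = ax_x + eps, ax_y + 2.0 * eps

    crossings = np.zeros((nx, ny, nz + 1), dtype=np.int64)
    tri = mesh.nodes[mesh.faces]  # (F, 3, 3)
    for v in tri:
        x0, y0 = v[:, 0], v[:, 1]
        i0 = np.searchsorted(sx, x0.min())
        i1 = np.searchsorted(sx, x0.max(), side="right")
        j0 = np.searchsorted(sy, y0.min())
        j1 = np.searchsorted(sy, y0.max(), side="right")
        if i0 >= i1 or j0 >= j1:
            continue
        px, py = np.meshgrid(sx[i0:i1], sy[j0:j1], indexing="ij")
        # 2-D barycentric coordinates of the pixel centers
        d = (y0[1] - y0[2]) * (x0[0] - x0[2]) + (x0[2] - x0[1]) * (y0[0] - y0[2])
        if abs(d) < 1e-12:
            continue  # triangle vertical in SI: zero projected area
        l0 = ((y0[1] - y0[2]) * (px - x0[2]) + (x0[2] - x0[1]) * (py - y0[2])) / d
        l1 = ((y0[2] - y0[0]) * (px - x0[2]) + (x0[0] - x0[2]) * (py - y0[2])) / d
        l2 = 1.0 - l0 - l1
        inside = (l0 >= 0) & (l1 >= 0) & (l2 >= 0)
        if not inside.any():
            continue
        zi = l0 * v[0, 2] + l1 * v[1, 2] + l2 * v[2, 2]
        ii, jj = np.nonzero(inside)
        kk = np.searchsorted(ax_z, zi[ii, jj], side="right")
        np.add.at(crossings, (ii + i0, jj + j0, kk), 1)

    below = np.cumsum(crossings[:, :, :nz], axis=2)
    return (below % 2) == 1


# ---------------------------------------------------------------------------
# mask warping (contour propagation)
# ---------------------------------------------------------------------------

def invert_dvf(dvf: VolumetricDVF, n_iter: int = 10) -> VolumetricDVF:
    """Approximate inverse displacement by fixed-point iteration.

    Solves psi(x) = -D(x + psi(x)); accurate for smooth fields whose spatial
    gradient is well below 1.
    """
    spacing = np.array(dvf.grid.spacing)
    centers = dvf.grid.voxel_centers()
    psi = np.zeros_like(dvf.field)
    for _ in range(n_iter):
        psi = -dvf.sample(centers + psi)
    return VolumetricDVF(psi, dvf.grid)


def warp_mask(mask: np.ndarray, dvf: VolumetricDVF, n_iter: int = 10) -> np.ndarray:
    """Propagate a binary mask along a forward (prior -> target) field.

    Backward warping with the numerically inverted field: the warped value at
    x is the prior mask sampled at x + D^{-1}(x), trilinear, thresholded at
    0.5.  Exact for integer-voxel rigid translations.
    """
    mask = np.asarray(mask)
    if mask.shape != tuple(dvf.grid.shape):
        raise GridError("mask and DVF must live on the same grid")
    psi = invert_dvf(dvf, n_iter=n_iter)
    idx = dvf.grid.world_to_index(dvf.grid.voxel_centers() + psi.field)
    vals = map_coordinates(mask.astype(np.float64), np.moveaxis(idx, -1, 0),
                           order=1, mode="constant", cval=0.0)
    return vals > 0.5


def warp_volume(volume: np.ndarray, dvf: VolumetricDVF, n_iter: int = 10,
                cval: float = 0.0) -> np.ndarray:
    """Like :func:`warp_mask` but for continuous volumes (no thresholding)."""
    if volume.shape != tuple(dvf.grid.shape):
        raise GridError("volume and DVF must live on the same grid")
    psi = invert_dvf(dvf, n_iter=n_iter)
    idx = dvf.grid.world_to_index(dvf.grid.voxel_centers() + psi.field)
    return map_coordinates(volume.astype(np.float64), np.moveaxis(idx, -1, 0),
                           order=1, mode="constant", cval=cval)


# ---------------------------------------------------------------------------
# breathing motion
# ---------------------------------------------------------------------------

class _AnalyticMotion:
    """Smooth cyclic displacement field built from three spatial modes.

    Mode 1: SI-dominant bulk motion weighted by a broad Gaussian centered
    near the liver, plus an anterior chest-rise AP term.  Mode 2 and 3 are
    weaker, spatially shifted modes driven out of phase with mode 1, giving
    the cycle hysteresis and a rank-3 structure for the PCA motion model.
    """

    def __init__(self, cfg: PhantomConfig, params: MotionParams, rng):
        c = np.asarray(cfg.liver_center, float)
        jitter = lambda s: rng.normal(0.0, s, size=3)
        self.centers = [c + jitter(8.0), c + np.array([20, 10, -30]) + jitter(8.0),
                        c + np.array([-15, -20, 25]) + jitter(8.0)]
        self.sigmas = [np.array([180.0, 150.0, 220.0]),
                       np.array([140.0, 120.0, 160.0]),
                       np.array([120.0, 140.0, 150.0])]
        self.dirs = [np.array([0.12, 0.35, 1.0]),
                     np.array([0.25, 0.6, 0.45]),
                     np.array([1.0, 0.3, 0.35])]
        self.dirs = [d / np.linalg.norm(d) for d in self.dirs]
        self.mode_amp = np.array([1.0, 0.35, 0.18])
        # anterior chest-rise profile parameters (AP ramp)
        self.ap_mid = 0.0
        self.ap_width = cfg.body_half_axes[1]
        self.params = params
        self.cfg = cfg
        self.jit = params.phase_jitter

    def coefficients(self, n_phases: int, rng):
        """Per-phase drive of the three modes; exactly zero at phase 0."""
        t = np.arange(n_phases)
        phi = 2.0 * np.pi * t / n_phases
        a = 0.5 * (1.0 - np.cos(phi))
        b = np.sin(phi) * 0.5 * (1.0 - np.cos(phi))
        c = 0.25 * (1.0 - np.cos(2.0 * phi)) * np.sign(np.sin(phi) + 1e-30)
        coeff = np.stack([a, b, c], axis=1) * self.mode_amp
        if self.jit > 0:
            coeff = coeff * (1.0 + self.jit * rng.standard_normal(coeff.shape))
        coeff[0] = 0.0  # phase 0% is the reference: identically zero
        return coeff

    def raw_field(self, points: np.ndarray, coeff_row) -> np.ndarray:
        """Unscaled displacement at world points for one phase."""
        p = points.reshape(-1, 3)
        out = np.zeros_like(p)
        for w, c0, sg, d in zip(coeff_row, self.centers, self.sigmas, self.dirs):
            if w == 0.0:
                continue
            g = np.exp(-0.5 * (((p - c0) / sg) ** 2).sum(axis=1))
            out += w * g[:, None] * d
        # chest rise: AP displacement grows toward the anterior surface
        ramp = np.clip((p[:, 1] - (self.ap_mid - self.ap_width)) /
                       (2.0 * self.ap_width), 0.0, 1.0)
        out[:, 1] += coeff_row[0] * 0.5 * ramp
        return out.reshape(points.shape)


def make_breathing_phases(phantom: AnatomyPhantom, n_phases: int = 10,
                          motion_params: MotionParams = None,
                          seed: int = 0) -> PhaseSet:
    """Generate smooth cyclic breathing phases for a phantom.

    Per-component amplitudes are normalized so the maximum liver-node
    displacement over the cycle equals the configured peak in each axis
    (SI >= AP >= LR by default).  Body-surface motion is driven by the same
    field, so a surface-to-liver mapping exists to be learned; with
    ``correlation < 1`` an independent seeded mode degrades that coupling.
    Deterministic given ``seed``.
    """
    params = motion_params or MotionParams()
    amps = np.array([params.amplitude_lr, params.amplitude_ap, params.amplitude_si])
    if np.any(amps < 0):
        raise ConfigurationError("motion amplitudes must be non-negative")
    if n_phases < 2:
        raise ConfigurationError("need at least 2 phases")
    rng = np.random.default_rng(seed)
    motion = _AnalyticMotion(phantom.config or PhantomConfig(), params, rng)
    coeff = motion.coefficients(n_phases, rng)

    liver_nodes = phantom.liver_mesh.nodes
    raw_liver = np.stack([motion.raw_field(liver_nodes, c) for c in coeff])
    peak = np.abs(raw_liver).max(axis=(0, 1))          # per-component raw peak
    scale = np.where(peak > 1e-12, amps / np.maximum(peak, 1e-12), 0.0)

    body_nodes = phantom.body_mesh.nodes
    centers = phantom.grid.voxel_centers()

    decouple = None
    if params.correlation < 1.0:
        # independent surface-only mode (breaks internal-external correlation)
        k = rng.normal(size=3)
        k /= np.linalg.norm(k)
        phase_drive = rng.standard_normal(n_phases)
        phase_drive[0] = 0.0
        decouple = (k, phase_drive)

    phases, b_dvfs, s_dvfs, v_dvfs = [], [], [], []
    for t in range(n_phases):
        phases.append(f"{t * 100 // n_phases}%")
        dl = motion.raw_field(liver_nodes, coeff[t]) * scale
        db = motion.raw_field(body_nodes, coeff[t]) * scale
        dv = motion.raw_field(centers, coeff[t]) * scale
        if decouple is not None:
            k, drive = decouple
            extra = (1.0 - params.correlation) * amps * 0.5
            db = db + drive[t] * extra * k
        b_dvfs.append(BoundaryDVF(dl, mesh_ref="liver"))
        s_dvfs.append(BoundaryDVF(db, mesh_ref="body"))
        v_dvfs.append(VolumetricDVF(dv, phantom.grid))
    return PhaseSet(phases, b_dvfs, s_dvfs, v_dvfs)
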