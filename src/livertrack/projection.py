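"""Cone-beam x-ray projection simulation.

Exact radiological path lengths through the voxel grid are computed with a
Siddon-style traversal (all voxel-boundary plane crossings along each ray,
merged and sorted), vectorized over detector pixels.  Photon statistics
follow the compound Poisson + Gaussian model of quantum and electronic
detector noise.

Geometry convention: the gantry rotates about the SI axis; at 0 degrees the
source is anterior of the patient (AP view) and the detector u-axis points
to the patient's left; at 90 degrees the beam enters from the patient's left
(left-lateral view).  The detector v-axis always points superior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .grid import GridSpec
from .mesh import TriMesh

__all__ = [
    "ProjectionGeometry",
    "XRayProjection",
    "PhotonNoiseConfig",
    "raytrace",
    "add_photon_noise",
    "project_nodes",
]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Source/detector layout of the on-board imager.

    SAD/SDD default to the conventional LINAC on-board imager values; the
    detector defaults to 512 x 384 pixels at 0.776 mm pitch.
    """

    sad: float = 1000.0               # source-axis distance, mm
    sdd: float = 1500.0               # source-detector distance, mm
    gantry_deg: float = 0.0           # 0 = AP view, 90 = left-lateral
    det_shape: tuple = (512, 384)     # (n_u, n_v) pixels
    pixel_pitch: float = 0.776        # mm

    def __post_init__(self):
        if not (self.sdd > self.sad > 0):
            raise ValueError("geometry requires SDD > SAD > 0")
        if not (0.0 <= self.gantry_deg < 360.0):
            raise ValueError("gantry angle must be in [0, 360)")

    # -- frame vectors ----------------------------------------------------
    @property
    def source(self) -> np.ndarray:
        th = np.deg2rad(self.gantry_deg)
        return np.array([self.sad * np.sin(th), self.sad * np.cos(th), 0.0])

    @property
    def beam_axis(self) -> np.ndarray:
        """Unit vector from source through the iso-center."""
        s = self.source
        return -s / np.linalg.norm(s)

    @property
    def u_axis(self) -> np.ndarray:
        th = np.deg2rad(self.gantry_deg)
        return np.array([np.cos(th), -np.sin(th), 0.0])

    @property
    def v_axis(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])

    @property
    def detector_center(self) -> np.ndarray:
        return self.source + self.beam_axis * self.sdd

    def pixel_positions(self) -> np.ndarray:
        """(n_v, n_u, 3) world coordinates of detector pixel centers."""
        nu, nv = self.det_shape
        us = (np.arange(nu) - (nu - 1) / 2.0) * self.pixel_pitch
        vs = (np.arange(nv) - (nv - 1) / 2.0) * self.pixel_pitch
        c, u, v = self.detector_center, self.u_axis, self.v_axis
        return (c[None, None, :]
                + vs[:, None, None] * v[None, None, :]
                + us[None, :, None] * u[None, None, :])

    def detector_half_extent(self):
        nu, nv = self.det_shape
        return nu * self.pixel_pitch / 2.0, nv * self.pixel_pitch / 2.0


@dataclass(frozen=True)
class PhotonNoiseConfig:
    """Photon fluence and electronic noise of the detector model."""

    mean_photons: float = 1.0e5       # I0 per pixel (unattenuated)
    electronic_sd: float = 10.0       # Gaussian sd, photons

    def __post_init__(self):
        if self.mean_photons <= 0 or self.electronic_sd < 0:
            raise ValueError("invalid photon-noise configuration")


@dataclass
class XRayProjection:
    """Line-integral image (n_v, n_u), dimensionless, row = v (superior up).

    ``noisy_counts`` holds the photon-count realization when noise has been
    applied; ``line_integrals`` is then the log-recovered noisy attenuation.
    """

    line_integrals: np.ndarray
    geometry: ProjectionGeometry
    noisy_counts: np.ndarray = None

    def __post_init__(self):
        self.line_integrals = np.asarray(self.line_integrals, dtype=np.float64)
        nv_nu = (self.geometry.det_shape[1], self.geometry.det_shape[0])
        if self.line_integrals.shape != nv_nu:
            raise ValueError(
                f"projection shape {self.line_integrals.shape} != {nv_nu}"
            )


# ---------------------------------------------------------------------------
# ray tracing
# ---------------------------------------------------------------------------

def raytrace(volume: np.ndarray, grid: GridSpec,
             geometry: ProjectionGeometry,
             chunk: int = 8192) -> XRayProjection:
    """Exact line integrals of the attenuation volume over all detector rays.

    For each ray the parametric positions of every voxel-face crossing within
    the grid bounding box are merged and sorted; each resulting segment
    contributes (segment length) * mu(voxel at segment midpoint).
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.shape != tuple(grid.shape):
        raise ValueError("volume does not match the grid")
    src = geometry.source
    pix = geometry.pixel_positions().reshape(-1, 3)
    lo, hi = grid.bounds()
    spacing = np.array(grid.spacing)

    out = np.zeros(pix.shape[0])
    planes = [lo[k] + spacing[k] * np.arange(grid.shape[k] + 1) for k in range(3)]

    for start in range(0, pix.shape[0], chunk):
        p = pix[start:start + chunk]
        d = p - src                                   # (n, 3)
        n = p.shape[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = (lo - src) / d
            t_hi = (hi - src) / d
        t_min = np.where(np.abs(d) > 1e-12, np.minimum(t_lo, t_hi), -np.inf)
        t_max = np.where(np.abs(d) > 1e-12, np.maximum(t_lo, t_hi), np.inf)
        # rays parallel to an axis but outside that slab never intersect
        outside = (np.abs(d) <= 1e-12) & ((src < lo) | (src > hi))
        a0 = np.maximum(t_min.max(axis=1), 0.0)
        a1 = np.minimum(t_max.min(axis=1), 1.0)
        a1 = np.where(outside.any(axis=1), a0, a1)
        valid = a1 > a0
        if not valid.any():
            continue

        alphas = []
        for k in range(3):
            with np.errstate(divide="ignore", invalid="ignore"):
                a = (planes[k][None, :] - src[k]) / d[:, k:k + 1]
            a = np.where(np.abs(d[:, k:k + 1]) > 1e-12, a, np.nan)
            alphas.append(a)
        a = np.concatenate(alphas, axis=1)
        a = np.clip(a, a0[:, None], a1[:, None])
        a = np.where(np.isnan(a), a0[:, None], a)
        a = np.sort(a, axis=1)
        seg = np.diff(a, axis=1)                      # (n, K-1)
        mid = 0.5 * (a[:, 1:] + a[:, :-1])
        pts = src[None, None, :] + mid[:, :, None] * d[:, None, :]
        idx = np.floor((pts - lo) / spacing).astype(np.int64)
        ok = (seg > 1e-12) & np.all((idx >= 0) &
                                    (idx < np.array(grid.shape)), axis=2)
        idx = np.clip(idx, 0, np.array(grid.shape) - 1)
        mu = volume[idx[..., 0], idx[..., 1], idx[..., 2]]
        ray_len = np.linalg.norm(d, axis=1)
        out[start:start + n] = (np.where(ok, mu * seg, 0.0).sum(axis=1)
                                * ray_len * valid)

    nv, nu = geometry.det_shape[1], geometry.det_shape[0]
    img = out.reshape(nv, nu)
    if img.max() == 0.0:
        warnings.warn("no ray intersected the attenuating volume")
    return XRayProjection(img, geometry)


# ---------------------------------------------------------------------------
# photon / electronic noise
# ---------------------------------------------------------------------------

def add_photon_noise(projection: XRayProjection, cfg: PhotonNoiseConfig,
                     rng) -> XRayProjection:
    """Poisson quantum noise plus Gaussian electronic noise.

    counts = Poisson(I0 * exp(-line_integral)) + N(0, sd), clipped at zero
    and rounded; the noisy line integrals are -ln(max(counts, 1) / I0).
    Bit-reproducible for a given seeded generator.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    li = projection.line_integrals
    expected = cfg.mean_photons * np.exp(-li)
    counts = rng.poisson(expected).astype(np.float64)
    if cfg.electronic_sd > 0:
        counts = counts + rng.normal(0.0, cfg.electronic_sd, size=counts.shape)
    counts = np.clip(np.rint(counts), 0, None)
    noisy_li = -np.log(np.maximum(counts, 1.0) / cfg.mean_photons)
    return XRayProjection(noisy_li, projection.geometry, noisy_counts=counts)


# ---------------------------------------------------------------------------
# node projection
# ---------------------------------------------------------------------------

def project_nodes(mesh_or_nodes, geometry: ProjectionGeometry):
    """Perspective projection of mesh nodes onto the detector.

    Returns ``(uv_mm, in_fov)`` where ``uv_mm`` is (N, 2) detector
    coordinates in mm relative to the detector center (u to patient left at
    0 degrees, v superior) and ``in_fov`` flags nodes projecting inside the
    detector extent; nodes at or behind the source are flagged out of FOV.
    """
    nodes = mesh_or_nodes.nodes if isinstance(mesh_or_nodes, TriMesh) else np.asarray(mesh_or_nodes, float)
    s = geometry.source
    w = geometry.beam_axis
    u, v = geometry.u_axis, geometry.v_axis
    rel = nodes - s
    depth = rel @ w                               # distance along beam axis
    safe = depth > 1e-6
    mag = np.where(safe, geometry.sdd / np.where(safe, depth, 1.0), 0.0)
    uv = np.stack([(rel @ u) * mag, (rel @ v) * mag], axis=1)
    half_u, half_v = geometry.detector_half_extent()
    in_fov = safe & (np.abs(uv[:, 0]) <= half_u) & (np.abs(uv[:, 1]) <= half_v)
    return uv, in_fov


def detector_mm_to_pixels(uv_mm: np.ndarray, geometry: ProjectionGeometry):
    """Convert detector mm offsets to fractional (row=v, col=u) pixel indices."""
    nu, nv = geometry.det_shape
    col = uv_mm[:, 0] / geometry.pixel_pitch + (nu - 1) / 2.0
    row = uv_mm[:, 1] / geometry.pixel_pitch + (nv - 1) / 2.0
    return np.stack([row, col], axis=1)
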