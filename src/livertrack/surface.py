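"""Optical surface heightmap simulation and its corruption model.

The optical camera is modelled orthographically: a surface image is a 2-D
grid over the (LR, SI) plane whose pixel value is the AP coordinate of the
anterior body surface relative to the iso-center plane, in mm.  Rendering
evaluates the mesh itself (barycentric interpolation per triangle, keeping
the most anterior intersection), which is exact linear interpolation of the
triangulated surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .grid import GridSpec
from .mesh import MeshError, TriMesh

__all__ = [
    "SurfaceImage",
    "SurfaceNoiseConfig",
    "BACKGROUND",
    "mesh_from_body_mask",
    "render_surface_image",
    "corrupt_surface",
]

#: background sentinel for pixels with no surface intersection (mm; far
#: posterior of any anatomy; excluded from losses and statistics)
BACKGROUND = -1000.0


@dataclass
class SurfaceImage:
    """Heightmap over (SI, LR): ``heights[i, j]`` is the AP height (mm) at
    SI index i (increasing superior) and LR index j (increasing patient-left).
    """

    heights: np.ndarray
    fov_mm: float = 202.0
    center: tuple = (0.0, 0.0)       # (LR, SI) of the image center
    background: float = BACKGROUND

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 2:
            raise ValueError("surface image must be 2-D")

    @property
    def shape(self):
        return self.heights.shape

    @property
    def pixel_spacing(self) -> float:
        return self.fov_mm / self.heights.shape[0]

    @property
    def foreground(self) -> np.ndarray:
        return self.heights != self.background

    def axes(self):
        """1-D world coordinates (SI, LR) of the pixel centers."""
        n_si, n_lr = self.heights.shape
        ps = self.pixel_spacing
        si = self.center[1] + (np.arange(n_si) - (n_si - 1) / 2.0) * ps
        lr = self.center[0] + (np.arange(n_lr) - (n_lr - 1) / 2.0) * ps
        return si, lr


@dataclass(frozen=True)
class SurfaceNoiseConfig:
    """The three surface corruption mechanisms emulating imperfect
    internal-external correlation.

    translational_fraction: rigid shift amplitude, as a fraction of the mean
    surface motion magnitude.  deformable_sd_fraction: per-pixel Gaussian sd
    as a fraction of that pixel's motion vs the prior surface, floored at
    ``deformable_sd_bound_mm`` where the motion is smaller than the bound.
    phase_mismatch_prob: chance that the training target is the neighbor
    breathing phase (one 10 %-of-cycle step away) while the image is not.
    """

    translational_fraction: float = 0.4
    deformable_sd_fraction: float = 1.0
    deformable_sd_bound_mm: float = 5.0
    phase_mismatch_prob: float = 0.5
    phase_mismatch_step: int = 1

    def __post_init__(self):
        if min(self.translational_fraction, self.deformable_sd_fraction,
               self.deformable_sd_bound_mm) < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if not 0.0 <= self.phase_mismatch_prob <= 1.0:
            raise ValueError("phase_mismatch_prob must be a probability")


# ---------------------------------------------------------------------------
# body surface extraction
# ---------------------------------------------------------------------------

def mesh_from_body_mask(mask: np.ndarray, grid: GridSpec,
                        max_radius_mm: float = 2.5,
                        max_rounds: int = 12) -> TriMesh:
    """Triangulated body surface from a binary mask.

    Marching-cubes surface extraction followed by midpoint subdivision of
    every face whose circumradius exceeds ``max_radius_mm``, so all triangles
    satisfy the circumradius bound.
    """
    from skimage import measure
    import trimesh as _tm

    mask = np.asarray(mask)
    if not mask.any():
        raise MeshError("cannot mesh an empty mask")
    # pad so the surface closes even when the mask touches the grid edge;
    # a one-voxel Gaussian smoothing removes the voxelization staircase
    # before surface extraction
    padded = ndimage.gaussian_filter(np.pad(mask.astype(np.float64), 2),
                                     sigma=1.0)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=grid.spacing)
    verts = verts + np.asarray(grid.origin) - np.asarray(grid.spacing) * 2.0
    tm = _tm.Trimesh(vertices=verts, faces=faces, process=True)
    for _ in range(max_rounds):
        mesh = TriMesh(np.asarray(tm.vertices, float),
                       np.asarray(tm.faces, np.int64))
        bad = np.nonzero(mesh.circumradii() > max_radius_mm)[0]
        if len(bad) == 0:
            return mesh
        v, f = _tm.remesh.subdivide(tm.vertices, tm.faces, face_index=bad)
        tm = _tm.Trimesh(vertices=v, faces=f, process=False)
    raise MeshError("circumradius bound not reached; mesh too degenerate")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_surface_image(body_mesh: TriMesh, shape=(260, 260),
                         fov_mm: float = 202.0,
                         center=(0.0, 0.0)) -> SurfaceImage:
    """Render the anterior-surface heightmap of a body mesh.

    For every pixel the AP coordinate of the most anterior surface point
    above the pixel's (LR, SI) position is recorded (linear interpolation
    within each triangle).  Pixels without any surface intersection receive
    the background sentinel; a mesh with no FOV overlap yields an
    all-background image (with a warning, not an error).
    """
    import warnings

    shape = tuple(shape)
    img = np.full(shape, BACKGROUND, dtype=np.float64)
    out = SurfaceImage(img, fov_mm=fov_mm, center=tuple(center))
    si_ax, lr_ax = out.axes()
    # tiny offset avoids pixel centers exactly on triangle edges
    eps = 1.2345678e-6 * out.pixel_spacing
    si_s, lr_s = si_ax + eps, lr_ax + 2 * eps

    tri = body_mesh.nodes[body_mesh.faces]    # (F, 3, 3) in (LR, AP, SI)
    hit_any = False
    for v in tri:
        x0, z0 = v[:, 0], v[:, 2]             # LR, SI
        j0 = np.searchsorted(lr_s, x0.min())
        j1 = np.searchsorted(lr_s, x0.max(), side="right")
        i0 = np.searchsorted(si_s, z0.min())
        i1 = np.searchsorted(si_s, z0.max(), side="right")
        if i0 >= i1 or j0 >= j1:
            continue
        pz, px = np.meshgrid(si_s[i0:i1], lr_s[j0:j1], indexing="ij")
        d = (z0[1] - z0[2]) * (x0[0] - x0[2]) + (x0[2] - x0[1]) * (z0[0] - z0[2])
        if abs(d) < 1e-12:
            continue
        l0 = ((z0[1] - z0[2]) * (px - x0[2]) + (x0[2] - x0[1]) * (pz - z0[2])) / d
        l1 = ((z0[2] - z0[0]) * (px - x0[2]) + (x0[0] - x0[2]) * (pz - z0[2])) / d
        l2 = 1.0 - l0 - l1
        inside = (l0 >= 0) & (l1 >= 0) & (l2 >= 0)
        if not inside.any():
            continue
        hit_any = True
        h = l0 * v[0, 1] + l1 * v[1, 1] + l2 * v[2, 1]   # AP height
        block = img[i0:i1, j0:j1]
        np.maximum(block, np.where(inside, h, BACKGROUND), out=block)
    if not hit_any:
        warnings.warn("body mesh does not overlap the surface-image FOV")
    out.heights = img
    return out


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

def corrupt_surface(image_pair, phase_index: int, n_phases: int,
                    cfg: SurfaceNoiseConfig, rng):
    """Apply the three surface-noise mechanisms to a current-phase image.

    Parameters
    ----------
    image_pair : (prior SurfaceImage, current SurfaceImage)
        Rendered at phase 0% and at ``phase_index`` respectively, on the
        same image grid.
    phase_index, n_phases : position of the current phase in the cycle
        (used for the internal-external phase-mismatch mechanism).
    rng : seeded ``numpy.random.Generator``.

    Returns
    -------
    (corrupted SurfaceImage, target_phase_index)
        The image stays at ``phase_index``; with probability
        ``phase_mismatch_prob`` the returned target index is one cycle step
        away (direction chosen with equal probability, wrapping around).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    prior, current = image_pair
    if prior.shape != current.shape:
        raise ValueError("prior and current surface images must share a grid")
    fg = prior.foreground & current.foreground
    motion = np.where(fg, current.heights - prior.heights, 0.0)
    mean_mag = float(np.abs(motion[fg]).mean()) if fg.any() else 0.0

    heights = current.heights.copy()
    mask = current.foreground.astype(np.float64)

    # (1) rigid translational uncertainty: in-plane + height shift, each
    # component uniform within +-(fraction * mean motion magnitude)
    amp = cfg.translational_fraction * mean_mag
    if amp > 0:
        d_lr, d_si, d_ap = rng.uniform(-amp, amp, size=3)
        ps = current.pixel_spacing
        shift_px = (d_si / ps, d_lr / ps)    # (SI rows, LR cols)
        filled = np.where(current.foreground, heights, np.nan)
        filled = _fill_nearest(filled)
        shifted = ndimage.shift(filled, shift_px, order=1, mode="nearest")
        mask = ndimage.shift(mask, shift_px, order=1, mode="constant", cval=0.0)
        heights = np.where(mask > 0.5, shifted + d_ap, BACKGROUND)
    else:
        heights = np.where(mask > 0.5, heights, BACKGROUND)

    # (2) deformable uncertainty: zero-mean Gaussian, per-pixel sd equal to
    # the pixel's surface motion, floored at the bound for small motion
    sd = cfg.deformable_sd_fraction * np.abs(motion)
    sd = np.where(sd < cfg.deformable_sd_bound_mm, cfg.deformable_sd_bound_mm, sd)
    noise = rng.normal(0.0, 1.0, size=heights.shape) * sd
    fg_now = heights != BACKGROUND
    heights = np.where(fg_now, heights + noise, BACKGROUND)

    # (3) internal-external phase mismatch: the target label may belong to a
    # neighboring breathing phase while the image does not move
    target = phase_index
    if rng.uniform() < cfg.phase_mismatch_prob:
        step = cfg.phase_mismatch_step if rng.uniform() < 0.5 else -cfg.phase_mismatch_step
        target = (phase_index + step) % n_phases

    out = SurfaceImage(heights, fov_mm=current.fov_mm, center=current.center)
    return out, target


def _fill_nearest(img_with_nan: np.ndarray) -> np.ndarray:
    """Replace NaNs by their nearest finite neighbor (for safe shifting)."""
    nanmask = np.isnan(img_with_nan)
    if not nanmask.any():
        return img_with_nan
    idx = ndimage.distance_transform_edt(nanmask, return_distances=False,
                                         return_indices=True)
    return img_with_nan[tuple(idx)]
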