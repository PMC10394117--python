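"""End-to-end inference: surface regression, x-ray refinement, and
biomechanical propagation chained into one tumor-localization pass."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bionet import BioUNet, predict_intra_dvf
from .grid import BoundaryDVF, GridSpec, VolumetricDVF
from .mesh import TriMesh
from .phantom import warp_mask
from .projection import XRayProjection
from .surface import SurfaceImage
from .surfnet import SurfNet, predict_boundary_dvf
from .xnet import XNet, x_forward

__all__ = ["CascadeModels", "CascadeResult", "run_cascade", "VARIANTS"]

VARIANTS = ("prior", "surf-bio", "x-bio", "surf-x-bio")


class CascadeError(RuntimeError):
    """Raised with a stage-named diagnostic when a cascade stage mismatches."""


@dataclass
class CascadeModels:
    """Trained models plus the prior anatomy they are bound to.

    ``x_models`` maps gantry angles to refiners trained with surface-model
    initialization; ``x_zero_models`` holds the zero-initialization
    retrained ablation refiners.
    """

    surf: SurfNet
    x_models: dict                   # angle (deg) -> XNet
    x_zero_models: dict              # angle (deg) -> XNet (ablation)
    bio: BioUNet
    prior_liver: TriMesh
    bio_grid: GridSpec
    bio_band: np.ndarray
    prior_tumor_mask: np.ndarray     # on bio_grid


@dataclass
class CascadeResult:
    boundary_dvf: BoundaryDVF        # final liver boundary displacement
    deformed_mesh: TriMesh
    intra_dvf: VolumetricDVF         # on the bio grid
    tumor_mask: np.ndarray           # propagated prior tumor contour
    surf_dvf: BoundaryDVF = None     # stage (a) output, when used
    x_refinement: BoundaryDVF = None # stage (b) output, when used


def run_cascade(surface_image: SurfaceImage, projection: XRayProjection,
                prior_mesh: TriMesh, models: CascadeModels,
                variant: str = "surf-x-bio",
                isocenter_offset=None) -> CascadeResult:
    """Localize the tumor from one surface image and one x-ray projection.

    Variants: ``surf-x-bio`` (full cascade), ``surf-bio`` (skip the x-ray
    refiner), ``x-bio`` (zero-displacement initialization, retrained
    refiner), ``prior`` (no registration).  ``isocenter_offset`` is an
    optional rigid miscalibration vector added to the surface-predicted
    displacement before the x-ray stage (robustness protocol).
    """
    if variant not in VARIANTS:
        raise CascadeError(f"unknown cascade variant {variant!r}")
    n = prior_mesh.n_nodes

    if variant == "prior":
        surf_dvf = None
        boundary = BoundaryDVF(np.zeros((n, 3)), mesh_ref="liver")
        mesh = prior_mesh
        refinement = None
    else:
        if variant in ("surf-bio", "surf-x-bio"):
            if models.surf is None:
                raise CascadeError("surface stage: no trained surface model")
            try:
                surf_dvf = predict_boundary_dvf(models.surf, surface_image)
            except ValueError as e:
                raise CascadeError(f"surface stage: {e}") from e
        else:
            surf_dvf = BoundaryDVF(np.zeros((n, 3)), mesh_ref="liver")
        d0 = surf_dvf.d
        if isocenter_offset is not None:
            d0 = d0 + np.asarray(isocenter_offset, float)

        if variant in ("x-bio", "surf-x-bio"):
            registry = models.x_zero_models if variant == "x-bio" else models.x_models
            angle = projection.geometry.gantry_deg
            if angle not in registry:
                raise CascadeError(f"x-ray stage: no refiner for angle {angle}")
            xmodel = registry[angle]
            try:
                init_mesh = prior_mesh.with_nodes(prior_mesh.nodes + d0)
                refinement, mesh = x_forward(xmodel, projection, init_mesh)
            except ValueError as e:
                raise CascadeError(f"x-ray stage: {e}") from e
            boundary = BoundaryDVF(d0 + refinement.d, mesh_ref="liver")
        else:
            refinement = None
            boundary = BoundaryDVF(d0, mesh_ref="liver")
            mesh = prior_mesh.with_nodes(prior_mesh.nodes + d0)

    if variant == "prior":
        intra = VolumetricDVF(np.zeros(tuple(models.bio_grid.shape) + (3,)),
                              models.bio_grid)
        tumor = models.prior_tumor_mask.copy()
    else:
        try:
            intra = predict_intra_dvf(models.bio, boundary, models.prior_liver,
                                      models.bio_grid, models.bio_band)
        except Exception as e:
            raise CascadeError(f"biomechanical stage: {e}") from e
        tumor = warp_mask(models.prior_tumor_mask, intra)

    return CascadeResult(boundary, mesh, intra, tumor,
                         surf_dvf=surf_dvf, x_refinement=refinement)
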