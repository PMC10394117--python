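"""Serialization of meshes, volumes, displacement fields and images.

Meshes are written as PLY or OBJ; volumes and displacement fields as NIfTI
(.nii/.nii.gz) or MetaImage (.mha), with displacement fields stored as
3-component vector images in mm; surface images and projections as 32-bit
float TIFF with a JSON sidecar holding the geometry metadata.

The voxel convention everywhere in this package is index order
(LR, AP, SI) with world = origin + index * spacing; the NIfTI affine is the
corresponding diagonal mapping (no axis flips are applied).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .grid import GridSpec, VolumetricDVF
from .mesh import TriMesh
from .projection import ProjectionGeometry, XRayProjection
from .surface import SurfaceImage

__all__ = [
    "save_mesh", "load_mesh", "save_volume", "load_volume",
    "save_dvf", "load_dvf", "save_surface_image", "load_surface_image",
    "save_projection", "load_projection",
]


def save_mesh(mesh: TriMesh, path) -> None:
    """Write a mesh as PLY or OBJ (by extension)."""
    mesh.to_trimesh().export(str(path))


def load_mesh(path) -> TriMesh:
    import trimesh as _tm

    tm = _tm.load(str(path), process=False, force="mesh")
    return TriMesh.from_trimesh(tm)


def _affine(grid: GridSpec) -> np.ndarray:
    a = np.eye(4)
    a[:3, :3] = np.diag(grid.spacing)
    a[:3, 3] = grid.origin
    return a


def save_volume(volume: np.ndarray, grid: GridSpec, path) -> None:
    """Write a scalar volume as NIfTI or MetaImage (by extension)."""
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(volume, np.float32),
                                 _affine(grid)), path)
    elif path.endswith(".mha"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(
            np.ascontiguousarray(np.transpose(volume, (2, 1, 0)),
                                 dtype=np.float32))
        img.SetSpacing(tuple(grid.spacing))
        img.SetOrigin(tuple(grid.origin))
        sitk.WriteImage(img, path)
    else:
        raise ValueError(f"unsupported volume format: {path}")


def load_volume(path):
    """Read a scalar volume; returns ``(array, GridSpec)``."""
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        arr = np.asarray(img.dataobj, dtype=np.float64)
        aff = img.affine
        grid = GridSpec(tuple(aff[:3, 3]), tuple(np.diag(aff[:3, :3])),
                        arr.shape[:3])
        return arr, grid
    if path.endswith(".mha"):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0)).astype(np.float64)
        grid = GridSpec(tuple(img.GetOrigin()), tuple(img.GetSpacing()),
                        arr.shape[:3])
        return arr, grid
    raise ValueError(f"unsupported volume format: {path}")


def save_dvf(dvf: VolumetricDVF, path) -> None:
    """Write a displacement field as a 3-component vector image (mm)."""
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(dvf.field, np.float32),
                                 _affine(dvf.grid)), path)
    elif path.endswith(".mha"):
        import SimpleITK as sitk

        arr = np.ascontiguousarray(
            np.transpose(dvf.field, (2, 1, 0, 3)), dtype=np.float64)
        img = sitk.GetImageFromArray(arr, isVector=True)
        img.SetSpacing(tuple(dvf.grid.spacing))
        img.SetOrigin(tuple(dvf.grid.origin))
        sitk.WriteImage(img, path)
    else:
        raise ValueError(f"unsupported DVF format: {path}")


def load_dvf(path) -> VolumetricDVF:
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        arr, grid = load_volume(path)
        return VolumetricDVF(arr, GridSpec(grid.origin, grid.spacing,
                                           arr.shape[:3]))
    if path.endswith(".mha"):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0, 3)).astype(np.float64)
        grid = GridSpec(tuple(img.GetOrigin()), tuple(img.GetSpacing()),
                        arr.shape[:3])
        return VolumetricDVF(arr, grid)
    raise ValueError(f"unsupported DVF format: {path}")


def save_surface_image(image: SurfaceImage, path) -> None:
    """32-bit float TIFF plus a JSON sidecar with FOV and reference plane."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(str(path), image.heights.astype(np.float32))
    meta = dict(fov_mm=image.fov_mm, center=list(image.center),
                background=image.background,
                pixel_spacing=image.pixel_spacing,
                reference_plane="iso-center AP = 0")
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_surface_image(path) -> SurfaceImage:
    import tifffile

    path = Path(path)
    heights = tifffile.imread(str(path)).astype(np.float64)
    meta = json.loads(path.with_suffix(".json").read_text())
    return SurfaceImage(heights, fov_mm=meta["fov_mm"],
                        center=tuple(meta["center"]),
                        background=meta["background"])


def save_projection(projection: XRayProjection, path) -> None:
    """32-bit float TIFF of line integrals plus a JSON geometry sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(str(path), projection.line_integrals.astype(np.float32))
    g = projection.geometry
    meta = dict(sad=g.sad, sdd=g.sdd, gantry_deg=g.gantry_deg,
                det_shape=list(g.det_shape), pixel_pitch=g.pixel_pitch)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_projection(path) -> XRayProjection:
    import tifffile

    path = Path(path)
    li = tifffile.imread(str(path)).astype(np.float64)
    meta = json.loads(path.with_suffix(".json").read_text())
    geom = ProjectionGeometry(sad=meta["sad"], sdd=meta["sdd"],
                              gantry_deg=meta["gantry_deg"],
                              det_shape=tuple(meta["det_shape"]),
                              pixel_pitch=meta["pixel_pitch"])
    return XRayProjection(li, geom)
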