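"""Linear-elastic reference solver for intra-liver displacement propagation.

Propagates liver boundary displacements into the organ interior by solving
the homogeneous isotropic Navier-Cauchy equations

    mu * lap(u) + (lam + mu) * grad(div u) = 0

on the interior liver voxels with Dirichlet conditions given by the boundary
displacement field rasterized onto the liver shell voxels.  Central finite
differences on the uniform voxel grid; exact sparse solve.  This is a
small-strain stand-in for hyperelastic finite-element modelling: constants
satisfy the equations exactly (rigid translations pass through) and affine
displacement fields are reproduced exactly (uniform strain has zero residual
under central differences).

Supply ``mode="harmonic"`` to drop the grad-div coupling and solve three
independent Laplace problems (a useful cross-check: each displacement
component then obeys the discrete maximum principle).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .grid import BoundaryDVF, GridSpec
from .mesh import TriMesh

__all__ = [
    "solve_reference_biomechanics", "solve_dirichlet",
    "shell_and_interior", "rasterize_boundary",
]


def shell_and_interior(mask: np.ndarray):
    """Split a binary organ mask into its Dirichlet shell and interior.

    The interior contains voxels whose full 3x3x3 neighborhood lies inside
    the mask (so every finite-difference stencil point is defined); the
    shell is the rest of the mask.
    """
    mask = np.asarray(mask, bool)
    interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3, 3)))
    shell = mask & ~interior
    return shell, interior


def rasterize_boundary(boundary_dvf: BoundaryDVF, mesh: TriMesh,
                       shell: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Nearest-node rasterization of a boundary field onto shell voxels."""
    from scipy.spatial import cKDTree

    vals = np.zeros(shell.shape + (3,))
    idx = np.argwhere(shell)
    if len(idx) == 0:
        return vals
    pts = np.asarray(grid.origin) + idx * np.asarray(grid.spacing)
    _, nearest = cKDTree(mesh.nodes).query(pts)
    vals[idx[:, 0], idx[:, 1], idx[:, 2]] = boundary_dvf.d[nearest]
    return vals


def solve_dirichlet(mask: np.ndarray, shell_values: np.ndarray,
                    grid: GridSpec = None, nu: float = 0.45,
                    mode: str = "navier") -> np.ndarray:
    """Solve the discrete elastostatic Dirichlet problem on a voxel mask.

    Parameters
    ----------
    mask : binary organ mask; the stencil-complete interior is solved for,
        the rest of the mask acts as the Dirichlet shell.
    shell_values : (mask.shape + (3,)) displacement (mm) prescribed on the
        shell (values outside the shell are ignored).
    nu : Poisson ratio (0 <= nu < 0.5); only the ratio (lam+mu)/mu matters.
    mode : "navier" for the coupled equations, "harmonic" for three
        independent Laplace problems.

    Returns the displacement field, zero outside the mask, shell values on
    the shell, and the exact sparse solution on the interior.
    """
    if not 0.0 <= nu < 0.5:
        raise ValueError("Poisson ratio must be in [0, 0.5)")
    mask = np.asarray(mask, bool)
    shell, interior = shell_and_interior(mask)
    out = np.zeros(mask.shape + (3,))
    out[shell] = shell_values[shell]
    n_int = int(interior.sum())
    if n_int == 0:
        return out

    # grad-div coupling strength (lam + mu) / mu for mu = 1
    lam = 2.0 * nu / (1.0 - 2.0 * nu)
    gd = 0.0 if mode == "harmonic" else lam + 1.0

    shape = mask.shape
    index = -np.ones(shape, dtype=np.int64)
    ij = np.argwhere(interior)
    index[interior] = np.arange(n_int)

    known = np.zeros(shape + (3,))
    known[shell] = shell_values[shell]

    rows, cols, vals = [], [], []
    rhs = np.zeros(3 * n_int)

    def add(r_vox, r_comp, c_off, c_comp, coeff):
        """Stencil entry: equation (r_vox, r_comp) <- coeff * u_comp at
        voxel + offset; known (shell) values go to the RHS."""
        nb = ij + c_off
        nb_idx = index[nb[:, 0], nb[:, 1], nb[:, 2]]
        r = 3 * np.arange(n_int) + r_comp
        unknown = nb_idx >= 0
        rows.append(r[unknown])
        cols.append(3 * nb_idx[unknown] + c_comp)
        vals.append(np.full(unknown.sum(), coeff))
        kv = known[nb[~unknown][:, 0], nb[~unknown][:, 1], nb[~unknown][:, 2], c_comp]
        np.subtract.at(rhs, r[~unknown], coeff * kv)

    # Laplacian part: mu * sum_k (u(+e_k) - 2u + u(-e_k)) / h^2, and
    # grad-div part: (lam+mu) * d^2 u_j / dx_i dx_j.  The common 1/h^2
    # factor cancels in the homogeneous system (isotropic spacing).
    for comp in range(3):
        add(None, comp, np.array([0, 0, 0]), comp, -6.0 - 2.0 * gd)
        for ax in range(3):
            e = np.zeros(3, dtype=np.int64)
            e[ax] = 1
            c_diag = 1.0 + (gd if ax == comp else 0.0)
            add(None, comp, e, comp, c_diag)
            add(None, comp, -e, comp, c_diag)
        if gd:
            for other in range(3):
                if other == comp:
                    continue
                e1 = np.zeros(3, dtype=np.int64)
                e2 = np.zeros(3, dtype=np.int64)
                e1[comp] = 1
                e2[other] = 1
                for s1 in (1, -1):
                    for s2 in (1, -1):
                        add(None, comp, s1 * e1 + s2 * e2, other,
                            gd * 0.25 * s1 * s2)

    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(3 * n_int, 3 * n_int))
    sol = spla.spsolve(A, rhs)
    out[ij[:, 0], ij[:, 1], ij[:, 2]] = sol.reshape(n_int, 3)
    return out


def solve_reference_biomechanics(liver_mask: np.ndarray,
                                 boundary_dvf: BoundaryDVF,
                                 mesh: TriMesh, grid: GridSpec,
                                 nu: float = 0.45,
                                 mode: str = "navier") -> np.ndarray:
    """Reference intra-liver displacement for a boundary displacement field.

    Rasterizes the mesh-node displacements onto the liver shell voxels
    (nearest node) and solves the linear-elastic Dirichlet problem inside.
    Returns a (mask.shape + (3,)) field in mm, zero outside the liver.
    Users with an external finite-element package can substitute their own
    fields anywhere a reference field is consumed.
    """
    shell, interior = shell_and_interior(np.asarray(liver_mask, bool))
    vals = rasterize_boundary(boundary_dvf, mesh, shell, grid)
    if interior.sum() == 0:
        out = np.zeros(liver_mask.shape + (3,))
        out[shell] = vals[shell]
        return out
    return solve_dirichlet(liver_mask, vals, grid, nu=nu, mode=mode)
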