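"""Galerkin FEM assembly over linear tetrahedral elements.

Builds the sparse system matrices of the time-domain diffusion model:

* ``K`` — stiffness: volume term ``∫ D ∇u_i·∇u_j + mu_a u_i u_j dΩ``
  plus the Robin boundary term ``(1/2q) ∫ u_i u_j d(∂Ω)``;
* ``C`` — mass-like matrix ``(1/c) ∫ u_i u_j dΩ``.

Coefficients are piecewise constant per element (per-region optical
properties); all element integrals use the closed forms for linear
barycentric basis functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .mesh_model import InvalidPropertyError, Mesh, MeshError, PropertyField

__all__ = [
    "SystemMatrices",
    "element_mass",
    "element_stiffness",
    "face_boundary_matrix",
    "tet_gradients",
    "assemble_system",
]

# ∫ u_i u_j over a tet = V (1+δij)/20 ; over a triangle = A (1+δij)/12
_TET_MASS = (np.ones((4, 4)) + np.eye(4)) / 20.0
_TRI_MASS = (np.ones((3, 3)) + np.eye(3)) / 12.0


@dataclass
class SystemMatrices:
    """Assembled sparse FEM matrices (both symmetric, CSC)."""

    K: sp.csc_matrix
    C: sp.csc_matrix

    def propagator_matrix(self, dt: float) -> sp.csc_matrix:
        """``A = K + C/dt`` — symmetric positive definite for dt > 0."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        return (self.K + self.C / dt).tocsc()


def tet_gradients(verts: np.ndarray) -> tuple[np.ndarray, float]:
    """Constant gradients of the 4 barycentric basis functions and the volume.

    ``verts`` is 4x3.  Raises :class:`MeshError` for degenerate elements.
    The gradients satisfy ``sum_i grad_i = 0``.
    """
    verts = np.asarray(verts, dtype=float)
    J = verts[1:] - verts[0]  # 3x3
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    if vol == 0:
        raise MeshError("degenerate (zero-volume) tetrahedron")
    invJT = np.linalg.inv(J).T  # rows = grad(u_1..u_3)
    grads = np.vstack([-invJT.sum(axis=0), invJT])  # u_0 = 1 - ξ - η - ζ
    return grads, abs(vol)


def element_mass(verts: np.ndarray, c: float) -> np.ndarray:
    """4x4 element matrix ``(1/c) ∫ u_i u_j`` = ``(V/c)(1+δij)/20``."""
    _, vol = tet_gradients(verts)
    return (vol / c) * _TET_MASS


def element_stiffness(verts: np.ndarray, D: float, mu_a: float) -> np.ndarray:
    """4x4 element matrix ``∫ D ∇u_i·∇u_j + mu_a u_i u_j``."""
    if D < 0 or mu_a < 0:
        raise InvalidPropertyError("D and mu_a must be nonnegative")
    grads, vol = tet_gradients(verts)
    return D * vol * (grads @ grads.T) + mu_a * vol * _TET_MASS


def face_boundary_matrix(verts: np.ndarray, q: float) -> np.ndarray:
    """3x3 Robin boundary matrix ``(1/2q) ∫ u_i u_j`` over a surface triangle."""
    if q <= 0:
        raise InvalidPropertyError("q must be > 0")
    verts = np.asarray(verts, dtype=float)
    area = 0.5 * np.linalg.norm(
        np.cross(verts[1] - verts[0], verts[2] - verts[0])
    )
    return (area / (2.0 * q)) * _TRI_MASS


def assemble_system(
    mesh: Mesh,
    props: PropertyField,
    q: float | None = None,
    include_boundary: bool = True,
) -> SystemMatrices:
    """Assemble K and C by scattering closed-form element matrices.

    ``q`` defaults to ``props.q``.  ``include_boundary=False`` omits the
    Robin surface term (useful for null-space checks).
    """
    if q is None:
        q = props.q
    mu_a_e, _, D_e = props.element_arrays(mesh)
    p = mesh.node_coords
    conn = mesh.tet_conn
    n = mesh.n_nodes

    # vectorized per-element gradients and volumes
    v0 = p[conn[:, 0]]
    J = p[conn[:, 1:]] - v0[:, None, :]  # (M,3,3) rows = edge vectors
    detJ = np.linalg.det(J)
    vols = np.abs(detJ) / 6.0
    if np.any(vols == 0):
        bad = int(np.flatnonzero(vols == 0)[0])
        raise MeshError(f"degenerate element {bad} during assembly")
    invJT = np.transpose(np.linalg.inv(J), (0, 2, 1))  # (M,3,3)
    grads = np.empty((len(conn), 4, 3))
    grads[:, 1:, :] = invJT
    grads[:, 0, :] = -invJT.sum(axis=1)

    gram = np.einsum("eik,ejk->eij", grads, grads)  # (M,4,4)
    ke = D_e[:, None, None] * vols[:, None, None] * gram
    ke += (mu_a_e * vols)[:, None, None] * _TET_MASS
    ce = (vols / props.c)[:, None, None] * np.broadcast_to(
        _TET_MASS, (len(conn), 4, 4)
    )

    rows = np.repeat(conn, 4, axis=1).ravel()
    cols = np.tile(conn, (1, 4)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n))
    C = sp.coo_matrix((ce.ravel(), (rows, cols)), shape=(n, n))

    if include_boundary and len(mesh.boundary_faces):
        bf = mesh.boundary_faces
        e1 = p[bf[:, 1]] - p[bf[:, 0]]
        e2 = p[bf[:, 2]] - p[bf[:, 0]]
        areas = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
        be = (areas / (2.0 * q))[:, None, None] * np.broadcast_to(
            _TRI_MASS, (len(bf), 3, 3)
        )
        brows = np.repeat(bf, 3, axis=1).ravel()
        bcols = np.tile(bf, (1, 3)).ravel()
        K = K + sp.coo_matrix((be.ravel(), (brows, bcols)), shape=(n, n))

    K = K.tocsc()
    C = C.tocsc()
    # enforce exact symmetry against floating accumulation-order noise
    K = ((K + K.T) * 0.5).tocsc()
    C = ((C + C.T) * 0.5).tocsc()
    return SystemMatrices(K=K, C=C)
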