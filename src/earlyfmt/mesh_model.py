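"""Tetrahedral mesh model, optical properties, and the synthetic phantom.

The imaging volume is a tetrahedral mesh with per-element tissue-region
labels.  Optical properties (absorption ``mu_a``, reduced scattering
``mu_s_prime``) are assigned per region; the diffusion coefficient is
derived as ``D = 1/(3*(mu_a + mu_s_prime))``.  The synthetic phantom is a
cylinder (radius 1.2 cm, height 3 cm, axis = z, the rotation axis of the
acquisition stage) with ellipsoidal organ regions and a small cylindrical
fluorescent target, standing in for a segmented small-animal torso.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "Mesh",
    "PropertyField",
    "PhantomSpec",
    "OrganSpec",
    "TargetSpec",
    "FluorophoreMap",
    "TISSUE_OPTICAL_PROPERTIES",
    "diffusion_coefficient",
    "effective_reflection_mismatch",
    "build_cylindrical_phantom",
    "extract_boundary",
]

VACUUM_LIGHT_SPEED_CM_PER_PS = 0.0299792458

#: Published absorption / reduced-scattering coefficients (1/cm) for the
#: tissue types of the heterogeneous small-animal model.
TISSUE_OPTICAL_PROPERTIES: dict[str, tuple[float, float]] = {
    "background": (0.1, 10.0),
    "heart": (0.156, 9.0),
    "lung": (0.516, 21.2),
    "liver": (0.935, 6.4),
}


class InvalidPropertyError(ValueError):
    """An optical or fluorophore property violates its physical range."""


class MeshError(ValueError):
    """A mesh fails a structural invariant (degenerate or non-manifold)."""


class GeometryError(ValueError):
    """A geometric configuration request cannot be satisfied."""


def diffusion_coefficient(mu_a: float, mu_s_prime: float) -> float:
    """Diffusion coefficient ``D = 1/(3*(mu_a + mu_s_prime))`` in cm.

    Parameters are the absorption and reduced scattering coefficients in
    1/cm.  ``mu_s_prime`` must be positive (diffusive regime); ``mu_a``
    may be zero.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    if np.any(mu_s_prime <= 0):
        raise InvalidPropertyError("mu_s_prime must be > 0 (diffusive medium)")
    if np.any(mu_a < 0):
        raise InvalidPropertyError("mu_a must be >= 0")
    out = 1.0 / (3.0 * (mu_a + mu_s_prime))
    return float(out) if out.ndim == 0 else out


def effective_reflection_mismatch(n_rel: float) -> float:
    """Boundary mismatch coefficient q for relative refractive index n.

    Uses the standard effective-reflection fit
    ``R_eff = -1.440 n^-2 + 0.710 n^-1 + 0.668 + 0.0636 n`` and
    ``q = (1 + R_eff) / (1 - R_eff)``.
    """
    if n_rel <= 0:
        raise InvalidPropertyError("refractive index must be positive")
    r_eff = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    if not (0 <= r_eff < 1):
        raise InvalidPropertyError(f"R_eff={r_eff:.3f} outside [0,1)")
    return (1.0 + r_eff) / (1.0 - r_eff)


@dataclass
class Mesh:
    """Tetrahedral volume mesh with region labels and an oriented boundary.

    Attributes
    ----------
    node_coords : (N, 3) float array, cm
    tet_conn : (M, 4) int array
        0-based connectivity; every tet is oriented to positive signed
        volume.
    region_label : (M,) int array
        Tissue region per element.
    boundary_faces : (F, 3) int array
        Surface triangles (faces belonging to exactly one tet).
    face_normal : (F, 3) float array
        Outward unit normals.
    """

    node_coords: np.ndarray
    tet_conn: np.ndarray
    region_label: np.ndarray
    boundary_faces: np.ndarray = field(default=None)  # type: ignore[assignment]
    face_normal: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.node_coords = np.ascontiguousarray(self.node_coords, dtype=float)
        self.tet_conn = np.ascontiguousarray(self.tet_conn, dtype=np.int64)
        self.region_label = np.ascontiguousarray(self.region_label, dtype=np.int64)
        if self.tet_conn.size and self.tet_conn.max() >= len(self.node_coords):
            raise MeshError("connectivity references a node beyond N")
        self._orient_positive()
        if self.boundary_faces is None:
            self.boundary_faces, self.face_normal = extract_boundary(self)

    # -- geometry -----------------------------------------------------
    def _orient_positive(self) -> None:
        vol = self.tet_volumes(signed=True)
        if np.any(vol == 0):
            bad = int(np.flatnonzero(vol == 0)[0])
            raise MeshError(f"degenerate (zero-volume) tetrahedron at element {bad}")
        flip = vol < 0
        if np.any(flip):
            conn = self.tet_conn.copy()
            conn[flip, 0], conn[flip, 1] = self.tet_conn[flip, 1], self.tet_conn[flip, 0]
            self.tet_conn = conn

    def tet_volumes(self, signed: bool = False) -> np.ndarray:
        p = self.node_coords[self.tet_conn]
        v = np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        ) / 6.0
        return v if signed else np.abs(v)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_elements(self) -> int:
        return len(self.tet_conn)

    def nodal_volumes(self) -> np.ndarray:
        """Per-node volume share: each tet contributes V/4 to its vertices."""
        vols = self.tet_volumes()
        out = np.zeros(self.n_nodes)
        np.add.at(out, self.tet_conn.ravel(), np.repeat(vols / 4.0, 4))
        return out

    def element_centroids(self) -> np.ndarray:
        return self.node_coords[self.tet_conn].mean(axis=1)


def extract_boundary(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Surface faces (shared by exactly one tet) with outward unit normals.

    Raises :class:`MeshError` if any face is shared by more than two tets
    (non-manifold mesh).
    """
    conn = mesh.tet_conn
    # the four faces of tet (a,b,c,d)
    face_idx = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    faces = conn[:, face_idx].reshape(-1, 3)  # (4M, 3)
    owner = np.repeat(np.arange(len(conn)), 4)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    if np.any(counts > 2):
        raise MeshError("non-manifold face shared by more than 2 tetrahedra")
    is_boundary = counts[inv] == 1
    bfaces = faces[is_boundary]
    bowner = owner[is_boundary]

    p = mesh.node_coords
    normal = np.cross(
        p[bfaces[:, 1]] - p[bfaces[:, 0]], p[bfaces[:, 2]] - p[bfaces[:, 0]]
    )
    norm = np.linalg.norm(normal, axis=1, keepdims=True)
    normal = normal / norm
    # orient away from the owning tet's centroid
    centroid = p[conn[bowner]].mean(axis=1)
    face_c = p[bfaces].mean(axis=1)
    flip = np.einsum("ij,ij->i", normal, face_c - centroid) < 0
    normal[flip] *= -1.0
    bfaces = bfaces.copy()
    bfaces[flip, 1], bfaces[flip, 2] = bfaces[flip, 2].copy(), bfaces[flip, 1].copy()
    return bfaces, normal


@dataclass
class PropertyField:
    """Per-region optical properties mapped onto mesh elements.

    ``mu_a`` and ``mu_s_prime`` are dicts region-label -> value (1/cm);
    ``D`` is derived.  ``q`` is the boundary refractive-mismatch
    coefficient and ``c`` the in-medium light speed (cm/ps), both shared
    across the mesh.  The same properties are used at excitation and
    emission wavelengths.
    """

    mu_a: dict[int, float]
    mu_s_prime: dict[int, float]
    q: float
    c: float

    def __post_init__(self) -> None:
        for lbl, m in self.mu_a.items():
            if m < 0:
                raise InvalidPropertyError(f"mu_a < 0 for region {lbl}")
        for lbl, m in self.mu_s_prime.items():
            if m <= 0:
                raise InvalidPropertyError(f"mu_s_prime <= 0 for region {lbl}")
        if self.q <= 0:
            raise InvalidPropertyError("q must be > 0")
        if self.c <= 0:
            raise InvalidPropertyError("light speed must be > 0")

    @property
    def D(self) -> dict[int, float]:
        return {
            lbl: diffusion_coefficient(self.mu_a[lbl], self.mu_s_prime[lbl])
            for lbl in self.mu_a
        }

    def element_arrays(self, mesh: Mesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mu_a, mu_s', D) per element; errors on unmapped region labels."""
        labels = mesh.region_label
        unknown = set(np.unique(labels)) - set(self.mu_a)
        if unknown:
            raise MeshError(f"elements with unmapped region labels: {sorted(unknown)}")
        mu_a = np.array([self.mu_a[l] for l in labels])
        mu_s = np.array([self.mu_s_prime[l] for l in labels])
        return mu_a, mu_s, 1.0 / (3.0 * (mu_a + mu_s))

    @classmethod
    def from_tissue_table(
        cls,
        region_names: dict[int, str],
        n_rel: float = 1.37,
        overrides: dict[str, tuple[float, float]] | None = None,
    ) -> "PropertyField":
        table = dict(TISSUE_OPTICAL_PROPERTIES)
        if overrides:
            table.update(overrides)
        mu_a = {lbl: table[name][0] for lbl, name in region_names.items()}
        mu_s = {lbl: table[name][1] for lbl, name in region_names.items()}
        return cls(
            mu_a=mu_a,
            mu_s_prime=mu_s,
            q=effective_reflection_mismatch(n_rel),
            c=VACUUM_LIGHT_SPEED_CM_PER_PS / n_rel,
        )


@dataclass
class FluorophoreMap:
    """Per-node fluorescence yield eta (arbitrary units) and lifetime tau (ps)."""

    eta: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        if np.any(self.eta < 0):
            raise InvalidPropertyError("eta must be >= 0 everywhere")
        if self.tau <= 0:
            raise InvalidPropertyError("lifetime tau must be > 0")


@dataclass
class OrganSpec:
    """Axis-aligned ellipsoidal organ region."""

    name: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    label: int


@dataclass
class TargetSpec:
    """Small cylindrical fluorescent inclusion (axis along z)."""

    center: tuple[float, float, float] = (-0.31, -0.02, 1.93)
    radius: float = 0.1
    height: float = 0.2
    value: float = 1.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        cx, cy, cz = self.center
        r2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
        tol = 1e-12
        return (r2 <= (self.radius + tol) ** 2) & (
            np.abs(pts[:, 2] - cz) <= self.height / 2.0 + tol
        )


def default_organs() -> list[OrganSpec]:
    """Three ellipsoidal organs placed clear of the fluorescent target."""
    return [
        OrganSpec("heart", (0.35, 0.10, 2.00), (0.30, 0.25, 0.35), 1),
        OrganSpec("lung", (-0.20, 0.55, 2.20), (0.45, 0.35, 0.50), 2),
        OrganSpec("liver", (0.10, -0.45, 1.00), (0.55, 0.45, 0.70), 3),
    ]


@dataclass
class PhantomSpec:
    """Configuration of the synthetic cylindrical phantom.

    Defaults emulate the study geometry: 3 cm tall volume, small
    cylindrical target (r 0.1 cm, h 0.2 cm) at (-0.31, -0.02, 1.93) cm,
    heart/lung/liver regions with the published optical properties.
    """

    radius: float = 1.2
    height: float = 3.0
    organs: Sequence[OrganSpec] = field(default_factory=default_organs)
    target: TargetSpec = field(default_factory=TargetSpec)
    edge_length: float = 0.18
    tau_ps: float = 560.0
    n_rel: float = 1.37

    def __post_init__(self) -> None:
        cx, cy, cz = self.target.center
        if (
            np.hypot(cx, cy) + self.target.radius >= self.radius
            or cz - self.target.height / 2 <= 0
            or cz + self.target.height / 2 >= self.height
        ):
            raise GeometryError("fluorescent target must lie strictly inside the cylinder")

    def region_names(self) -> dict[int, str]:
        names = {0: "background"}
        for org in self.organs:
            names[org.label] = org.name
        return names


def _cylinder_lattice(radius: float, height: float, edge: float) -> np.ndarray:
    """Structured cylindrical point lattice: concentric rings per z layer."""
    n_ring = max(1, int(round(radius / edge)))
    n_layer = max(1, int(round(height / edge)))
    zs = np.linspace(0.0, height, n_layer + 1)
    pts = []
    for z in zs:
        pts.append([0.0, 0.0, z])
        for k in range(1, n_ring + 1):
            r = radius * k / n_ring
            m = max(6, int(round(2 * np.pi * r / edge)))
            ang = 2 * np.pi * np.arange(m) / m
            # stagger alternating rings for better-shaped triangles
            ang = ang + (np.pi / m) * (k % 2)
            ring = np.column_stack(
                [r * np.cos(ang), r * np.sin(ang), np.full(m, z)]
            )
            pts.append(ring)
    return np.vstack([np.atleast_2d(p) for p in pts])


def _target_cluster(target: TargetSpec) -> tuple[np.ndarray, np.ndarray]:
    """Local point cluster resolving the target.

    Inside points are placed so that their Voronoi cells, bounded by a
    surrounding shell of outside points, tile the target cylinder; this
    keeps the discretized fluorophore mass close to value x volume.
    Returns (points, is_inside_flag).
    """
    cx, cy, cz = target.center
    r, h = target.radius, target.height
    pts, inside = [], []

    def add_ring(rad, z, m, flag, phase=0.0):
        if m == 1:
            pts.append([cx, cy, z])
            inside.append(flag)
            return
        ang = 2 * np.pi * np.arange(m) / m + phase
        for a in ang:
            pts.append([cx + rad * np.cos(a), cy + rad * np.sin(a), z])
            inside.append(flag)

    z_in = [cz - h * 0.35, cz, cz + h * 0.35]
    for z in z_in:
        add_ring(0.0, z, 1, True)
        add_ring(0.6 * r, z, 6, True)
    # bounding shell just outside the target surface: Voronoi boundaries
    # fall at radius (0.6r+1.4r)/2 = r and height +-(0.35h+0.65h)/2 = h/2
    z_out = [cz - h * 0.65, cz + h * 0.65]
    for z in z_out:
        add_ring(0.0, z, 1, False)
        add_ring(0.6 * r, z, 6, False, phase=np.pi / 6)
    for z in z_in + [cz - h * 0.55, cz + h * 0.55]:
        add_ring(1.4 * r, z, 10, False, phase=np.pi / 10)
    return np.asarray(pts), np.asarray(inside, dtype=bool)


def build_cylindrical_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[Mesh, PropertyField, FluorophoreMap]:
    """Generate the heterogeneous cylindrical phantom.

    A structured cylindrical lattice (with a tiny deterministic jitter to
    break Delaunay degeneracies) is combined with a local cluster of
    points resolving the fluorescent target, then tetrahedralized with
    scipy's Delaunay (the cylinder is convex, so the triangulation fills
    it exactly).  Element regions are assigned by centroid membership in
    the organ ellipsoids; nodal fluorescence yield is ``target.value``
    inside the target cylinder and 0 elsewhere.
    """
    if spec is None:
        spec = PhantomSpec()

    lattice = _cylinder_lattice(spec.radius, spec.height, spec.edge_length)
    cluster, _ = _target_cluster(spec.target)

    # clear lattice points from the cluster neighbourhood so the local
    # Voronoi design is not disturbed
    cx, cy, cz = spec.target.center
    near = (
        np.hypot(lattice[:, 0] - cx, lattice[:, 1] - cy) < 2.0 * spec.target.radius
    ) & (np.abs(lattice[:, 2] - cz) < 1.1 * spec.target.height)
    lattice = lattice[~near]

    # deterministic jitter on lattice points only (breaks cocircular /
    # coplanar degeneracies in the Delaunay step); boundary points are
    # jittered tangentially+axially so the hull stays on the cylinder
    rng = np.random.default_rng(20130331)
    jitter = (rng.random(lattice.shape) - 0.5) * (2e-3 * spec.edge_length)
    rad = np.hypot(lattice[:, 0], lattice[:, 1])
    on_wall = np.isclose(rad, spec.radius)
    on_cap = np.isclose(lattice[:, 2], 0.0) | np.isclose(lattice[:, 2], spec.height)
    jitter[on_wall, :2] = 0.0
    jitter[on_cap, 2] = 0.0
    # the cluster is symmetric too; a jitter far below the containment
    # tolerance margin breaks its Delaunay degeneracies
    cjitter = (rng.random(cluster.shape) - 0.5) * (2e-4 * spec.target.radius)
    points = np.vstack([lattice + jitter, cluster + cjitter])

    tri = Delaunay(points)
    conn = tri.simplices
    # drop slivers of essentially zero volume that qhull may emit on the hull
    p = points[conn]
    vol = np.einsum(
        "ij,ij->i",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    ) / 6.0
    keep = np.abs(vol) > 1e-12 * spec.edge_length**3
    conn = conn[keep]

    centroids = points[conn].mean(axis=1)
    labels = np.zeros(len(conn), dtype=np.int64)
    for org in spec.organs:
        c = np.asarray(org.center)
        a = np.asarray(org.semi_axes)
        inside = np.sum(((centroids - c) / a) ** 2, axis=1) <= 1.0
        labels[inside & (labels == 0)] = org.label

    mesh = Mesh(points, conn, labels)
    props = PropertyField.from_tissue_table(spec.region_names(), n_rel=spec.n_rel)
    eta = np.where(spec.target.contains(points), spec.target.value, 0.0)
    fluor = FluorophoreMap(eta=eta, tau=spec.tau_ps)
    return mesh, props, fluor
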