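"""Rotation-stage acquisition geometry: sources per projection, detectors by FOV.

The specimen hangs on a rotation stage whose axis is the z axis; the
frame rotates in fixed angular increments (default 6 projections at
60°).  For each projection one excitation source illuminates the
surface, and detectors are boundary nodes on the opposite side within a
configurable angular field of view (default 120°) and z band.  Rotating
the source/detector frame around a fixed mesh is equivalent to rotating
the specimen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_model import GeometryError, Mesh

__all__ = ["ProjectionGeometry", "place_sources", "select_detectors", "build_pairs"]


@dataclass
class ProjectionGeometry:
    """Projection/FOV configuration of the rotation stage."""

    n_projections: int = 6
    angular_increment: float = 60.0
    source_height: float = 1.9
    fov_degrees: float = 120.0
    detector_zband: float = 0.75
    detectors_per_projection: int = 120

    def __post_init__(self) -> None:
        if abs(self.n_projections * self.angular_increment - 360.0) > 1e-9:
            raise GeometryError(
                "n_projections x angular_increment must equal 360 degrees"
            )
        if not (0.0 < self.fov_degrees <= 360.0):
            raise GeometryError("fov_degrees must lie in (0, 360]")


def _boundary_nodes(mesh: Mesh) -> np.ndarray:
    return np.unique(mesh.boundary_faces)


def _azimuth_deg(xy: np.ndarray) -> np.ndarray:
    return np.degrees(np.arctan2(xy[:, 1], xy[:, 0])) % 360.0


def place_sources(geometry: ProjectionGeometry, mesh: Mesh) -> np.ndarray:
    """Source surface points: one per projection at azimuth i*increment.

    Each point lies on the boundary at the configured source height,
    found as the boundary-face centroid closest to the requested
    azimuth/height ray.
    """
    face_c = mesh.node_coords[mesh.boundary_faces].mean(axis=1)
    # only lateral faces near the source plane are candidates
    band = np.abs(face_c[:, 2] - geometry.source_height) < max(
        0.5, 3 * np.median(np.abs(np.diff(np.sort(face_c[:, 2]))))
    )
    if not np.any(band):
        raise GeometryError("mesh boundary does not intersect the source plane")
    cand = face_c[band]
    az = _azimuth_deg(cand[:, :2])
    out = []
    for i in range(geometry.n_projections):
        want = (i * geometry.angular_increment) % 360.0
        dist = np.abs((az - want + 180.0) % 360.0 - 180.0)
        score = dist + 30.0 * np.abs(cand[:, 2] - geometry.source_height)
        j = int(np.argmin(score))
        if dist[j] > 3 * geometry.angular_increment:
            raise GeometryError(f"no boundary point near azimuth {want} deg")
        out.append(cand[j])
    return np.asarray(out)


def select_detectors(
    mesh: Mesh,
    source_point: np.ndarray,
    geometry: ProjectionGeometry,
) -> np.ndarray:
    """Boundary detector nodes opposite a source within the FOV.

    Nodes whose azimuth lies within ±fov/2 of the source's antipodal
    azimuth and within the z band are selected, then deterministically
    subsampled (uniform stride over azimuth-sorted candidates) to the
    requested per-projection count.
    """
    nodes = _boundary_nodes(mesh)
    coords = mesh.node_coords[nodes]
    lateral = np.hypot(coords[:, 0], coords[:, 1]) > 0.5 * np.max(
        np.hypot(coords[:, 0], coords[:, 1])
    )
    zband = np.abs(coords[:, 2] - geometry.source_height) <= geometry.detector_zband
    src_az = _azimuth_deg(np.atleast_2d(np.asarray(source_point)[:2]))[0]
    antipode = (src_az + 180.0) % 360.0
    az = _azimuth_deg(coords[:, :2])
    angdist = np.abs((az - antipode + 180.0) % 360.0 - 180.0)
    infov = angdist <= geometry.fov_degrees / 2.0
    mask = lateral & zband & infov
    if geometry.fov_degrees >= 360.0:
        mask = lateral & zband
    if not np.any(mask):
        raise GeometryError("empty detector selection for source")
    sel = nodes[mask]
    # deterministic ordering: azimuth-major, z-minor
    order = np.lexsort((coords[mask][:, 2], az[mask]))
    sel = sel[order]
    m = geometry.detectors_per_projection
    if m and len(sel) > m:
        idx = np.floor(np.linspace(0, len(sel) - 1, m)).astype(int)
        sel = sel[np.unique(idx)]
    return sel


def build_pairs(
    mesh: Mesh, geometry: ProjectionGeometry
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Sources and per-source detector node sets for the full scan."""
    sources = place_sources(geometry, mesh)
    detectors = [select_detectors(mesh, s, geometry) for s in sources]
    return sources, detectors
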