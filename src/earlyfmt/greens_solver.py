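"""Implicit time stepping for excitation and detector-adjoint Green's functions.

The time-domain diffusion system ``C dΦ/dt + K Φ = S(t)`` is advanced
with backward Euler:

    (K + C/Δt) G(k+1) = (C/Δt) G(k) + S(k),     G(-1) = G(0) = 0.

The matrix ``A = K + C/Δt`` is symmetric positive definite and shared by
every source, detector and time step, so it is factorized exactly once
(sparse LU) and reused — the "precompute the inversion" economy.
Detector-adjoint fields for many detectors are advanced as one
multi-column state, one time node at a time, then restructured into
per-detector node-by-time arrays.

Time convention: fields are stored as N x (T+1) arrays over the nodes
t_k = k*Δt, k = 0..T, with the k = 0 column identically zero.  The
excitation impulse is a unit nodal load applied in the first update, so
the first nonzero column is k = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem_assembly import SystemMatrices
from .mesh_model import GeometryError, InvalidPropertyError, Mesh, PropertyField

__all__ = [
    "TimeGrid",
    "make_time_grid",
    "Propagator",
    "GreensField",
    "SourceVector",
    "point_source_vector",
    "propagate",
    "batched_detector_fields",
    "lifetime_kernel",
]


class ConfigurationError(ValueError):
    pass


class NumericalFailureError(RuntimeError):
    pass


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid: nodes t_k = k*dt, k = 0..n_steps.

    ``gate_index`` is the index of the reconstruction gate (the early
    time node at which the linear system is formed).
    """

    dt: float
    n_steps: int
    gate_index: int

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if not (0 < self.gate_index <= self.n_steps):
            raise ConfigurationError("gate_index must lie in 1..n_steps")

    @property
    def n_nodes(self) -> int:
        """Stored time nodes including t=0."""
        return self.n_steps + 1

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_nodes)

    @property
    def gate_time(self) -> float:
        return self.gate_index * self.dt


def make_time_grid(dt: float, t_end: float, gate_time: float) -> TimeGrid:
    """Build a :class:`TimeGrid`, snapping the gate to the nearest node.

    A warning is emitted when the gate does not fall exactly on a node
    (it is snapped to ``round(gate_time/dt)``).
    """
    if dt <= 0 or gate_time <= 0:
        raise ConfigurationError("dt and gate_time must be positive")
    if gate_time > t_end + dt / 2:
        raise ConfigurationError("gate_time exceeds t_end")
    n_steps = int(round(t_end / dt))
    gate_index = int(round(gate_time / dt))
    snapped = gate_index * dt
    if abs(snapped - gate_time) > 1e-9 * dt:
        warnings.warn(
            f"gate time {gate_time} ps is not on the grid; snapped to {snapped} ps",
            stacklevel=2,
        )
    gate_index = min(max(gate_index, 1), n_steps)
    return TimeGrid(dt=dt, n_steps=n_steps, gate_index=gate_index)


class Propagator:
    """Reusable exact-solve handle for ``A = K + C/Δt`` plus ``C/Δt``.

    The expensive inversion work is always performed once, in double
    precision, and reused by every source, detector and time step;
    ``solve_count`` instruments the reuse.  Two application modes:

    * ``factorized`` (default): sparse LU; each solve is a pair of
      double-precision triangular solves.
    * ``dense_inverse``: the inverse is precomputed (in double) as a
      dense matrix, cast to the working dtype, and each "solve" becomes
      a single matrix multiplication in that dtype — the scheme used to
      push the per-time-node batched detector solves onto reduced-
      precision multiply hardware.
    """

    def __init__(
        self,
        system: SystemMatrices,
        dt: float,
        dtype=np.float64,
        dense_inverse: bool = False,
    ):
        self.dt = float(dt)
        self.dtype = np.dtype(dtype)
        self.dense_inverse = dense_inverse
        self.B = (system.C / dt).astype(self.dtype).tocsc()
        A = (system.K + system.C / dt).tocsc()
        self._lu = spla.splu(A.astype(np.float64))
        self._A = A.astype(self.dtype)
        self.n = A.shape[0]
        self.solve_count = 0
        self._inv = None
        if dense_inverse:
            eye = np.eye(self.n, dtype=np.float64)
            self._inv = np.ascontiguousarray(self._lu.solve(eye), dtype=self.dtype)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        self.solve_count += 1
        rhs = np.asarray(rhs, dtype=self.dtype)
        if self._inv is not None:
            return self._inv @ rhs
        return self._lu.solve(np.asarray(rhs, dtype=np.float64)).astype(
            self.dtype, copy=False
        )

    def residual_check(self, rhs: np.ndarray) -> float:
        """Relative residual of a solve (diagnostic)."""
        x = self._lu.solve(np.asarray(rhs, dtype=self.dtype))
        r = self._A @ x - rhs
        return float(np.linalg.norm(r) / max(np.linalg.norm(rhs), 1e-300))


@dataclass
class SourceVector:
    """Per-node load series.

    For an excitation delta the series is nonzero at exactly one node and
    one time step; emission sources carry a dense node x step array.
    ``values[:, k]`` is the load entering the update that produces the
    field at time node k+1.
    """

    values: np.ndarray  # (N, n_steps) dense or per-step provider output
    kind: Literal["excitation_delta", "emission"]
    anchor_node: int | None = None


@dataclass
class GreensField:
    """Nodal photon-density field, N x (T+1), column k at t = k*dt."""

    values: np.ndarray
    time_grid: TimeGrid
    kind: Literal["excitation", "emission", "detector_adjoint"]
    anchor: dict = field(default_factory=dict)

    @property
    def gate_values(self) -> np.ndarray:
        return self.values[:, self.time_grid.gate_index]


def point_source_vector(
    mesh: Mesh,
    surface_point: np.ndarray,
    props: PropertyField,
    time_grid: TimeGrid,
    kind: Literal["excitation", "detector_adjoint"] = "excitation",
) -> SourceVector:
    """Unit impulsive nodal load for a source (or detector-adjoint) point.

    The surface point is displaced one transport mean free path
    ``1/mu_s'`` along the inward surface normal, then snapped to the
    nearest mesh node; the load is 1 at that node in the first time step
    and 0 afterwards.
    """
    surface_point = np.asarray(surface_point, dtype=float)
    face_c = mesh.node_coords[mesh.boundary_faces].mean(axis=1)
    i_face = int(np.argmin(np.linalg.norm(face_c - surface_point, axis=1)))
    normal = mesh.face_normal[i_face]
    # reduced scattering of the region owning the nearest element
    _, mu_s_e, _ = props.element_arrays(mesh)
    cent = mesh.element_centroids()
    i_el = int(np.argmin(np.linalg.norm(cent - surface_point, axis=1)))
    depth = 1.0 / mu_s_e[i_el]
    interior = surface_point - depth * normal
    node = int(np.argmin(np.linalg.norm(mesh.node_coords - interior, axis=1)))
    if np.linalg.norm(mesh.node_coords[node] - interior) > 5 * depth:
        raise GeometryError("displaced source point is far from any mesh node")
    values = np.zeros((mesh.n_nodes, time_grid.n_steps))
    values[node, 0] = 1.0
    return SourceVector(values=values, kind="excitation_delta", anchor_node=node)


def propagate(
    propagator: Propagator,
    time_grid: TimeGrid,
    source: SourceVector,
    kind: Literal["excitation", "emission", "detector_adjoint"] = "excitation",
) -> GreensField:
    """Step the implicit scheme over the full grid for one source."""
    n = propagator.n
    T = time_grid.n_steps
    dtype = propagator.dtype
    out = np.zeros((n, T + 1), dtype=dtype)
    g = np.zeros(n, dtype=dtype)
    src = source.values
    for k in range(T):
        rhs = propagator.B @ g
        if src.ndim == 2:
            rhs = rhs + src[:, k].astype(dtype)
        g = propagator.solve(rhs)
        if not np.all(np.isfinite(g)):
            raise NumericalFailureError(f"non-finite field at time step {k + 1}")
        out[:, k + 1] = g
    anchor = {"node": source.anchor_node} if source.anchor_node is not None else {}
    return GreensField(values=out, time_grid=time_grid, kind=kind, anchor=anchor)


def batched_detector_fields(
    propagator: Propagator,
    time_grid: TimeGrid,
    detector_nodes: Sequence[int],
) -> list[GreensField]:
    """Detector-adjoint fields for many detectors, advanced jointly.

    A multi-column state (one column per unique detector) is advanced one
    time node at a time; the stacked result is then restructured into
    per-detector N x (T+1) fields.  Duplicate anchors are solved once and
    shared (a warning is emitted).
    """
    detector_nodes = list(int(d) for d in detector_nodes)
    unique = list(dict.fromkeys(detector_nodes))
    if len(unique) < len(detector_nodes):
        warnings.warn("duplicate detector anchor nodes; deduplicated", stacklevel=2)
    n = propagator.n
    T = time_grid.n_steps
    dtype = propagator.dtype
    m = len(unique)
    state = np.zeros((n, m), dtype=dtype)
    stacked = np.zeros((n, m, T + 1), dtype=dtype)
    impulse = np.zeros((n, m), dtype=dtype)
    impulse[unique, np.arange(m)] = 1.0
    for k in range(T):
        rhs = propagator.B @ state
        if k == 0:
            rhs = rhs + impulse
        state = propagator.solve(rhs)
        stacked[:, :, k + 1] = state
    by_node = {node: stacked[:, j, :] for j, node in enumerate(unique)}
    return [
        GreensField(
            values=by_node[node],
            time_grid=time_grid,
            kind="detector_adjoint",
            anchor={"node": node},
        )
        for node in detector_nodes
    ]


def lifetime_kernel(tau: float, time_grid: TimeGrid) -> np.ndarray:
    """Exponential decay ``E(t) = exp(-t/tau)`` sampled on the time nodes."""
    if tau <= 0:
        raise InvalidPropertyError("lifetime tau must be > 0")
    return np.exp(-time_grid.times / tau)
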