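"""Temporal convolution, Born weight matrices, and forward measurement synthesis.

The fluorescence measurement at a source-detector pair is, to first
Born order, a weighted integral of the nodal fluorescence yield eta:

    Phi_m(r_sd, t) = sum_n W(r_sd, n, t) eta_n,
    W(r_sd, r, t)  = G_s(r_s, r, t) * E(t) * G(r, r_d, t),

with ``*`` the causal temporal convolution and ``E(t) = exp(-t/tau)``
the fluorophore lifetime kernel.  Discretely the weight entries are
evaluated with the exact adjoint identity of the implicit time-stepping
scheme, so that ``W @ eta`` reproduces the fully coupled two-stage
simulation to rounding error (the model is exactly linear in eta).

The normalized Born system divides each pair's fluorescence datum by
the co-located excitation datum at the gate, cancelling source strength
and coupling heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp

from .greens_solver import (
    ConfigurationError,
    GreensField,
    Propagator,
    SourceVector,
    TimeGrid,
    propagate,
)
from .mesh_model import FluorophoreMap, InvalidPropertyError

__all__ = [
    "temporal_convolve",
    "convolve_rows",
    "MeasurementSet",
    "WeightSystem",
    "build_weight_matrix",
    "emission_source_series",
    "simulate_measurements",
    "normalized_born",
    "add_noise",
]

#: Pairs whose gated excitation falls below this fraction of the maximum
#: gated excitation are flagged unusable (early-gate validity floor).
DEFAULT_VALIDITY_FLOOR = 1e-9


class DegenerateSystemError(ValueError):
    pass


def temporal_convolve(a: np.ndarray, b: np.ndarray, dt: float) -> np.ndarray:
    """Causal discrete convolution ``out[k] = dt * sum_{j<=k} a[j] b[k-j]``.

    Both series must share length and time step; the output is truncated
    to the common length.  The accumulation is a plain sequential double
    sum (reproducible floating order).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("series must be 1-D with equal lengths")
    T = len(a)
    out = np.zeros(T)
    for k in range(T):
        s = 0.0
        for j in range(k + 1):
            s += a[j] * b[k - j]
        out[k] = dt * s
    return out


def convolve_rows(A: np.ndarray, e: np.ndarray, dt: float) -> np.ndarray:
    """Row-wise causal convolution of an (N, T) array with a kernel.

    Vectorized via a lower-triangular Toeplitz operator; used on the hot
    path where per-row floating order does not matter.
    """
    A = np.asarray(A)
    e = np.asarray(e, dtype=A.dtype)
    T = A.shape[1]
    idx = np.arange(T)
    L = np.where(idx[:, None] >= idx[None, :], e[np.abs(idx[:, None] - idx[None, :])], 0)
    return A.dtype.type(dt) * (A @ L.T)


@dataclass
class MeasurementSet:
    """Time-resolved excitation/fluorescence data per source-detector pair.

    ``pairs`` lists ``(source_index, detector_node)``; ``phix`` and
    ``phim`` are (P, T+1) series.  ``phix_gate``/``phim_gate`` hold the
    gated data actually fed to reconstruction — they start as the gate
    column of the series and are replaced by noisy copies by
    :func:`add_noise`.
    """

    pairs: list[tuple[int, int]]
    phix: np.ndarray
    phim: np.ndarray
    time_grid: TimeGrid
    phix_gate: np.ndarray = None  # type: ignore[assignment]
    phim_gate: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        g = self.time_grid.gate_index
        if self.phix_gate is None:
            self.phix_gate = self.phix[:, g].copy()
        if self.phim_gate is None:
            self.phim_gate = self.phim[:, g].copy()

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def normalized_gate(self, floor: float = DEFAULT_VALIDITY_FLOOR):
        """Gated normalized-Born data and the usable-pair mask."""
        ref = np.max(np.abs(self.phix_gate))
        usable = np.abs(self.phix_gate) > floor * ref
        out = np.zeros_like(self.phim_gate)
        out[usable] = self.phim_gate[usable] / self.phix_gate[usable]
        return out, usable


@dataclass
class WeightSystem:
    """Gated linear system ``W @ eta = b`` over usable pairs.

    ``weights`` rows are indexed by usable (source, detector) pairs and
    columns by mesh nodes.  ``pair_index`` maps rows back to the pair
    list; ``excluded`` records pairs dropped by the validity floor.
    """

    weights: np.ndarray
    rhs: np.ndarray
    pair_index: list[tuple[int, int]]
    excluded: list[tuple[int, int]]

    @property
    def n_rows(self) -> int:
        return self.weights.shape[0]


def build_weight_matrix(
    Gs: GreensField,
    Gd_set: Sequence[GreensField],
    E: np.ndarray,
    time_grid: TimeGrid,
    C: sp.spmatrix,
    c: float,
    tau: float,
    backend: Literal["accelerated", "reference"] = "accelerated",
) -> np.ndarray:
    """Gated Born weight rows for one source and its detectors.

    Each row (one per detector) holds, for every mesh node n,

        W[n] = (c/tau) * sum_{j=0..K} (Gs * E)[n, j] * (C @ Gd)[n, K-j]

    with K the gate index — the exact discrete counterpart of
    ``G_s * E * G_d`` with the mass matrix distributing the nodal
    emission density.  Rows over nodes are independent; the reference
    backend evaluates them node-by-node with :func:`temporal_convolve`,
    the accelerated backend with vectorized batched products.  Both
    agree to floating precision.
    """
    K = time_grid.gate_index
    values = Gs.values
    if K >= values.shape[1]:
        raise ConfigurationError("gate index beyond stored time nodes")
    dtype = values.dtype
    coeff = dtype.type(c / tau)
    dt = time_grid.dt
    rows = np.empty((len(Gd_set), values.shape[0]), dtype=dtype)
    if backend == "accelerated":
        GsE = convolve_rows(values, E.astype(dtype), dt)  # (N, T+1)
        GsE_g = GsE[:, : K + 1]
        for i, Gd in enumerate(Gd_set):
            CGd = C @ Gd.values[:, : K + 1]
            rows[i] = coeff * np.einsum("nj,nj->n", GsE_g, CGd[:, ::-1])
    elif backend == "reference":
        for i, Gd in enumerate(Gd_set):
            CGd = C @ Gd.values
            for n in range(values.shape[0]):
                gse = temporal_convolve(values[n], E, dt)
                s = 0.0
                for j in range(K + 1):
                    s += gse[j] * CGd[n, K - j]
                rows[i, n] = coeff * s
    else:
        raise ConfigurationError(f"unknown backend {backend!r}")
    return rows


def emission_source_series(
    eta_map: FluorophoreMap,
    Gx: GreensField,
    E: np.ndarray,
    C: sp.spmatrix,
    c: float,
    time_grid: TimeGrid,
) -> SourceVector:
    """Fluorescence emission load ``S_m(k) = C (c eta/tau * (G_x * E)(k))``.

    The excitation field convolved with the lifetime kernel drives the
    emission equation; the mass matrix distributes the nodal density
    into consistent FEM loads.
    """
    if eta_map.tau <= 0:
        raise InvalidPropertyError("lifetime tau must be > 0")
    dtype = Gx.values.dtype
    U = convolve_rows(Gx.values, E.astype(dtype), time_grid.dt)
    scale = (c / eta_map.tau) * eta_map.eta
    S = C @ (scale[:, None].astype(dtype) * U)
    return SourceVector(values=S[:, : time_grid.n_steps], kind="emission")


def simulate_measurements(
    propagator: Propagator,
    time_grid: TimeGrid,
    C: sp.spmatrix,
    c: float,
    sources: Sequence[SourceVector],
    detector_nodes_per_source: Sequence[Sequence[int]],
    eta_map: FluorophoreMap,
    excitation_fields: Sequence[GreensField] | None = None,
) -> tuple[MeasurementSet, list[GreensField]]:
    """Fully coupled two-stage forward simulation of gated measurements.

    For each source the excitation field is propagated, the emission
    load formed from ``eta``, and the emission field propagated; both
    fields are sampled at that source's detector anchor nodes across all
    time nodes.  Returns the measurement set and the excitation fields
    (reusable for weight-matrix construction).
    """
    from .greens_solver import lifetime_kernel

    E = lifetime_kernel(eta_map.tau, time_grid)
    pairs: list[tuple[int, int]] = []
    phix_rows, phim_rows = [], []
    gs_fields: list[GreensField] = []
    for i, src in enumerate(sources):
        if excitation_fields is not None:
            gx = excitation_fields[i]
        else:
            gx = propagate(propagator, time_grid, src, kind="excitation")
        gs_fields.append(gx)
        em = emission_source_series(eta_map, gx, E, C, c, time_grid)
        gm = propagate(propagator, time_grid, em, kind="emission")
        for d in detector_nodes_per_source[i]:
            pairs.append((i, int(d)))
            phix_rows.append(gx.values[int(d)])
            phim_rows.append(gm.values[int(d)])
    return (
        MeasurementSet(
            pairs=pairs,
            phix=np.array(phix_rows),
            phim=np.array(phim_rows),
            time_grid=time_grid,
        ),
        gs_fields,
    )


def normalized_born(
    weight_rows: np.ndarray,
    measurements: MeasurementSet,
    floor: float = DEFAULT_VALIDITY_FLOOR,
) -> WeightSystem:
    """Divide rows and data by the gated excitation per pair.

    Pairs whose gated excitation falls below ``floor`` times the maximum
    are flagged unusable and excluded (never silently dropped: they are
    listed in ``excluded``).
    """
    if weight_rows.shape[0] != measurements.n_pairs:
        raise ConfigurationError("one weight row per measurement pair required")
    b_all, usable = measurements.normalized_gate(floor)
    if not np.any(usable):
        raise DegenerateSystemError("all source-detector pairs below validity floor")
    W = weight_rows[usable] / measurements.phix_gate[usable, None]
    pair_index = [p for p, u in zip(measurements.pairs, usable) if u]
    excluded = [p for p, u in zip(measurements.pairs, usable) if not u]
    return WeightSystem(
        weights=W, rhs=b_all[usable], pair_index=pair_index, excluded=excluded
    )


def add_noise(
    measurements: MeasurementSet, level: float, seed: int
) -> MeasurementSet:
    """Proportional zero-mean Gaussian noise on the gated data.

    Each gated value v becomes ``v * (1 + level * z)`` with z standard
    normal; both measured channels (excitation and fluorescence) are
    perturbed.  Deterministic under a fixed seed.
    """
    if level < 0:
        raise ConfigurationError("noise level must be >= 0")
    rng = np.random.default_rng(seed)
    zx = rng.standard_normal(measurements.n_pairs)
    zm = rng.standard_normal(measurements.n_pairs)
    return replace(
        measurements,
        phix_gate=measurements.phix_gate * (1.0 + level * zx),
        phim_gate=measurements.phim_gate * (1.0 + level * zm),
    )
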