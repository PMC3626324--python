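"""Plain-text mesh I/O (TetGen, VTK legacy) and HDF5 field storage."""

from __future__ import annotations

import h5py
import numpy as np

from .greens_solver import GreensField, TimeGrid
from .forward_born import MeasurementSet
from .mesh_model import Mesh

__all__ = [
    "read_tetgen",
    "write_tetgen",
    "write_vtk",
    "save_greens",
    "load_greens",
    "save_measurements",
    "load_measurements",
]


class MeshIOError(IOError):
    pass


def _read_rows(path: str) -> list[list[str]]:
    try:
        with open(path) as fh:
            rows = []
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    rows.append(line.split())
            return rows
    except FileNotFoundError as exc:
        raise MeshIOError(f"missing mesh file: {path}") from exc


def read_tetgen(basename: str) -> Mesh:
    """Read a TetGen ``.node``/``.ele`` pair into a :class:`Mesh`.

    The index base declared by the files is honored; connectivity is
    stored 0-based internally.  Element attributes, when present, become
    region labels.
    """
    nrows = _read_rows(basename + ".node")
    n_nodes = int(nrows[0][0])
    body = nrows[1 : 1 + n_nodes]
    first_index = int(body[0][0])
    coords = np.array([[float(v) for v in r[1:4]] for r in body])

    erows = _read_rows(basename + ".ele")
    n_ele, _, n_attr = (int(v) for v in erows[0][:3])
    ebody = erows[1 : 1 + n_ele]
    conn = np.array([[int(v) for v in r[1:5]] for r in ebody]) - first_index
    if conn.min() < 0 or conn.max() >= n_nodes:
        raise MeshIOError(
            f"{basename}.ele references node index outside 0..{n_nodes - 1} "
            "after index-base normalization"
        )
    if n_attr >= 1:
        labels = np.array([int(float(r[5])) for r in ebody])
    else:
        labels = np.zeros(n_ele, dtype=np.int64)
    return Mesh(coords, conn, labels)


def write_tetgen(basename: str, mesh: Mesh) -> None:
    """Write ``.node``/``.ele`` files (0-based, region label as attribute)."""
    with open(basename + ".node", "w") as fh:
        fh.write(f"{mesh.n_nodes} 3 0 0\n")
        for i, (x, y, z) in enumerate(mesh.node_coords):
            fh.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
    with open(basename + ".ele", "w") as fh:
        fh.write(f"{mesh.n_elements} 4 1\n")
        for i, (tet, lbl) in enumerate(zip(mesh.tet_conn, mesh.region_label)):
            fh.write(f"{i} {tet[0]} {tet[1]} {tet[2]} {tet[3]} {lbl}\n")


def write_vtk(path: str, mesh: Mesh, point_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy ASCII VTK unstructured grid with optional nodal scalar arrays."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nearlyfmt field\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y, z in mesh.node_coords:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        m = mesh.n_elements
        fh.write(f"CELLS {m} {5 * m}\n")
        for tet in mesh.tet_conn:
            fh.write(f"4 {tet[0]} {tet[1]} {tet[2]} {tet[3]}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("\n".join(["10"] * m) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, values in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.17g}" for v in np.asarray(values)) + "\n")


_H5_OPTS = dict(track_times=False)


def save_greens(path: str, fields: list[GreensField]) -> None:
    with h5py.File(path, "w") as fh:
        for i, f in enumerate(fields):
            ds = fh.create_dataset(f"field_{i:04d}", data=f.values, **_H5_OPTS)
            ds.attrs["dt"] = f.time_grid.dt
            ds.attrs["gate_index"] = f.time_grid.gate_index
            ds.attrs["kind"] = f.kind
            ds.attrs["anchor_node"] = f.anchor.get("node", -1)


def load_greens(path: str) -> list[GreensField]:
    out = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            ds = fh[name]
            values = ds[()]
            tg = TimeGrid(
                dt=float(ds.attrs["dt"]),
                n_steps=values.shape[1] - 1,
                gate_index=int(ds.attrs["gate_index"]),
            )
            anchor_node = int(ds.attrs["anchor_node"])
            out.append(
                GreensField(
                    values=values,
                    time_grid=tg,
                    kind=str(ds.attrs["kind"]),
                    anchor={} if anchor_node < 0 else {"node": anchor_node},
                )
            )
    return out


def save_measurements(path: str, ms: MeasurementSet) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("pairs", data=np.asarray(ms.pairs, dtype=np.int64), **_H5_OPTS)
        for name in ("phix", "phim", "phix_gate", "phim_gate"):
            fh.create_dataset(name, data=getattr(ms, name), **_H5_OPTS)
        fh.attrs["dt"] = ms.time_grid.dt
        fh.attrs["gate_index"] = ms.time_grid.gate_index


def load_measurements(path: str) -> MeasurementSet:
    with h5py.File(path, "r") as fh:
        pairs = [tuple(int(v) for v in row) for row in fh["pairs"][()]]
        phix = fh["phix"][()]
        tg = TimeGrid(
            dt=float(fh.attrs["dt"]),
            n_steps=phix.shape[1] - 1,
            gate_index=int(fh.attrs["gate_index"]),
        )
        return MeasurementSet(
            pairs=pairs,
            phix=phix,
            phim=fh["phim"][()],
            time_grid=tg,
            phix_gate=fh["phix_gate"][()],
            phim_gate=fh["phim_gate"][()],
        )
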