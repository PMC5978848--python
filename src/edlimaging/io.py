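"""Readers and writers for the standard interchange formats.

Meshes travel as PLY (through trimesh) or legacy-ASCII VTK polydata so real
patient geometries can be substituted for the synthetic ones; electrode
coordinates and activation maps as CSV; transfer matrices and BSPMs as HDF5
with their metadata; study configurations as a single YAML or JSON document.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import trimesh
import yaml

from .bem import TransferMatrix
from .geometry import TriangleSurface
from .sources import BSPM


# -- meshes ------------------------------------------------------------------

def write_ply(surface: TriangleSurface, path: str | Path) -> None:
    mesh = trimesh.Trimesh(vertices=surface.vertices, faces=surface.faces,
                           process=False)
    Path(path).write_bytes(trimesh.exchange.ply.export_ply(
        mesh, encoding="ascii"))


def read_ply(path: str | Path, label: str = "") -> TriangleSurface:
    mesh = trimesh.load(str(path), file_type="ply", process=False)
    return TriangleSurface(np.asarray(mesh.vertices),
                           np.asarray(mesh.faces),
                           label or Path(path).stem)


def write_vtk(surface: TriangleSurface, path: str | Path,
              point_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy ASCII VTK polydata, optionally with per-vertex scalars."""
    v, f = surface.vertices, surface.faces
    lines = ["# vtk DataFile Version 3.0", surface.label or "surface",
             "ASCII", "DATASET POLYDATA", f"POINTS {len(v)} float"]
    lines += [" ".join(f"{x:.9g}" for x in row) for row in v]
    lines.append(f"POLYGONS {len(f)} {4 * len(f)}")
    lines += ["3 " + " ".join(str(int(i)) for i in row) for row in f]
    if point_data:
        lines.append(f"POINT_DATA {len(v)}")
        for name, values in point_data.items():
            values = np.asarray(values, float)
            if len(values) != len(v):
                raise ValueError(f"scalar {name!r} length mismatch")
            lines += [f"SCALARS {name} float 1", "LOOKUP_TABLE default"]
            lines += [f"{x:.9g}" for x in values]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path: str | Path) -> tuple[TriangleSurface, dict[str, np.ndarray]]:
    toks = Path(path).read_text().split()
    def find(kw):
        return toks.index(kw)
    i = find("POINTS")
    n = int(toks[i + 1])
    v = np.array(toks[i + 3:i + 3 + 3 * n], float).reshape(n, 3)
    i = find("POLYGONS")
    m = int(toks[i + 1])
    raw = np.array(toks[i + 3:i + 3 + 4 * m], int).reshape(m, 4)
    if not np.all(raw[:, 0] == 3):
        raise ValueError("only triangle polydata is supported")
    data: dict[str, np.ndarray] = {}
    j = 0
    while True:
        try:
            j = toks.index("SCALARS", j)
        except ValueError:
            break
        name = toks[j + 1]
        k = toks.index("default", j) + 1
        data[name] = np.array(toks[k:k + n], float)
        j = k + n
    return TriangleSurface(v, raw[:, 1:], Path(path).stem), data


# -- tabular -----------------------------------------------------------------

def write_electrodes_csv(coords: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(coords, columns=["x", "y", "z"]).to_csv(path, index=False)


def read_electrodes_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)[["x", "y", "z"]].to_numpy(float)


def write_activation_csv(tau: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"node": np.arange(len(tau)), "tau_ms": tau}
                 ).to_csv(path, index=False)


def read_activation_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path).sort_values("node")
    return df["tau_ms"].to_numpy(float)


def write_bspm_csv(bspm: BSPM, path: str | Path) -> None:
    cols = [f"t{t:g}" for t in bspm.times]
    pd.DataFrame(bspm.potentials, columns=cols).to_csv(path, index=False)


# -- HDF5 --------------------------------------------------------------------

def save_transfer(transfer: TransferMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=transfer.matrix)
        f.create_dataset("electrodes", data=transfer.electrodes)
        f.attrs["scale"] = transfer.scale
        f.attrs["meta"] = json.dumps(transfer.meta)


def load_transfer(path: str | Path) -> TransferMatrix:
    with h5py.File(path, "r") as f:
        return TransferMatrix(f["matrix"][()], f["electrodes"][()],
                              float(f.attrs["scale"]),
                              json.loads(f.attrs.get("meta", "{}")))


def save_bspm(bspm: BSPM, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("potentials", data=bspm.potentials)
        f.create_dataset("times", data=bspm.times)
        f.attrs["dt"] = bspm.dt
        f.attrs["zero_mean"] = bspm.zero_mean
        meta = {k: v for k, v in bspm.meta.items()
                if isinstance(v, (str, int, float, bool))}
        f.attrs["meta"] = json.dumps(meta)


def load_bspm(path: str | Path) -> BSPM:
    with h5py.File(path, "r") as f:
        return BSPM(f["potentials"][()], f["times"][()],
                    dt=float(f.attrs["dt"]),
                    zero_mean=bool(f.attrs["zero_mean"]),
                    meta=json.loads(f.attrs.get("meta", "{}")))


# -- configuration -----------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Study configuration from one YAML or JSON document."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def save_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))
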