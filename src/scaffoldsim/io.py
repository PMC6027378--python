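"""Field and trajectory export: VTK (legacy ASCII), CSV, HDF5.

The VTK writer emits STRUCTURED_POINTS legacy files readable by ParaView
and friends; floats are formatted with a fixed repr so identical inputs
produce byte-identical files (apart from nothing — no timestamps are
embedded).  Every artifact records the config hash passed by the caller.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import VoxelDomain

__all__ = ["export_domain_vtk", "export_fields_vtk", "export_domain_csv",
           "export_trajectory_csv", "export_state_h5", "import_state_h5"]

_FMT = "%.9e"


def _vtk_header(fh, domain: VoxelDomain, comment: str):
    nx, ny, nz = domain.shape
    hx, hy, hz = domain.spacing_um
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{comment}\n")
    fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
    fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
    fh.write("ORIGIN 0 0 0\n")
    fh.write(f"SPACING {hx:.9g} {hy:.9g} {hz:.9g}\n")
    fh.write(f"CELL_DATA {nx * ny * nz}\n")


def _write_scalar(fh, name, arr, fmt=_FMT):
    fh.write(f"SCALARS {name} {'int' if arr.dtype.kind == 'i' else 'float'}"
             " 1\nLOOKUP_TABLE default\n")
    flat = arr.transpose(2, 1, 0).ravel()  # VTK is z-major for x-fastest
    if arr.dtype.kind == "i":
        fh.write("\n".join(str(int(v)) for v in flat) + "\n")
    else:
        fh.write("\n".join(fmt % v for v in flat) + "\n")


def _write_vector(fh, name, arr):
    fh.write(f"VECTORS {name} float\n")
    flat = arr.transpose(2, 1, 0, 3).reshape(-1, 3)
    fh.write("\n".join(" ".join(_FMT % c for c in row) for row in flat)
             + "\n")


def export_domain_vtk(domain: VoxelDomain, path, config_hash="") -> Path:
    """Phase-label field as a VTK structured-points file."""
    path = Path(path)
    with open(path, "w") as fh:
        _vtk_header(fh, domain, f"scaffoldsim domain config={config_hash}")
        _write_scalar(fh, "phase", domain.labels.astype(np.int32))
    return path


def export_fields_vtk(domain: VoxelDomain, path, state=None, flow=None,
                      tau=None, config_hash="") -> Path:
    """Culture and flow fields on the voxel grid as VTK."""
    path = Path(path)
    with open(path, "w") as fh:
        _vtk_header(fh, domain, f"scaffoldsim fields config={config_hash}")
        _write_scalar(fh, "phase", domain.labels.astype(np.int32))
        if state is not None:
            _write_scalar(fh, "glucose_kg_m3", state.c_gf)
            _write_scalar(fh, "lactate_kg_m3", state.c_l)
            _write_scalar(fh, "eps_c", state.eps_c)
        if flow is not None:
            _write_scalar(fh, "pressure_Pa", flow.pressure)
            _write_vector(fh, "velocity_m_s", flow.velocity)
        if tau is not None:
            _write_scalar(fh, "shear_Pa", tau)
    return path


def export_domain_csv(domain: VoxelDomain, path, config_hash="") -> Path:
    """Voxel table: 0-based indices, center coordinates [um], phase label."""
    path = Path(path)
    nx, ny, nz = domain.shape
    cx, cy, cz = domain.cell_centers_um()
    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    df = pd.DataFrame({
        "i": I.ravel(), "j": J.ravel(), "k": K.ravel(),
        "x_um": cx[I.ravel()], "y_um": cy[J.ravel()], "z_um": cz[K.ravel()],
        "label": domain.labels.ravel()})
    with open(path, "w") as fh:
        fh.write(f"# scaffoldsim domain config={config_hash}\n")
        df.to_csv(fh, index=False)
    return path


def export_trajectory_csv(diag: pd.DataFrame, path, config_hash="") -> Path:
    """Per-step diagnostics (time, means, extrema, budgets)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# scaffoldsim trajectory config={config_hash}\n")
        diag.to_csv(fh, index=False)
    return path


def export_state_h5(path, domain: VoxelDomain, states, config_hash="",
                    times=None) -> Path:
    """Lossless HDF5 container for a trajectory of culture states."""
    path = Path(path)
    states = list(states)
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash
        f.attrs["spacing_um"] = domain.spacing_um
        f.create_dataset("labels", data=domain.labels)
        for i, s in enumerate(states):
            g = f.create_group(f"step_{i:05d}")
            g.attrs["t"] = s.t
            g.attrs["glucose_consumed"] = s.glucose_consumed
            g.attrs["lactate_produced"] = s.lactate_produced
            g.create_dataset("c_gf", data=s.c_gf)
            g.create_dataset("c_l", data=s.c_l)
            g.create_dataset("eps_c", data=s.eps_c)
    return path


def import_state_h5(path):
    """Read back an HDF5 trajectory: (labels, spacing_um, list of dicts)."""
    with h5py.File(path, "r") as f:
        labels = f["labels"][...]
        spacing = tuple(f.attrs["spacing_um"])
        steps = []
        for key in sorted(k for k in f.keys() if k.startswith("step_")):
            g = f[key]
            steps.append({
                "t": float(g.attrs["t"]),
                "glucose_consumed": float(g.attrs["glucose_consumed"]),
                "lactate_produced": float(g.attrs["lactate_produced"]),
                "c_gf": g["c_gf"][...], "c_l": g["c_l"][...],
                "eps_c": g["eps_c"][...]})
    return labels, spacing, steps
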