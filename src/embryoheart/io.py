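"""File interfaces: VTU/VTP meshes, TIFF cine stacks, CSV tables, YAML config.

The VTU/VTP writers emit plain ASCII XML (UnstructuredGrid / PolyData),
which ParaView and meshio read directly; a matching minimal reader supports
round-trip tests.  Cine stacks go to multi-page TIFF with a JSON sidecar
carrying the acquisition metadata.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import FEMesh

__all__ = [
    "write_vtu",
    "read_vtu",
    "write_vtp_points",
    "write_cine_stack",
    "read_cine_stack",
    "write_ensemble_tiff",
    "write_displacements_csv",
    "write_strain_curve_csv",
    "write_thickness_csv",
    "write_pv_csv",
    "write_stress_summary_csv",
    "write_waveform_csv",
    "read_waveform_csv",
    "write_mpa_csv",
    "read_mpa_csv",
    "load_config",
]

_VTK_TET4 = 10
_VTK_TET10 = 24


def _ascii(a: np.ndarray, fmt="{:.10g}") -> str:
    return " ".join(fmt.format(v) for v in np.asarray(a).ravel())


def write_vtu(
    path,
    mesh: FEMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    displacement: np.ndarray | None = None,
) -> None:
    """Write the mesh (optionally deformed) as an ASCII VTU file."""
    nodes = mesh.nodes if displacement is None else mesh.nodes + displacement
    n_pts, n_cells = len(nodes), mesh.n_elems
    nen = mesh.elems.shape[1]
    ctype = _VTK_TET10 if nen == 10 else _VTK_TET4
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _ascii(nodes),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _ascii(mesh.elems, "{:d}"),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _ascii(np.arange(1, n_cells + 1) * nen, "{:d}"),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        _ascii(np.full(n_cells, ctype), "{:d}"),
        "</DataArray>",
        "</Cells>",
    ]
    pdata = dict(point_data or {})
    if mesh.fiber is not None and "fiber" not in pdata:
        pdata["fiber"] = mesh.fiber
    lines.append("<PointData>")
    for name, arr in pdata.items():
        arr = np.asarray(arr)
        nc = 1 if arr.ndim == 1 else arr.shape[1]
        lines += [
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{nc}" format="ascii">',
            _ascii(arr),
            "</DataArray>",
        ]
    lines.append("</PointData>")
    lines.append("<CellData>")
    for name, arr in (cell_data or {}).items():
        arr = np.asarray(arr)
        nc = 1 if arr.ndim == 1 else int(np.prod(arr.shape[1:]))
        lines += [
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{nc}" format="ascii">',
            _ascii(arr),
            "</DataArray>",
        ]
    lines.append("</CellData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def read_vtu(path):
    """Minimal ASCII VTU reader: returns (nodes, elems, point_data)."""
    root = ET.parse(str(path)).getroot()
    piece = root.find(".//Piece")
    pts = piece.find("Points/DataArray")
    nodes = np.fromstring(pts.text, sep=" ").reshape(-1, 3)
    conn = off = None
    for da in piece.find("Cells"):
        if da.get("Name") == "connectivity":
            conn = np.fromstring(da.text, sep=" ", dtype=np.int64)
        elif da.get("Name") == "offsets":
            off = np.fromstring(da.text, sep=" ", dtype=np.int64)
    nen = off[0]
    elems = conn.reshape(-1, nen)
    point_data = {}
    pd_el = piece.find("PointData")
    if pd_el is not None:
        for da in pd_el:
            nc = int(da.get("NumberOfComponents", "1"))
            arr = np.fromstring(da.text, sep=" ")
            point_data[da.get("Name")] = arr.reshape(-1, nc) if nc > 1 else arr
    return nodes, elems, point_data


def write_vtp_points(path, points: np.ndarray, point_data=None) -> None:
    """Point cloud (e.g. analysis layer with principal directions) as VTP."""
    points = np.asarray(points)
    n = len(points)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">',
        "<PolyData>",
        f'<Piece NumberOfPoints="{n}" NumberOfVerts="{n}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _ascii(points),
        "</DataArray>",
        "</Points>",
        "<Verts>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _ascii(np.arange(n), "{:d}"),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _ascii(np.arange(1, n + 1), "{:d}"),
        "</DataArray>",
        "</Verts>",
        "<PointData>",
    ]
    for name, arr in (point_data or {}).items():
        arr = np.asarray(arr)
        nc = 1 if arr.ndim == 1 else arr.shape[1]
        lines += [
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{nc}" format="ascii">',
            _ascii(arr),
            "</DataArray>",
        ]
    lines += ["</PointData>", "</Piece>", "</PolyData>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# cine stacks
# ---------------------------------------------------------------------------


def write_cine_stack(path_stem, stack) -> None:
    """One multi-page TIFF per plane plus a JSON metadata sidecar.

    ``path_stem`` like ``out/cine`` produces ``cine_plane00.tif`` ... and
    ``cine_meta.json``.
    """
    import tifffile

    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "frame_interval_ms": stack.frame_interval,
        "plane_spacing_um": stack.plane_spacing,
        "pixel_size_um": stack.pixel_size,
        "plane_z_mm": list(map(float, stack.plane_z)),
        "phase_offsets_ms": None
        if stack.plane_phase is None
        else list(map(float, stack.plane_phase)),
    }
    for k, frames in enumerate(stack.planes):
        tifffile.imwrite(
            f"{stem}_plane{k:02d}.tif", np.asarray(frames, dtype=np.float32)
        )
    Path(f"{stem}_meta.json").write_text(json.dumps(meta, indent=1))


def read_cine_stack(path_stem):
    import tifffile

    from .cine import CineStack

    stem = Path(path_stem)
    meta = json.loads(Path(f"{stem}_meta.json").read_text())
    planes = []
    k = 0
    while Path(f"{stem}_plane{k:02d}.tif").exists():
        planes.append(tifffile.imread(f"{stem}_plane{k:02d}.tif"))
        k += 1
    return CineStack(
        planes=planes,
        frame_interval=meta["frame_interval_ms"],
        plane_spacing=meta["plane_spacing_um"],
        pixel_size=meta["pixel_size_um"],
        plane_z=np.array(meta["plane_z_mm"]),
        plane_phase=None
        if meta["phase_offsets_ms"] is None
        else np.array(meta["phase_offsets_ms"]),
    )


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------


def write_waveform_csv(path, waveform) -> None:
    pd.DataFrame({"time_ms": waveform.times, "volume_mm3": waveform.volumes}).to_csv(
        path, index=False
    )


def read_waveform_csv(path):
    from .calibration import VolumeWaveform

    df = pd.read_csv(path)
    return VolumeWaveform(
        times=df["time_ms"].to_numpy(), volumes=df["volume_mm3"].to_numpy()
    )


def write_mpa_csv(path, pressures_mmhg, lengths_um) -> None:
    pd.DataFrame(
        {"pressure_mmHg": pressures_mmhg, "aspirated_length_um": lengths_um}
    ).to_csv(path, index=False)


def read_mpa_csv(path):
    df = pd.read_csv(path)
    return df["pressure_mmHg"].to_numpy(), df["aspirated_length_um"].to_numpy()


def write_ensemble_tiff(path_stem, ensemble) -> None:
    """Arithmetic/quadratic ensemble cycles as multi-page TIFFs."""
    import tifffile

    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        f"{stem}_arithmetic.tif", np.asarray(ensemble.arithmetic, dtype=np.float32)
    )
    tifffile.imwrite(
        f"{stem}_quadratic.tif", np.asarray(ensemble.quadratic, dtype=np.float32)
    )


def write_displacements_csv(path, fields) -> None:
    """Block-matching displacement fields as one CSV.

    ``fields`` maps (plane, phase) -> the dict returned by
    :func:`embryoheart.cine.estimate_displacements`.
    """
    rows = []
    for (plane, phase), d in fields.items():
        for k in range(len(d["x"])):
            rows.append(
                dict(
                    x=d["x"][k], y=d["y"][k], plane=plane, phase=phase,
                    ux=d["ux"][k], uy=d["uy"][k], confidence=d["confidence"][k],
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_strain_curve_csv(path, phases, mean_strain, chamber="LV") -> None:
    pd.DataFrame(
        {"phase_ms": phases, "mean_e_min": mean_strain, "chamber": chamber}
    ).to_csv(path, index=False)


def write_thickness_csv(path, report) -> None:
    pd.DataFrame(
        {
            "sample_mm": report.samples,
            "chamber": report.chamber,
            "seed": report.seed,
        }
    ).to_csv(path, index=False)


def write_pv_csv(path, cycle_result) -> None:
    """Pressure-volume trace of a simulated cycle."""
    pd.DataFrame(
        {
            "time_ms": cycle_result.times,
            "pressure_Pa": cycle_result.pressures,
            "volume_mm3": cycle_result.volumes,
        }
    ).to_csv(path, index=False)


def write_stress_summary_csv(path, summary) -> None:
    pd.DataFrame(
        {
            "time_ms": summary.times,
            "frobenius_mean_Pa": summary.frobenius_mean,
            "projected_mean_Pa": summary.projected_mean,
        }
    ).to_csv(path, index=False)


def load_config(path) -> dict:
    """Run configuration (generator specs, solver settings) from YAML."""
    with open(path) as fh:
        return yaml.safe_load(fh)
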