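"""Mesh and table I/O.

PLY is the interchange format for labeled meshes: binary little-endian, with
an optional per-triangle integer property ``cell_label`` and optional
per-vertex float properties (e.g. ``gaussian_curvature``).  Plain meshes can
also be read through trimesh (PLY/OBJ/...).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import trimesh

from .geometry import CurvatureField, SurfaceMesh
from .segmentation import CellSegmentation

__all__ = [
    "write_labeled_ply",
    "read_labeled_ply",
    "load_mesh",
    "cell_table",
    "curvature_table",
]


def load_mesh(path) -> SurfaceMesh:
    """Read a PLY/OBJ mesh (any trimesh-supported format)."""
    tm = trimesh.load(str(path), process=False, force="mesh")
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def write_labeled_ply(
    path,
    mesh: SurfaceMesh,
    segmentation: CellSegmentation | None = None,
    vertex_props: dict[str, np.ndarray] | None = None,
) -> None:
    """Binary little-endian PLY with optional labels and vertex properties."""
    vertex_props = vertex_props or {}
    n_v, n_f = mesh.n_vertices, mesh.n_faces
    header = ["ply", "format binary_little_endian 1.0",
              f"element vertex {n_v}",
              "property float x", "property float y", "property float z"]
    for name in vertex_props:
        header.append(f"property float {name}")
    header.append(f"element face {n_f}")
    header.append("property list uchar int vertex_indices")
    if segmentation is not None:
        header.append("property int cell_label")
    header.append("end_header")

    vdata = [mesh.vertices.astype("<f4")]
    for name, arr in vertex_props.items():
        a = np.asarray(arr, dtype="<f4").reshape(-1, 1)
        if len(a) != n_v:
            raise ValueError(f"vertex property {name!r} has wrong length")
        vdata.append(a)
    vblock = np.hstack(vdata).astype("<f4").tobytes()

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(vblock)
        labels = (segmentation.triangle_labels
                  if segmentation is not None else None)
        faces = mesh.faces.astype("<i4")
        if labels is None:
            counts = np.full((n_f, 1), 3, dtype="u1")
            rec = np.zeros(n_f, dtype=[("c", "u1"), ("v", "<i4", 3)])
            rec["c"] = 3
            rec["v"] = faces
            fh.write(rec.tobytes())
        else:
            rec = np.zeros(
                n_f, dtype=[("c", "u1"), ("v", "<i4", 3), ("l", "<i4")])
            rec["c"] = 3
            rec["v"] = faces
            rec["l"] = np.asarray(labels, dtype="<i4")
            fh.write(rec.tobytes())


def read_labeled_ply(path):
    """Read a PLY written by :func:`write_labeled_ply`.

    Returns ``(mesh, segmentation_or_None, vertex_props)``.
    """
    with open(path, "rb") as fh:
        header_lines = []
        while True:
            line = fh.readline().decode("ascii").strip()
            header_lines.append(line)
            if line == "end_header":
                break
        n_v = n_f = 0
        vprops: list[str] = []
        face_props: list[str] = []
        element = None
        for line in header_lines:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "format" and parts[1] != "binary_little_endian":
                raise ValueError("only binary little-endian PLY supported")
            if parts[0] == "element":
                element = parts[1]
                if element == "vertex":
                    n_v = int(parts[2])
                else:
                    n_f = int(parts[2])
            elif parts[0] == "property" and element == "vertex":
                if parts[1] != "float":
                    raise ValueError("vertex properties must be float")
                vprops.append(parts[2])
            elif (parts[0] == "property" and element == "face"
                  and parts[1] != "list"):
                face_props.append(parts[2])
        vblock = np.frombuffer(fh.read(4 * len(vprops) * n_v),
                               dtype="<f4").reshape(n_v, len(vprops))
        face_dtype = [("c", "u1"), ("v", "<i4", 3)]
        for name in face_props:
            face_dtype.append((name, "<i4"))
        rec = np.frombuffer(fh.read(), dtype=face_dtype, count=n_f)
    vertices = vblock[:, :3].astype(np.float64)
    extra = {name: vblock[:, 3 + i].astype(np.float64)
             for i, name in enumerate(vprops[3:])}
    mesh = SurfaceMesh(vertices, rec["v"].astype(np.int64))
    seg = None
    if "cell_label" in face_props:
        seg = CellSegmentation(rec["cell_label"].astype(np.int64))
    return mesh, seg, extra


def cell_table(mesh: SurfaceMesh, segmentation: CellSegmentation,
               region=None, zones=None, mean_k=None) -> pd.DataFrame:
    """One row per cell: id, area, centroid, and optional region/zone/K."""
    areas = segmentation.cell_areas(mesh)
    cents = segmentation.cell_centroids(mesh)
    rows = []
    for c in sorted(areas):
        row = {"cell_id": c, "area_um2": areas[c],
               "centroid_x": cents[c][0], "centroid_y": cents[c][1],
               "centroid_z": cents[c][2]}
        if region is not None:
            row["in_region"] = c in region.cell_ids
            row["is_boundary"] = c in region.boundary_cells
        if zones is not None and c in zones.rings:
            row["ring"] = zones.rings[c]
            row["zone"] = zones.zone(c)
        if mean_k is not None:
            row["mean_gaussian_curvature"] = mean_k.get(c, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def curvature_table(mesh: SurfaceMesh, curvature: CurvatureField
                    ) -> pd.DataFrame:
    """Per-vertex curvature CSV payload."""
    return pd.DataFrame({
        "vertex": np.arange(mesh.n_vertices),
        "x": mesh.vertices[:, 0],
        "y": mesh.vertices[:, 1],
        "z": mesh.vertices[:, 2],
        "gaussian_curvature": curvature.K,
        "defined": curvature.defined,
    })
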