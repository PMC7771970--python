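"""Epidermal surface extraction and cell segmentation.

The analysis is 2.5D: from a cell-wall-stain stack the outer (L1) surface is
extracted as a height map (one height per lateral position, no overhangs),
the wall signal just below the surface is projected onto the mesh, and cells
are obtained by a seeded watershed of that projected field over the mesh
vertex graph — so cell areas are measured on the curved surface, not on a
flat projection.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import SurfaceMesh, heightmap_mesh
from .volume import VolumeStack

__all__ = [
    "CellSegmentation",
    "build_cell_graph",
    "extract_surface",
    "project_wall_signal",
    "segment_cells",
]


class SurfaceExtractionError(RuntimeError):
    """Raised when a stack does not contain a recognizable surface."""


@dataclass
class CellSegmentation:
    """Partition of a mesh into labeled epidermal cells.

    ``triangle_labels`` maps each mesh triangle to a positive cell label
    (0 = unassigned); ``vertex_labels`` is the vertex-level counterpart the
    watershed produces.  Each label's triangles form one edge-connected
    patch; label 0 is ignored by every area computation.
    """

    triangle_labels: np.ndarray
    vertex_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.triangle_labels = np.asarray(self.triangle_labels, dtype=np.int64)
        if self.vertex_labels is not None:
            self.vertex_labels = np.asarray(self.vertex_labels, dtype=np.int64)

    @property
    def labels(self) -> np.ndarray:
        """Sorted positive labels present."""
        u = np.unique(self.triangle_labels)
        return u[u > 0]

    def cell_areas(self, mesh: SurfaceMesh) -> dict[int, float]:
        """Surface area per cell, µm²."""
        lab = self.triangle_labels
        out: dict[int, float] = {}
        areas = mesh.triangle_areas
        order = np.argsort(lab, kind="stable")
        sl = lab[order]
        sa = areas[order]
        bounds = np.searchsorted(sl, np.unique(sl))
        uniq = np.unique(sl)
        for i, u in enumerate(uniq):
            if u <= 0:
                continue
            hi = bounds[i + 1] if i + 1 < len(bounds) else len(sl)
            out[int(u)] = float(sa[bounds[i]:hi].sum())
        return out

    def cell_centroids(self, mesh: SurfaceMesh) -> dict[int, np.ndarray]:
        """Area-weighted 3D centroid per cell."""
        lab = self.triangle_labels
        w = mesh.triangle_areas
        centers = mesh.vertices[mesh.faces].mean(axis=1)
        out: dict[int, np.ndarray] = {}
        for u in self.labels:
            sel = lab == u
            out[int(u)] = np.average(centers[sel], axis=0, weights=w[sel])
        return out


def triangle_labels_from_vertices(faces: np.ndarray,
                                  vertex_labels: np.ndarray) -> np.ndarray:
    """Majority vote of a triangle's three vertex labels (tie -> smallest)."""
    fl = vertex_labels[faces]  # (m, 3)
    fl_sorted = np.sort(fl, axis=1)
    out = fl_sorted[:, 0].copy()
    # if the two larger agree they outvote the smallest
    pair = fl_sorted[:, 1] == fl_sorted[:, 2]
    out[pair] = fl_sorted[pair, 1]
    return out


# ---------------------------------------------------------------------------
# surface extraction
# ---------------------------------------------------------------------------

def extract_surface(stack: VolumeStack, threshold: float) -> SurfaceMesh:
    """Extract the outer surface of a stack as a height-map mesh.

    For each (x, y) column the topmost voxel above ``threshold`` defines the
    height (quantized at the z step); the height map is 3×3 median-filtered
    and triangulated on the pixel grid.  Columns with no voxel above the
    threshold are filled from their neighbors, but if more than half of all
    columns are empty the stack is rejected as containing no surface.
    """
    a = np.asarray(stack.intensities)
    if a.size == 0:
        raise SurfaceExtractionError("empty stack")
    dz, dy, dx = stack.voxel_size
    above = a > threshold
    any_above = above.any(axis=0)
    frac_empty = 1.0 - any_above.mean()
    if frac_empty > 0.5:
        raise SurfaceExtractionError(
            f"no voxel above threshold in {frac_empty:.0%} of columns; "
            "not a surface")
    nz = a.shape[0]
    # topmost = highest z index above threshold
    top = nz - 1 - np.argmax(above[::-1], axis=0)
    top = np.where(any_above, top, -1)
    if (top < 0).any():
        # fill holes from nearest valid column
        yy, xx = ndimage.distance_transform_edt(
            top < 0, return_distances=False, return_indices=True)
        top = top[yy, xx]
    heights = top.astype(np.float64) * dz
    heights = ndimage.median_filter(heights, size=3, mode="nearest")
    return heightmap_mesh(heights, dy, dx)


# ---------------------------------------------------------------------------
# signal projection along inward normals
# ---------------------------------------------------------------------------

def sample_band_along_normals(
    stack: VolumeStack,
    mesh: SurfaceMesh,
    band: tuple[float, float],
    aggregate: str = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate stack intensity along each vertex's inward normal.

    Samples at steps of half the smallest voxel dimension across
    ``band = (d_min, d_max)`` µm below the surface, with trilinear
    interpolation; returns ``(values, valid)`` where ``valid`` is False for
    vertices whose ray leaves the stack (those are flagged, not zeroed).
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must satisfy band_min < band_max")
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    dz, dy, dx = stack.voxel_size
    step = 0.5 * min(stack.voxel_size)
    depths = np.arange(lo, hi + 0.5 * step, step)
    inward = -mesh.vertex_normals  # outward normals have +z mean
    # (n, k, 3) sample points in µm
    pts = mesh.vertices[:, None, :] + depths[None, :, None] * inward[:, None, :]
    coords = np.empty((3, pts.shape[0], pts.shape[1]))
    coords[0] = pts[..., 2] / dz
    coords[1] = pts[..., 1] / dy
    coords[2] = pts[..., 0] / dx
    shape = np.array(stack.shape)
    inside = ((coords >= 0) & (coords <= (shape - 1)[:, None, None])).all(axis=0)
    valid = inside.all(axis=1)
    sampled = ndimage.map_coordinates(
        np.asarray(stack.intensities, dtype=np.float64),
        coords.reshape(3, -1), order=1, mode="nearest",
    ).reshape(pts.shape[0], pts.shape[1])
    if aggregate == "mean":
        values = sampled.mean(axis=1)
    else:
        values = sampled.max(axis=1)
    return values, valid


def project_wall_signal(
    stack: VolumeStack,
    mesh: SurfaceMesh,
    band: tuple[float, float] = (0.0, 4.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Mean wall-stain intensity 0–4 µm below the surface, per vertex.

    Returns ``(values, valid)``; invalid vertices (normal exits the stack)
    must be excluded from the watershed.
    """
    return sample_band_along_normals(stack, mesh, band, aggregate="mean")


# ---------------------------------------------------------------------------
# watershed over the mesh vertex graph
# ---------------------------------------------------------------------------

def _vertex_adjacency(mesh: SurfaceMesh):
    """CSR-style neighbor arrays (offsets, neighbors) for mesh vertices."""
    e = mesh.edges
    n = mesh.n_vertices
    src = np.r_[e[:, 0], e[:, 1]]
    dst = np.r_[e[:, 1], e[:, 0]]
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    offsets = np.searchsorted(src, np.arange(n + 1))
    return offsets, dst


def _graph_watershed(offsets, nbrs, field, seed_vertices, mask):
    """Priority-flood watershed; deterministic given seeds and field."""
    n = len(field)
    labels = np.zeros(n, dtype=np.int64)
    heap = []
    counter = 0
    for lab, sv in enumerate(seed_vertices, start=1):
        labels[sv] = lab
        heap.append((field[sv], counter, int(sv), lab))
        counter += 1
    heapq.heapify(heap)
    while heap:
        _, _, v, lab = heapq.heappop(heap)
        for u in nbrs[offsets[v]:offsets[v + 1]]:
            if labels[u] == 0 and mask[u]:
                labels[u] = lab
                heapq.heappush(heap, (field[u], counter, int(u), lab))
                counter += 1
    return labels


def _reconstruction_by_erosion(offsets, nbrs, marker, mask_img):
    """Morphological reconstruction by erosion on a vertex graph.

    marker >= mask everywhere; the result is the largest image <= marker ...
    conceptually: low values propagate uphill until blocked by ``mask_img``.
    Used for h-minima suppression.
    """
    recon = marker.astype(np.float64).copy()
    heap = [(recon[i], i) for i in range(len(recon))]
    heapq.heapify(heap)
    while heap:
        val, v = heapq.heappop(heap)
        if val > recon[v]:
            continue
        for u in nbrs[offsets[v]:offsets[v + 1]]:
            cand = max(mask_img[u], recon[v])
            if cand < recon[u]:
                recon[u] = cand
                heapq.heappush(heap, (cand, int(u)))
    return recon


def _regional_minima_seeds(offsets, nbrs, field, mask):
    """One seed vertex (lowest index) per regional-minimum plateau."""
    n = len(field)
    visited = np.zeros(n, dtype=bool)
    seeds = []
    for v in range(n):
        if visited[v] or not mask[v]:
            continue
        # flood the equal-value plateau containing v
        plateau = [v]
        visited[v] = True
        is_min = True
        stack = [v]
        val = field[v]
        while stack:
            w = stack.pop()
            for u in nbrs[offsets[w]:offsets[w + 1]]:
                if not mask[u]:
                    continue
                if field[u] == val and not visited[u]:
                    visited[u] = True
                    plateau.append(int(u))
                    stack.append(int(u))
                elif field[u] < val:
                    is_min = False
        if is_min:
            seeds.append(min(plateau))
    return seeds


def segment_cells(
    mesh: SurfaceMesh,
    wall_signal: np.ndarray,
    seeds: np.ndarray | None = None,
    min_cell_area: float = 4.0,
    valid: np.ndarray | None = None,
    h_rel: float = 0.10,
    seed_refine_radius: float = 1.5,
) -> CellSegmentation:
    """Seeded watershed of the projected wall signal over the vertex graph.

    ``seeds`` are 3D points snapped to the nearest vertex and then refined
    to the lowest wall-signal vertex within ``seed_refine_radius`` µm (a
    marker that lands on a wall ridge would otherwise flood a degenerate
    basin).  Without seeds, regional minima of the wall field after
    h-minima suppression (h = ``h_rel`` of the field's dynamic range) are
    used.  Segments smaller than ``min_cell_area`` µm² (watershed slivers)
    are merged into the neighbor with the longest shared boundary.  Label
    *i*+1 corresponds to seed *i*, which downstream ground-truth
    comparisons rely on.
    """
    wall_signal = np.asarray(wall_signal, dtype=np.float64)
    if valid is None:
        valid = np.ones(mesh.n_vertices, dtype=bool)
    if valid.mean() < 0.9:
        raise ValueError("wall signal defined on fewer than 90% of vertices")
    offsets, nbrs = _vertex_adjacency(mesh)
    if seeds is not None and len(seeds) > 0:
        tree = cKDTree(mesh.vertices)
        seed_vertices = tree.query(np.atleast_2d(np.asarray(seeds, float)))[1]
        seed_vertices = np.asarray(seed_vertices, dtype=np.int64).ravel()
        if seed_refine_radius > 0:
            refined = []
            taken = set()
            field = np.where(valid, wall_signal, np.inf)
            for sv in seed_vertices:
                ball = tree.query_ball_point(mesh.vertices[sv],
                                             seed_refine_radius)
                ball = np.sort(np.asarray(ball, dtype=np.int64))
                best = int(sv)
                if len(ball):
                    for cand in ball[np.argsort(field[ball], kind="stable")]:
                        if int(cand) not in taken:
                            best = int(cand)
                            break
                refined.append(best)
                taken.add(best)
            seed_vertices = np.asarray(refined, dtype=np.int64)
    else:
        f = np.where(valid, wall_signal, wall_signal[valid].max())
        # find seeds on a lightly smoothed field: sampling jitter on the
        # extracted surface ripples cell interiors and would split basins
        fs = f.copy()
        e = mesh.edges
        deg = np.zeros(len(fs))
        np.add.at(deg, e[:, 0], 1.0)
        np.add.at(deg, e[:, 1], 1.0)
        for _ in range(2):
            acc = fs.copy()
            np.add.at(acc, e[:, 0], fs[e[:, 1]])
            np.add.at(acc, e[:, 1], fs[e[:, 0]])
            fs = acc / (deg + 1.0)
        h = h_rel * (fs[valid].max() - fs[valid].min())
        recon = _reconstruction_by_erosion(offsets, nbrs, fs + h, fs)
        seed_vertices = _regional_minima_seeds(offsets, nbrs, recon, valid)
        if len(seed_vertices) == 0:
            raise ValueError("no watershed seeds found")
    vertex_labels = _graph_watershed(offsets, nbrs, wall_signal,
                                     seed_vertices, valid)
    tri_labels = triangle_labels_from_vertices(mesh.faces, vertex_labels)
    seg = CellSegmentation(tri_labels, vertex_labels)
    if min_cell_area > 0:
        seg = _merge_small_cells(mesh, seg, min_cell_area)
    return seg


def _shared_boundary_lengths(mesh: SurfaceMesh, tri_labels: np.ndarray):
    """Length of the boundary between each adjacent label pair."""
    tm = mesh._tm
    fa = tm.face_adjacency
    fe = tm.face_adjacency_edges
    la, lb = tri_labels[fa[:, 0]], tri_labels[fa[:, 1]]
    diff = la != lb
    if not diff.any():
        return {}
    lengths = np.linalg.norm(
        mesh.vertices[fe[diff, 0]] - mesh.vertices[fe[diff, 1]], axis=1)
    pairs = np.sort(np.column_stack([la[diff], lb[diff]]), axis=1)
    out: dict[tuple[int, int], float] = {}
    for (p, q), L in zip(map(tuple, pairs), lengths):
        out[(int(p), int(q))] = out.get((int(p), int(q)), 0.0) + float(L)
    return out


def _merge_small_cells(mesh: SurfaceMesh, seg: CellSegmentation,
                       min_cell_area: float) -> CellSegmentation:
    tri = seg.triangle_labels.copy()
    vert = None if seg.vertex_labels is None else seg.vertex_labels.copy()
    while True:
        areas = CellSegmentation(tri).cell_areas(mesh)
        small = sorted(l for l, a in areas.items() if a < min_cell_area)
        if not small:
            break
        shared = _shared_boundary_lengths(mesh, tri)
        merged_any = False
        target_label = small[0]
        best, best_len = None, -1.0
        for (p, q), L in shared.items():
            other = q if p == target_label else p if q == target_label else None
            if other is not None and L > best_len:
                best, best_len = other, L
        if best is None:
            break  # isolated sliver with no neighbor; keep it
        tri[tri == target_label] = best
        if vert is not None:
            vert[vert == target_label] = best
        merged_any = True
        if not merged_any:
            break
    return CellSegmentation(tri, vert)


def build_cell_graph(segmentation: CellSegmentation,
                     mesh: SurfaceMesh) -> nx.Graph:
    """Cell-adjacency graph: edge iff two labels share >=1 mesh edge."""
    g = nx.Graph()
    g.add_nodes_from(int(l) for l in segmentation.labels)
    tm = mesh._tm
    fa = tm.face_adjacency
    la = segmentation.triangle_labels[fa[:, 0]]
    lb = segmentation.triangle_labels[fa[:, 1]]
    sel = (la != lb) & (la > 0) & (lb > 0)
    g.add_edges_from(
        (int(p), int(q))
        for p, q in np.unique(
            np.sort(np.column_stack([la[sel], lb[sel]]), axis=1), axis=0)
    )
    return g
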