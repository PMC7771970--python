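"""Meristem delimitation, zonation, and per-apex quantification.

The meristem is the region between the developing primordia; its boundary is
delimited by negative Gaussian curvature: starting from the central (summit)
cell, cells are flooded over the adjacency graph while their area-weighted
mean curvature stays non-negative, and the first K < 0 cells encountered form
the (excluded) saddle boundary.  Zones follow cell-graph distance from the
central cell: rings 0–2 are the central zone (CZ), rings 3–5 the surrounding
peripheral ring (PZ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .geometry import CurvatureField, SurfaceMesh
from .segmentation import CellSegmentation

__all__ = [
    "MeristemRegion",
    "ZoneAssignment",
    "Primordium",
    "MorphometricRecord",
    "delimit_meristem",
    "find_central_cell",
    "assign_zones",
    "summarize_apex",
    "locate_primordia",
    "predict_incipient_positions",
    "cell_mean_curvature",
]


class DelimitationError(RuntimeError):
    """Raised when no meristem can be delimited (e.g. saddle at the summit)."""


@dataclass(frozen=True)
class Primordium:
    """An existing (P_n) or predicted incipient (i_n) primordium.

    ``age_rank`` is n: P_1 is the youngest existing primordium (smallest
    bump), larger n is older/larger.  Azimuth is degrees in [0, 360) about
    the apex (+z) axis.
    """

    id: str
    centroid: np.ndarray
    azimuth: float
    age_rank: int
    area: float = float("nan")

    def __post_init__(self):
        object.__setattr__(self, "centroid",
                           np.asarray(self.centroid, dtype=np.float64))
        object.__setattr__(self, "azimuth", float(self.azimuth) % 360.0)


@dataclass
class MeristemRegion:
    """Delimited meristem: cell set, summit cell, saddle boundary, area."""

    cell_ids: frozenset[int]
    central_cell: int
    boundary_cells: frozenset[int]
    area: float
    cell_count: int

    def __post_init__(self):
        self.cell_ids = frozenset(int(c) for c in self.cell_ids)
        self.boundary_cells = frozenset(int(c) for c in self.boundary_cells)
        if self.central_cell not in self.cell_ids:
            raise ValueError("central cell not in region")
        if not self.boundary_cells.isdisjoint(self.cell_ids):
            raise ValueError("boundary cells must be excluded from the region")
        if self.cell_count != len(self.cell_ids):
            raise ValueError("cell_count inconsistent with cell_ids")


@dataclass
class ZoneAssignment:
    """Ring distance from the central cell and CZ/PZ zone labels."""

    rings: dict[int, int]
    cz_max: int = 2
    pz_max: int = 5

    def zone(self, cell: int) -> str:
        r = self.rings[cell]
        if r <= self.cz_max:
            return "CZ"
        if r <= self.pz_max:
            return "PZ_ring"
        return "outside"


@dataclass
class MorphometricRecord:
    """Per-apex summary: meristem area, cell number, cell-area statistics."""

    apex_id: str
    genotype: str
    condition: str
    meristem_area: float
    cell_number: int
    cell_areas: dict[int, float]
    zone_of: dict[int, str] = field(default_factory=dict)

    @property
    def median_cell_area(self) -> float:
        return float(np.median(list(self.cell_areas.values())))

    @property
    def mean_cell_area(self) -> float:
        return float(np.mean(list(self.cell_areas.values())))

    def zone_summary(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for zone in ("CZ", "PZ_ring"):
            vals = [a for c, a in self.cell_areas.items()
                    if self.zone_of.get(c) == zone]
            if vals:
                out[zone] = {"median": float(np.median(vals)),
                             "mean": float(np.mean(vals)),
                             "n": len(vals)}
        return out


# ---------------------------------------------------------------------------

def cell_mean_curvature(mesh: SurfaceMesh, segmentation: CellSegmentation,
                        curvature: CurvatureField) -> dict[int, float]:
    """Area-weighted mean of defined vertex K within each cell.

    Vertex weights are barycentric vertex areas; vertices with undefined K
    are left out of both numerator and denominator.  A cell with no defined
    vertex maps to NaN.
    """
    if segmentation.vertex_labels is None:
        raise ValueError("segmentation lacks vertex labels")
    lab = segmentation.vertex_labels
    w = np.where(curvature.defined, mesh.vertex_areas, 0.0)
    kw = np.where(curvature.defined, np.nan_to_num(curvature.K) * w, 0.0)
    nmax = int(lab.max()) + 1
    num = np.bincount(lab, weights=kw, minlength=nmax)
    den = np.bincount(lab, weights=w, minlength=nmax)
    out = {}
    for c in segmentation.labels:
        out[int(c)] = float(num[c] / den[c]) if den[c] > 0 else float("nan")
    return out


def find_central_cell(mesh: SurfaceMesh, segmentation: CellSegmentation,
                      axis=(0.0, 0.0, 1.0)) -> int:
    """Cell containing the summit vertex (max coordinate along ``axis``).

    Ties are broken by the lowest vertex index; vertices without a positive
    label are skipped.
    """
    if segmentation.vertex_labels is None:
        raise ValueError("segmentation lacks vertex labels")
    proj = mesh.vertices @ np.asarray(axis, dtype=np.float64)
    order = np.argsort(-proj, kind="stable")  # stable -> lowest index wins ties
    for idx in order:
        lab = segmentation.vertex_labels[idx]
        if lab > 0:
            return int(lab)
    raise ValueError("segmentation has no labeled vertex")


def delimit_meristem(
    mesh: SurfaceMesh,
    segmentation: CellSegmentation,
    curvature: CurvatureField,
    graph: nx.Graph,
    central: int,
    include_boundary: bool = False,
) -> MeristemRegion:
    """Flood-fill the meristem from the summit through K >= 0 cells.

    The first K < 0 cells encountered are the saddle boundary; they are
    excluded from the region by default (``include_boundary=True`` counts
    them in, for sensitivity analyses).  Cells with undefined curvature are
    treated as boundary-like barriers.  Raises :class:`DelimitationError`
    if the central cell itself sits on negative curvature.
    """
    mean_k = cell_mean_curvature(mesh, segmentation, curvature)
    if central not in mean_k:
        raise KeyError(f"central cell {central} not in segmentation")
    if not math.isfinite(mean_k[central]) or mean_k[central] < 0:
        raise DelimitationError(
            "central cell has negative or undefined curvature; no meristem")
    region = {central}
    boundary = set()
    frontier = [central]
    while frontier:
        nxt = []
        for c in frontier:
            for nb in graph.neighbors(c):
                if nb in region or nb in boundary:
                    continue
                k = mean_k.get(nb, float("nan"))
                if math.isfinite(k) and k >= 0:
                    region.add(nb)
                    nxt.append(nb)
                else:
                    boundary.add(nb)
        frontier = nxt
    if include_boundary:
        region |= boundary
        boundary = set()
    areas = segmentation.cell_areas(mesh)
    return MeristemRegion(
        cell_ids=frozenset(region),
        central_cell=central,
        boundary_cells=frozenset(boundary),
        area=float(sum(areas[c] for c in region)),
        cell_count=len(region),
    )


def assign_zones(graph: nx.Graph, region: MeristemRegion,
                 cz_max: int = 2, pz_max: int = 5) -> ZoneAssignment:
    """Ring = BFS distance from the central cell within the region."""
    sub = graph.subgraph(region.cell_ids)
    rings = nx.single_source_shortest_path_length(sub, region.central_cell)
    return ZoneAssignment(dict(rings), cz_max, pz_max)


def summarize_apex(
    mesh: SurfaceMesh,
    segmentation: CellSegmentation,
    region: MeristemRegion,
    zones: ZoneAssignment | None = None,
    apex_id: str = "apex",
    genotype: str = "Col-0",
    condition: str = "",
) -> MorphometricRecord:
    """Meristem area, cell number, and per-cell areas of the region."""
    areas = segmentation.cell_areas(mesh)
    cell_areas = {c: areas[c] for c in sorted(region.cell_ids)}
    zone_of = {}
    if zones is not None:
        zone_of = {c: zones.zone(c) for c in cell_areas if c in zones.rings}
    return MorphometricRecord(
        apex_id=apex_id,
        genotype=genotype,
        condition=condition,
        meristem_area=region.area,
        cell_number=region.cell_count,
        cell_areas=cell_areas,
        zone_of=zone_of,
    )


def locate_primordia(
    mesh: SurfaceMesh,
    segmentation: CellSegmentation,
    curvature: CurvatureField,
    region: MeristemRegion,
    graph: nx.Graph | None = None,
    min_area: float = 40.0,
    k_min: float = 5e-4,
    k_peak: float = 2e-3,
) -> list[Primordium]:
    """Detect developing primordia as K > 0 bumps outside the meristem.

    Connected components (over the cell graph) of cells with mean curvature
    above ``k_min`` (1/µm²; excludes the near-flat far field) lying outside
    the region and its saddle boundary, with total area >= ``min_area`` and
    peak cell curvature >= ``k_peak``, are primordia.  The peak criterion
    rejects shallow positive ripples the estimator produces where the
    saddle flattens out, which are an order of magnitude weaker than any
    organ bump.  P_1 is the smallest (youngest) bump; ``age_rank`` grows
    with bump area.  Azimuths are measured about the apex axis through the
    summit cell centroid.
    """
    if graph is None:
        from .segmentation import build_cell_graph
        graph = build_cell_graph(segmentation, mesh)
    mean_k = cell_mean_curvature(mesh, segmentation, curvature)
    excluded = region.cell_ids | region.boundary_cells
    cand = [c for c, k in mean_k.items()
            if c not in excluded and math.isfinite(k) and k > k_min]
    sub = graph.subgraph(cand)
    areas = segmentation.cell_areas(mesh)
    centroids = segmentation.cell_centroids(mesh)
    center_xy = centroids[region.central_cell][:2]
    comps = []
    for comp in nx.connected_components(sub):
        area = sum(areas[c] for c in comp)
        if area < min_area or max(mean_k[c] for c in comp) < k_peak:
            continue
        cen = np.average([centroids[c] for c in comp], axis=0,
                         weights=[areas[c] for c in comp])
        d = cen[:2] - center_xy
        azim = math.degrees(math.atan2(d[1], d[0])) % 360.0
        comps.append((area, cen, azim))
    comps.sort(key=lambda t: t[0])  # youngest (smallest) first
    return [
        Primordium(id=f"P_{i+1}", centroid=cen, azimuth=azim,
                   age_rank=i + 1, area=area)
        for i, (area, cen, azim) in enumerate(comps)
    ]


def predict_incipient_positions(
    primordia: list[Primordium],
    divergence: float = 137.5,
    k: int = 2,
    boundary_radius: float | None = None,
) -> list[Primordium]:
    """Golden-angle extrapolation of future primordium positions.

    i_n is placed at the azimuth of the youngest existing primordium plus
    n × divergence (mod 360); radially at ``boundary_radius`` from the apex
    axis when given, else at the youngest primordium's radius.
    """
    if not primordia:
        raise ValueError("at least one existing primordium is required")
    youngest = min(primordia, key=lambda p: p.age_rank)
    r = boundary_radius
    if r is None:
        r = float(np.hypot(*youngest.centroid[:2]))
    out = []
    for n in range(1, k + 1):
        az = (youngest.azimuth + n * divergence) % 360.0
        cen = np.array([r * math.cos(math.radians(az)),
                        r * math.sin(math.radians(az)), 0.0])
        out.append(Primordium(id=f"i_{n}", centroid=cen, azimuth=az,
                              age_rank=-n))
    return out
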