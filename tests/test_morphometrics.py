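"""Meristem delimitation, zonation, summaries, and primordium logic."""

from collections import deque

import numpy as np
import pytest

from meristemorph.geometry import CurvatureField, SurfaceMesh, heightmap_mesh
from meristemorph.morphometrics import (DelimitationError, Primordium,
                                        assign_zones, delimit_meristem,
                                        find_central_cell, locate_primordia,
                                        predict_incipient_positions,
                                        summarize_apex)
from meristemorph.segmentation import (CellSegmentation, build_cell_graph,
                                       triangle_labels_from_vertices)

from conftest import ALL_PRESETS, SEEDS, make_grid_mesh


def bfs_rings_oracle(graph, source, allowed):
    """Hand-rolled breadth-first rings, independent of networkx."""
    rings = {source: 0}
    q = deque([source])
    while q:
        c = q.popleft()
        for nb in graph.neighbors(c):
            if nb in allowed and nb not in rings:
                rings[nb] = rings[c] + 1
                q.append(nb)
    return rings


def spherical_cap_cells(r=30.0, step=0.5):
    """Pure spherical cap (K>0 everywhere) partitioned into angular sectors."""
    half = 0.75 * r
    n = int(2 * half / step) + 1
    x, y = np.meshgrid(np.linspace(-half, half, n),
                       np.linspace(-half, half, n))
    z = np.sqrt(np.maximum(r * r - x * x - y * y, 0.0))
    mesh = heightmap_mesh(z, step, step, origin=(-half, -half))
    rr = np.hypot(mesh.vertices[:, 0], mesh.vertices[:, 1])
    az = np.degrees(np.arctan2(mesh.vertices[:, 1], mesh.vertices[:, 0]))
    lab = np.where(rr < 8.0, 1, 2 + (az.astype(int) + 180) // 60)
    tri = triangle_labels_from_vertices(mesh.faces, lab)
    return mesh, CellSegmentation(tri, lab.astype(np.int64))


class TestDelimitation:
    @pytest.mark.parametrize("preset,seed",
                             [("vegetative", 1), ("domed", 1)])
    def test_pipeline_jaccard_with_truth(self, analyses, scenes, preset,
                                         seed):
        an = analyses(preset, seed)
        det = set(an.region.cell_ids)
        tru = set(scenes(preset, seed).true_region)
        jac = len(det & tru) / len(det | tru)
        assert jac >= 0.90

    @pytest.mark.parametrize("preset", ALL_PRESETS)
    def test_detected_area_within_10pct_of_truth(self, truth_products,
                                                 preset):
        tp = truth_products(preset, 1)
        assert (tp.region.area / tp.scene.true_region_area()
                == pytest.approx(1.0, abs=0.10))

    def test_spherical_cap_without_primordia_keeps_all_cells(self):
        from meristemorph.geometry import gaussian_curvature
        mesh, seg = spherical_cap_cells()
        curv = gaussian_curvature(mesh, radius=10.0)
        graph = build_cell_graph(seg, mesh)
        central = find_central_cell(mesh, seg)
        region = delimit_meristem(mesh, seg, curv, graph, central)
        assert region.cell_ids == frozenset(int(l) for l in seg.labels)
        assert not region.boundary_cells

    def test_negative_curvature_summit_raises(self, hex_cells):
        mesh, seg, center = hex_cells
        graph = build_cell_graph(seg, mesh)
        curv = CurvatureField(np.full(mesh.n_vertices, -1e-3),
                              np.ones(mesh.n_vertices, dtype=bool))
        with pytest.raises(DelimitationError):
            delimit_meristem(mesh, seg, curv, graph, center)

    def test_region_noise_stability(self, truth_products):
        """±5%-of-range curvature noise moves the detected area < 5%."""
        tp = truth_products("vegetative", 1)
        K = tp.curvature.K
        rng_span = np.nanmax(K) - np.nanmin(K)
        rng = np.random.default_rng(11)
        noisy = CurvatureField(
            K + rng.normal(0, 0.05 * rng_span, len(K)),
            tp.curvature.defined, tp.curvature.neighborhood_radius)
        sc = tp.scene
        region = delimit_meristem(sc.mesh, sc.true_segmentation, noisy,
                                  tp.graph, tp.central)
        assert region.area == pytest.approx(tp.region.area, rel=0.05)

    def test_include_boundary_toggle_grows_region(self, truth_products):
        tp = truth_products("narrow_meristem", 1)
        sc = tp.scene
        grown = delimit_meristem(sc.mesh, sc.true_segmentation,
                                 tp.curvature, tp.graph, tp.central,
                                 include_boundary=True)
        assert grown.cell_ids >= tp.region.cell_ids
        assert not grown.boundary_cells


class TestCentralCell:
    @pytest.mark.parametrize("preset", ALL_PRESETS)
    @pytest.mark.parametrize("seed", SEEDS)
    def test_matches_generator_truth(self, scenes, preset, seed):
        sc = scenes(preset, seed)
        assert (find_central_cell(sc.mesh, sc.true_segmentation)
                == sc.true_central_cell)

    def test_translation_invariance(self, scenes):
        sc = scenes("narrow_meristem", 1)
        moved = SurfaceMesh(sc.mesh.vertices + np.array([50.0, -20.0, 7.0]),
                            sc.mesh.faces)
        assert (find_central_cell(moved, sc.true_segmentation)
                == sc.true_central_cell)

    def test_tie_broken_by_lowest_vertex_index(self):
        v = np.array([[0, 0, 1.0], [1, 0, 1.0], [0, 1, 0.0], [1, 1, 0.0]])
        f = np.array([[0, 1, 2], [1, 3, 2]])
        mesh = SurfaceMesh(v, f)
        seg = CellSegmentation(np.array([1, 2]),
                               np.array([5, 9, 5, 9]))
        # vertices 0 and 1 tie at z=1; vertex 0 (label 5) must win
        assert find_central_cell(mesh, seg) == 5


class TestZones:
    def test_central_cell_is_ring_zero_cz(self, truth_products):
        tp = truth_products("vegetative", 1)
        zones = assign_zones(tp.graph, tp.region)
        assert zones.rings[tp.region.central_cell] == 0
        assert zones.zone(tp.region.central_cell) == "CZ"

    def test_hexagonal_rings_have_6k_cells(self, hex_cells):
        mesh, seg, center = hex_cells
        graph = build_cell_graph(seg, mesh)
        rings = bfs_rings_oracle(graph, center, set(graph.nodes))
        for k in (1, 2, 3):
            assert sum(1 for r in rings.values() if r == k) == 6 * k

    def test_rings_match_brute_force_bfs(self, truth_products):
        tp = truth_products("narrow_meristem", 1)   # 60-cell region
        zones = assign_zones(tp.graph, tp.region)
        oracle = bfs_rings_oracle(tp.graph, tp.region.central_cell,
                                  tp.region.cell_ids)
        assert zones.rings == oracle

    def test_adjacent_ring_difference_at_most_one(self, truth_products):
        tp = truth_products("vegetative", 1)
        zones = assign_zones(tp.graph, tp.region)
        for a, b in tp.graph.subgraph(tp.region.cell_ids).edges:
            assert abs(zones.rings[a] - zones.rings[b]) <= 1

    def test_enlarging_cz_never_shrinks_it(self, truth_products):
        tp = truth_products("vegetative", 1)
        prev = set()
        for cz_max in (1, 2, 3, 4):
            zones = assign_zones(tp.graph, tp.region, cz_max=cz_max)
            cz = {c for c in tp.region.cell_ids
                  if c in zones.rings and zones.zone(c) == "CZ"}
            assert cz >= prev
            prev = cz


class TestSummaries:
    def test_cell_number_equals_region_size(self, analyses):
        an = analyses("vegetative", 1)
        assert an.record.cell_number == len(an.region.cell_ids)

    def test_uniform_tessellation_zone_medians(self, hex_cells):
        mesh, seg, center = hex_cells
        graph = build_cell_graph(seg, mesh)
        areas = seg.cell_areas(mesh)
        interior = [c for c in graph.nodes if graph.degree[c] == 6]
        from meristemorph.morphometrics import MeristemRegion
        region_cells = {c for c in interior}
        region_cells.add(center)
        # restrict to a connected interior patch around the center
        rings = bfs_rings_oracle(graph, center, region_cells)
        cells = {c for c, r in rings.items() if r <= 3}
        region = MeristemRegion(
            cell_ids=frozenset(cells), central_cell=center,
            boundary_cells=frozenset(),
            area=sum(areas[c] for c in cells), cell_count=len(cells))
        zones = assign_zones(graph, region)
        rec = summarize_apex(mesh, seg, region, zones)
        nominal = 5.0 ** 2 * np.sqrt(3) / 2  # hex lattice cell area
        for z, summ in rec.zone_summary().items():
            assert summ["median"] == pytest.approx(nominal, rel=0.10)

    def test_scale_covariance(self, truth_products):
        """Scaling the scene by s: area × s², cell number unchanged."""
        from meristemorph.geometry import gaussian_curvature
        tp = truth_products("narrow_meristem", 1)
        sc = tp.scene
        s = 2.0
        scaled = SurfaceMesh(sc.mesh.vertices * s, sc.mesh.faces)
        curv = gaussian_curvature(scaled, radius=10.0 * s)
        region = delimit_meristem(scaled, sc.true_segmentation, curv,
                                  tp.graph, tp.central)
        assert region.cell_count == tp.region.cell_count
        assert region.area == pytest.approx(tp.region.area * s ** 2,
                                            rel=0.01)


class TestPrimordia:
    def test_three_bumps_found_near_truth(self, analyses, scenes):
        sc = scenes("domed", 1)
        an = analyses("domed", 1)
        prims = locate_primordia(an.mesh, an.segmentation, an.curvature,
                                 an.region, an.graph)
        assert len(prims) == len(sc.true_primordia) == 3
        # match by azimuth, compare centroids
        for p in prims:
            best = min(sc.true_primordia,
                       key=lambda t: abs((t.azimuth - p.azimuth + 180)
                                         % 360 - 180))
            assert np.linalg.norm(p.centroid[:2] - best.centroid[:2]) < 5.0

    def test_no_bumps_gives_empty_list(self, scenes):
        import dataclasses
        from meristemorph.geometry import gaussian_curvature
        from meristemorph.synthetic import generate_apex_scene, get_preset
        p = dataclasses.replace(get_preset("narrow_meristem"), n_primordia=0)
        sc = generate_apex_scene(p, 1)
        curv = gaussian_curvature(sc.mesh, radius=10.0)
        graph = build_cell_graph(sc.true_segmentation, sc.mesh)
        central = find_central_cell(sc.mesh, sc.true_segmentation)
        region = delimit_meristem(sc.mesh, sc.true_segmentation, curv,
                                  graph, central)
        assert locate_primordia(sc.mesh, sc.true_segmentation, curv,
                                region, graph) == []

    def test_recovered_azimuths_follow_divergence_angle(self, analyses):
        an = analyses("domed", 1)
        prims = locate_primordia(an.mesh, an.segmentation, an.curvature,
                                 an.region, an.graph)
        prims = sorted(prims, key=lambda p: p.age_rank)
        for a, b in zip(prims, prims[1:]):
            diff = (a.azimuth - b.azimuth + 180) % 360 - 180
            assert abs(abs(diff) - 137.5) < 10.0

    def test_age_rank_orders_by_bump_area(self, analyses):
        an = analyses("domed", 1)
        prims = locate_primordia(an.mesh, an.segmentation, an.curvature,
                                 an.region, an.graph)
        prims = sorted(prims, key=lambda p: p.age_rank)
        areas = [p.area for p in prims]
        assert areas == sorted(areas)


class TestIncipientPrediction:
    def test_golden_angle_extrapolation(self):
        p1 = Primordium(id="P_1", centroid=[10, 0, 0], azimuth=0.0,
                        age_rank=1)
        preds = predict_incipient_positions([p1], divergence=137.5, k=2)
        assert preds[0].azimuth == pytest.approx(137.5)
        assert preds[1].azimuth == pytest.approx(275.0)

    def test_empty_primordium_list_raises(self):
        with pytest.raises(ValueError):
            predict_incipient_positions([])

    def test_prediction_overlaps_generator_truth(self, analyses, scenes):
        sc = scenes("domed", 1)
        an = analyses("domed", 1)
        prims = locate_primordia(an.mesh, an.segmentation, an.curvature,
                                 an.region, an.graph)
        preds = predict_incipient_positions(prims, k=1)
        err = (preds[0].azimuth - sc.true_incipient[0].azimuth + 180) \
            % 360 - 180
        assert abs(err) < 15.0
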