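"""Shared fixtures: small analytic meshes and cached synthetic scenes.

Scene generation and curvature estimation are the expensive steps, so they
are cached per session and shared between the module tests and the
acceptance suite.
"""

from __future__ import annotations

import dataclasses
from types import SimpleNamespace

import numpy as np
import pytest
import trimesh

from meristemorph.geometry import (SurfaceMesh, gaussian_curvature,
                                   heightmap_mesh)
from meristemorph.morphometrics import delimit_meristem, find_central_cell
from meristemorph.pipeline import analyze_scene
from meristemorph.segmentation import CellSegmentation, build_cell_graph
from meristemorph.synthetic import generate_apex_scene, get_preset

ALL_PRESETS = ("vegetative", "domed", "inflorescence", "ft_tsf_like",
               "narrow_meristem")
SEEDS = (1, 2, 3)


# ---------------------------------------------------------------------------
# small analytic meshes
# ---------------------------------------------------------------------------

def make_grid_mesh(fn, half=20.0, step=0.5):
    n = int(2 * half / step) + 1
    x, y = np.meshgrid(np.linspace(-half, half, n),
                       np.linspace(-half, half, n))
    return heightmap_mesh(fn(x, y), step, step, origin=(-half, -half))


@pytest.fixture(scope="session")
def sphere_mesh():
    s = trimesh.creation.icosphere(subdivisions=4, radius=25.0)
    return SurfaceMesh(s.vertices, s.faces)


@pytest.fixture(scope="session")
def plane_mesh():
    return make_grid_mesh(lambda x, y: np.zeros_like(x))


@pytest.fixture(scope="session")
def saddle_mesh():
    c = 20.0
    return make_grid_mesh(lambda x, y: (x * x - y * y) / (2 * c))


@pytest.fixture(scope="session")
def bump_mesh():
    """Gaussian hill with a known analytic curvature profile."""
    h, s = 15.0, 12.0
    return make_grid_mesh(lambda x, y: h * np.exp(-(x * x + y * y)
                                                  / (2 * s * s)), half=30.0)


def hex_tessellation(n_rings=6, pitch=5.0, step=0.25):
    """Flat mesh partitioned into hexagonal cells by nearest hex-lattice seed.

    Returns (mesh, segmentation, center_label).
    """
    pts = [(0.0, 0.0)]
    for q in range(-n_rings, n_rings + 1):
        for r in range(-n_rings, n_rings + 1):
            if q == 0 and r == 0:
                continue
            x = pitch * (q + r / 2.0)
            y = pitch * (np.sqrt(3) / 2.0) * r
            if np.hypot(x, y) <= pitch * n_rings + 1e-9:
                pts.append((x, y))
    seeds = np.array(pts)
    half = pitch * n_rings + pitch
    n = int(2 * half / step) + 1
    x, y = np.meshgrid(np.linspace(-half, half, n),
                       np.linspace(-half, half, n))
    mesh = heightmap_mesh(np.zeros_like(x), step, step,
                          origin=(-half, -half))
    from scipy.spatial import cKDTree
    lab = cKDTree(seeds).query(mesh.vertices[:, :2])[1] + 1
    from meristemorph.segmentation import triangle_labels_from_vertices
    tri = triangle_labels_from_vertices(mesh.faces, lab)
    return mesh, CellSegmentation(tri, lab.astype(np.int64)), 1


@pytest.fixture(scope="session")
def hex_cells():
    return hex_tessellation()


# ---------------------------------------------------------------------------
# cached synthetic scenes and pipeline products
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def scenes():
    """Factory for cached scenes: scenes(preset, seed, noise_sd=None)."""
    cache = {}

    def get(preset, seed, noise_sd=None):
        key = (preset, seed, noise_sd)
        if key not in cache:
            p = get_preset(preset)
            if noise_sd is not None:
                p = dataclasses.replace(p, noise_sd=noise_sd)
            cache[key] = generate_apex_scene(p, seed)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def analyses(scenes):
    """Factory for cached full-pipeline analyses (stack in, record out)."""
    cache = {}

    def get(preset, seed):
        key = (preset, seed)
        if key not in cache:
            cache[key] = analyze_scene(scenes(preset, seed),
                                       apex_id=f"{preset}-{seed}",
                                       condition=preset)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def truth_products(scenes):
    """Curvature + graph + delimitation computed on the *truth* mesh."""
    cache = {}

    def get(preset, seed):
        key = (preset, seed)
        if key not in cache:
            sc = scenes(preset, seed)
            curv = gaussian_curvature(sc.mesh, radius=10.0)
            graph = build_cell_graph(sc.true_segmentation, sc.mesh)
            central = find_central_cell(sc.mesh, sc.true_segmentation)
            region = delimit_meristem(sc.mesh, sc.true_segmentation, curv,
                                      graph, central)
            cache[key] = SimpleNamespace(scene=sc, curvature=curv,
                                         graph=graph, central=central,
                                         region=region)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def doming_records(analyses):
    """Pipeline morphometric records for vegetative vs domed, seeds 1-3."""
    out = {}
    for preset in ("vegetative", "domed"):
        out[preset] = [analyses(preset, s).record for s in SEEDS]
    return out
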