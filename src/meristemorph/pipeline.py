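"""End-to-end apex analysis: stack → surface → cells → meristem → record.

`analyze_scene` runs the full measurement chain on a synthetic scene's
wall-stain stack exactly as it would run on a real acquisition; the scene's
ground truth is only used for seeding the watershed (the stand-in for the
interactive seed correction a human operator performs) and, in tests, for
scoring the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .geometry import gaussian_curvature
from .morphometrics import (
    MorphometricRecord,
    assign_zones,
    delimit_meristem,
    find_central_cell,
    locate_primordia,
    summarize_apex,
)
from .segmentation import (
    build_cell_graph,
    extract_surface,
    project_wall_signal,
    segment_cells,
)
from .synthetic import SyntheticScene, generate_apex_scene


@dataclass
class ApexAnalysis:
    """Everything the pipeline measured on one apex."""

    mesh: Any
    segmentation: Any
    graph: Any
    curvature: Any
    central_cell: int
    region: Any
    zones: Any
    record: MorphometricRecord
    primordia: list = field(default_factory=list)


def true_seed_points(scene: SyntheticScene) -> np.ndarray:
    """3D tessellation seed positions (the watershed markers)."""
    ny, nx = scene.zsurf.shape
    dx = dy = scene.params.voxel_xy
    ix = np.clip(np.round(scene.seeds_xy[:, 0] / dx).astype(int), 0, nx - 1)
    iy = np.clip(np.round(scene.seeds_xy[:, 1] / dy).astype(int), 0, ny - 1)
    return np.column_stack([scene.seeds_xy[:, 0], scene.seeds_xy[:, 1],
                            scene.zsurf[iy, ix]])


def analyze_scene(
    scene: SyntheticScene,
    curvature_radius: float = 10.0,
    wall_band: tuple[float, float] = (0.0, 4.0),
    surface_threshold: float | None = None,
    seeded: bool = True,
    min_cell_area: float = 4.0,
    locate_bumps: bool = False,
    apex_id: str | None = None,
    condition: str | None = None,
) -> ApexAnalysis:
    """Run the full measurement chain on a scene's wall-stain stack.

    ``seeded=True`` markers the watershed with the scene's tessellation
    seeds (so pipeline label i+1 corresponds to true cell i+1);
    ``seeded=False`` exercises the automatic h-minima seeding.
    """
    preset = scene.params
    if surface_threshold is None:
        surface_threshold = 0.5 * preset.sheet_amplitude
    mesh = extract_surface(scene.wall_stack, surface_threshold)
    wall, valid = project_wall_signal(scene.wall_stack, mesh, wall_band)
    seeds = true_seed_points(scene) if seeded else None
    seg = segment_cells(mesh, wall, seeds=seeds,
                        min_cell_area=min_cell_area, valid=valid)
    graph = build_cell_graph(seg, mesh)
    curv = gaussian_curvature(mesh, radius=curvature_radius)
    central = find_central_cell(mesh, seg)
    region = delimit_meristem(mesh, seg, curv, graph, central)
    zones = assign_zones(graph, region)
    record = summarize_apex(
        mesh, seg, region, zones,
        apex_id=apex_id or f"{preset.name}-{scene.seed}",
        genotype="synthetic",
        condition=condition or preset.name,
    )
    primordia = []
    if locate_bumps:
        primordia = locate_primordia(mesh, seg, curv, region, graph)
    return ApexAnalysis(mesh=mesh, segmentation=seg, graph=graph,
                        curvature=curv, central_cell=central, region=region,
                        zones=zones, record=record, primordia=primordia)


def run_condition(preset_name: str, seeds: list[int],
                  **kwargs) -> list[ApexAnalysis]:
    """Generate and analyze one apex per seed for a preset."""
    out = []
    for s in seeds:
        scene = generate_apex_scene(preset_name, s)
        out.append(analyze_scene(scene, apex_id=f"{preset_name}-{s}",
                                 condition=preset_name, **kwargs))
    return out


def records_frame(analyses: list[ApexAnalysis]):
    """Per-apex summary DataFrame from a list of analyses."""
    import pandas as pd
    rows = []
    for an in analyses:
        r = an.record
        rows.append({
            "apex_id": r.apex_id,
            "genotype": r.genotype,
            "condition": r.condition,
            "meristem_area": r.meristem_area,
            "cell_number": r.cell_number,
            "median_cell_area": r.median_cell_area,
            "mean_cell_area": r.mean_cell_area,
        })
    return pd.DataFrame(rows)


DEFAULT_CONFIG = {
    "plan": [{"preset": "vegetative", "seeds": [1, 2, 3]},
             {"preset": "domed", "seeds": [1, 2, 3]}],
    "baseline": "vegetative",
    "curvature_radius": 10.0,
    "wall_band": [0.0, 4.0],
    "seeded": True,
    "min_cell_area": 4.0,
    "alpha": 0.05,
    "metrics": ["meristem_area", "cell_number", "median_cell_area"],
    "heatmaps": False,
}


def _load_config(config):
    import yaml
    if isinstance(config, (str, bytes)) or hasattr(config, "read_text"):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping or a YAML file path")
    merged = dict(DEFAULT_CONFIG)
    merged.update(config)
    return merged


def run_pipeline(config) -> "Path":
    """Execute the whole analysis described by a config.

    The config (dict or YAML path) must name an ``output_dir`` and a
    ``plan`` of generator presets × seeds; validation happens before any
    computation.  Writes per-apex cell tables, a summary CSV, ANOVA/Tukey
    comparison tables with compact letters, fold changes vs the baseline
    condition, optional heat maps, and a run log with all parameters and
    the package version.  A stage failure aborts with the stage and the
    offending apex in the log.
    """
    import json
    import logging
    from pathlib import Path

    import pandas as pd

    from . import __version__
    from .io import cell_table
    from .morphometrics import cell_mean_curvature
    from .stats import anova_tukey, fold_changes

    cfg = _load_config(config)
    if not cfg.get("output_dir"):
        raise ValueError("config must set output_dir")
    if not cfg.get("plan"):
        raise ValueError("config must set a non-empty plan")
    for entry in cfg["plan"]:
        if "preset" not in entry or not entry.get("seeds"):
            raise ValueError("each plan entry needs a preset and seeds")

    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("meristemorph.pipeline")
    if not log.handlers:
        log.addHandler(logging.StreamHandler())
        fh = logging.FileHandler(out / "run.log", mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(fh)
        log.setLevel(logging.INFO)
    log.info("meristemorph %s", __version__)
    log.info("resolved config: %s", json.dumps(cfg, sort_keys=True))

    analyses = []
    for entry in cfg["plan"]:
        for s in entry["seeds"]:
            apex = f"{entry['preset']}-{s}"
            try:
                scene = generate_apex_scene(entry["preset"], int(s))
            except Exception:
                log.exception("stage=generate apex=%s", apex)
                raise
            try:
                an = analyze_scene(
                    scene,
                    curvature_radius=cfg["curvature_radius"],
                    wall_band=tuple(cfg["wall_band"]),
                    seeded=cfg["seeded"],
                    min_cell_area=cfg["min_cell_area"],
                    apex_id=apex, condition=entry["preset"])
            except Exception:
                log.exception("stage=analyze apex=%s", apex)
                raise
            analyses.append(an)
            mean_k = cell_mean_curvature(an.mesh, an.segmentation,
                                         an.curvature)
            cell_table(an.mesh, an.segmentation, an.region, an.zones,
                       mean_k).to_csv(out / f"cells_{apex}.csv", index=False,
                                      float_format="%.4g")
            if cfg["heatmaps"]:
                from .signal import render_heatmap
                areas = an.segmentation.cell_areas(an.mesh)
                render_heatmap(
                    {c: areas[c] for c in an.region.cell_ids},
                    an.mesh, an.segmentation,
                    png_path=out / f"cell_area_{apex}.png")
            log.info("apex=%s area=%.1f cells=%d median=%.2f", apex,
                     an.record.meristem_area, an.record.cell_number,
                     an.record.median_cell_area)

    summary = records_frame(analyses)
    summary.to_csv(out / "apex_summary.csv", index=False)

    try:
        comp_rows = []
        letter_rows = []
        for metric in cfg["metrics"]:
            groups = {c: g[metric].to_numpy()
                      for c, g in summary.groupby("condition", sort=False)}
            if len(groups) < 2 or min(len(v) for v in groups.values()) < 2:
                continue
            comp = anova_tukey(groups, alpha=cfg["alpha"])
            for (a, b), (diff, p) in comp.tukey.items():
                comp_rows.append({"metric": metric, "group_a": a,
                                  "group_b": b, "difference": diff,
                                  "p_adj": p,
                                  "F": comp.f_statistic,
                                  "anova_p": comp.p_value})
            for g, letters in comp.letters.items():
                letter_rows.append({"metric": metric, "condition": g,
                                    "letters": letters})
        if comp_rows:
            pd.DataFrame(comp_rows).to_csv(out / "tukey.csv", index=False)
            pd.DataFrame(letter_rows).to_csv(out / "letters.csv", index=False)
        if cfg.get("baseline"):
            fold_changes(summary, cfg["baseline"]).to_csv(
                out / "fold_changes.csv", index=False)
    except Exception:
        log.exception("stage=stats")
        raise
    log.info("report written to %s", out)
    return out
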