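# meristemorph

2.5D morphometrics of the shoot apical meristem (SAM) epidermis, with a
calibrated synthetic apex generator.

When an *Arabidopsis* shoot switches from vegetative growth to flowering,
its apical meristem transiently "domes": the meristematic area grows about
fourfold, the number of epidermal cells three- to fourfold, and the median
cell area by roughly 80%. Quantifying this from confocal stacks requires a
chain of image-analysis steps — extracting the epidermal (L1) surface as a
curved 2.5D mesh, segmenting cells on it, delimiting the meristem proper
from the surrounding organ primordia, and projecting reporter fluorescence
onto the cellular mesh. `meristemorph` implements that chain as a tested,
scriptable pipeline:

- **Surface extraction** — per-column topmost voxel of a cell-wall-stain
  stack (z step 0.4 µm), median-filtered and triangulated on the pixel grid.
- **Cell segmentation** — wall signal projected 0–4 µm below the surface
  along inward normals; seeded (or h-minima) watershed over the mesh vertex
  graph, so cell areas are measured on the curved surface.
- **Curvature** — per-vertex Gaussian curvature K by local quadric/quartic
  fitting over a 10 µm neighborhood; for a surface patch
  z = f(u,v), K = (f_uu f_vv − f_uv²)/(1 + f_u² + f_v²)².
- **Meristem delimitation** — the SAM is the region between the first
  developing primordia: cells are flooded outward from the summit (central)
  cell while their area-weighted mean K ≥ 0; the first K < 0 (saddle) cells
  are the boundary.
- **Zonation** — central zone (CZ) = cells 0–2 graph steps from the central
  cell, peripheral ring (PZ) = steps 3–5.
- **Primordia** — K > 0 bumps outside the region, aged by size; incipient
  positions i_n predicted at golden-angle (137.5°) steps from the youngest
  primordium.
- **Signal maps** — reporter intensity extracted 2–10 µm below the surface
  and projected per cell; heat-map renderings.
- **Statistics** — one-way ANOVA + Tukey HSD (Tukey–Kramer for unbalanced
  designs) with a compact letter display, and fold changes vs a baseline.

No public image data accompany the doming measurements, so the package
ships a **synthetic apex generator** (`meristemorph.synthetic`): a
spherical-cap dome ringed by a negative-curvature moat, golden-angle
primordium bumps, a density-controlled Voronoi epidermis, and rendered
wall-stain/reporter volumes. The vegetative → domed presets are calibrated
so the ground truth carries exactly the doming effect sizes (area ×4.0,
cells ×3.1, median cell area ×1.8), which makes every pipeline stage
testable against known truth.

## Worked example

```python
from meristemorph import generate_apex_scene, analyze_scene

scene = generate_apex_scene("domed", seed=1)       # full ground truth
result = analyze_scene(scene)                      # stack -> measurements
r = result.record
print(f"meristem area  {r.meristem_area:.0f} µm²   "
      f"cells {r.cell_number}   median cell {r.median_cell_area:.1f} µm²")
```

prints

```
meristem area  10363 µm²   cells 310   median cell 36.5 µm²
```

i.e. the pipeline recovers this domed apex's ground truth (10 000 µm²
nominal cap, 310 cells, 34.2 µm² median) from its rendered wall-stain stack
alone, within a few percent. The analysis scripts chain this over the
stage panel:

```bash
python analysis/01_generate_scenes.py        # truth panel -> results/scene_truth.csv
python analysis/02_morphometrics_pipeline.py # full pipeline -> results/pipeline/
python analysis/03_group_statistics.py       # ANOVA/Tukey/letters, fold changes
python analysis/04_signal_maps.py            # reporter projection + heat maps
python analysis/05_primordium_prediction.py  # P_n detection, i_n prediction
```

`03_group_statistics.py` ends with (vegetative baseline, 3 apices/stage):

```
 condition  meristem_area_ratio  cell_number_ratio  median_cell_area_pct_change
vegetative             1.000000                1.0                     0.000000
     domed             3.974773                3.1                    74.255892
```

A command-line interface mirrors the stages
(`meristemorph generate|segment|morpho|signal|run`); see `--help`.

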