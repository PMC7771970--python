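# Example pipeline configuration for `meristemorph run --config ...`
# (same schema as meristemorph.pipeline.run_pipeline).
output_dir: results/example_run
plan:
  - preset: narrow_meristem
    seeds: [1, 2]
  - preset: ft_tsf_like
    seeds: [1, 2]
baseline: narrow_meristem
curvature_radius: 10.0   # µm, Gaussian-curvature neighborhood
wall_band: [0.0, 4.0]    # µm below the surface, wall-stain projection
seeded: true             # watershed markers from the scene's seed points
min_cell_area: 4.0       # µm², sliver merge threshold
alpha: 0.05
heatmaps: false
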