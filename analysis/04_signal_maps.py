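"""Project reporter signals onto a segmented apex (2–10 µm depth band).

Renders two reporter patterns on a domed apex — peripheral-zone patches at
the incipient-primordium positions (a GA-biosynthesis-like domain) and
abaxial primordium domains (a GA-catabolism-like domain) — projects each
onto the cellular mesh, and writes per-cell intensity tables plus heat maps.
"""

import argparse
from pathlib import Path

import pandas as pd

from meristemorph.signal import project_signal, render_heatmap
from meristemorph.synthetic import generate_apex_scene, make_reporter_field


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--preset", default="domed")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/signal"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    sc = generate_apex_scene(args.preset, args.seed)
    for pattern in ("pz_patches", "abaxial_primordia"):
        stack = make_reporter_field(sc, pattern)
        smap = project_signal(stack, sc.mesh, sc.true_segmentation,
                              reporter=pattern)
        df = pd.DataFrame({
            "cell_id": sorted(smap.values),
            "reporter": pattern,
            "mean_intensity": [smap.values[c]
                               for c in sorted(smap.values)],
            "band_min": smap.band[0], "band_max": smap.band[1],
        })
        df.to_csv(args.out / f"signal_{pattern}.csv", index=False,
                  float_format="%.3f")
        render_heatmap(smap.defined(), sc.mesh, sc.true_segmentation,
                       png_path=args.out / f"signal_{pattern}.png")
        top = df.nlargest(3, "mean_intensity")
        print(f"{pattern}: brightest cells "
              f"{list(top.cell_id)} at {list(top.mean_intensity.round(1))}")


if __name__ == "__main__":
    main()
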