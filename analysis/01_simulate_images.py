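#!/usr/bin/env python
"""Render desk-scale synthetic coverslips for the cohesion assay.

Produces two image sets under scratch/images/ (OME-TIFF, ~binary scratch) and
their ground-truth tables under results/:

* ``lcl_single`` — 200 LCL-like cells, pericentrin only, pair distances
  ~ N(1.2 μm, 0.15 μm) truncated at 0: the control C/C regime.
* ``lcl_dual`` — 120 cells with both pericentrin and γ-tubulin channels and
  decoy single-marker dots, distances ~ N(1.1 μm, 0.156 μm): the
  dual-marker duplicated-centrosome regime.
"""

from pathlib import Path

from ccsplit.synth import ImageSimConfig, simulate_image_set, write_image_set

ROOT = Path(__file__).resolve().parents[1]

SETS = {
    "lcl_single": ImageSimConfig(
        n_cells=200, two_dot_fraction=1.0, mitotic_fraction=0.03,
        distance_mean_um=1.2, distance_sd_um=0.15, noise_sd=5.0, seed=101),
    "lcl_dual": ImageSimConfig(
        n_cells=120, two_dot_fraction=1.0, mitotic_fraction=0.03,
        distance_mean_um=1.1, distance_sd_um=0.156, dual_marker=True,
        noise_sd=5.0, seed=102),
}


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for name, cfg in SETS.items():
        outdir = ROOT / "scratch" / "images" / name
        stacks, gt = simulate_image_set(cfg)
        write_image_set(stacks, gt, outdir)
        gt.cells.to_csv(results / f"ground_truth_{name}.csv", index=False)
        n_split = int(gt.cells["split"].sum())
        n_two = int((gt.cells["n_dots"] == 2).sum())
        print(f"{name}: {len(stacks)} fields, {len(gt.cells)} cells, "
              f"true split {100 * n_split / n_two:.1f}% of {n_two} two-dot "
              f"cells -> {outdir}")


if __name__ == "__main__":
    main()
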