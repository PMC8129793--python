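# bcquant — quantification of collective border-cell migration

`bcquant` is a Python toolkit for the image-derived measurements used to
characterise migration of the border-cell (BC) cluster in the *Drosophila*
egg chamber: a small group of follicle cells that migrates collectively
between nurse cells to the oocyte, and a standard model of invasive
collective cell migration. The package is aimed at labs quantifying
fixed confocal images and live time-lapse movies of such clusters, and at
anyone who needs a fully synthetic, ground-truthed test bed for these
measurements.

## What it computes

For an oriented (anterior-left) maximum projection of each frame, the
pipeline thresholds the cluster, keeps the largest connected component,
and splits the mask into a **cell body** (morphological opening with a
disk) and **extensions** (remaining connected components ≥ 2 µm²), with
the partition body ∪ extensions = cluster holding exactly. From these it
derives:

- **Protrusion sectors** — each extension's angle θ ∈ [0°, 360°) from the
  body centroid (0° = +x, the leading edge) is classified as
  front [315°, 45°), side [45°, 135°) ∪ [225°, 315°), or back
  [135°, 225°), half-open and left-inclusive.
- **Forward-directed speed** — v = ⟨(x(t+1) − x(t))⟩ / Δt on the
  migration (x) axis of the body-centroid track, in µm/min.
- **Migration index** — 100 · (x − x₀)/(x_boundary − x₀), the percent of
  the path to the oocyte/nurse-cell boundary traversed, clamped to [0, 100].
- **Tumbling index** — the percent of first-half frames in which the
  cluster is rounded (circularity 4πA/P² ≥ 0.85) *and* its nuclei change
  circular order, for runs of ≥ 2 consecutive frames.
- **Back/middle/front (BMF) polarity fractions** — areas under detected
  peaks of a line-scan intensity profile through the cluster, integrated
  above a local linear baseline, assigned to thirds of the cluster extent,
  and normalised to percent of total area.
- **Mosaic and junction ratios** — mean-intensity or raw-integrated-density
  ratios between a marked sub-clone and its wild-type sibling region, or
  between inner and outer junctions.
- **Promoter-window ChIP annotation** — strand-aware −1000..+200 windows
  around each TSS (0-based half-open) and per-replicate peak overlap
  counts from BED input.

A synthetic-data module (`bcquant.synthetic`) generates every input the
pipeline consumes — fixed images, time-lapse stacks with tumbling
episodes, line profiles, mosaic images, and BED/gene fixtures — with
machine-readable ground truth, so the whole chain is testable end to end
without microscopy data.

## Worked example

Simulate a severely tumbling, slowly advancing mutant-like cluster
(maximal-tumbling preset, true forward speed 0.09 µm/min) and analyze it:

```python
from bcquant.report import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(seed=1, out_dir="demo", max_tumbling=True,
                                 n_frames=20, forward_speed_um_per_min=0.09))
```

prints/writes (`demo/summary.json`):

```json
{
  "forward_speed_um_per_min": 0.09080206599223135,
  "n_frames": 20,
  "sector_percent": {
    "back": 26.666666666666668,
    "front": 56.666666666666664,
    "side": 16.666666666666668
  },
  "truth_forward_speed_um_per_min": 0.09,
  "tumbling_index_pct": 100.0
}
```

The recovered forward speed (0.091 µm/min) matches the generator's truth
within ~1%; the tumbling index is 100% because every first-half frame
shows a rounded cluster with persistent nuclei rearrangement; the sector
percentages are the pooled front/side/back shares of all detected
extensions (here from the movie's non-tumbling second half).

The same analysis is available from the shell:

```sh
bcquant report --seed 1 --max-tumbling --out-dir demo
bcquant simulate --seed 1 --out-dir sim      # writes sim/movie.tif + truth JSON
bcquant motility sim/movie.tif --out motility.json
bcquant chip --genes genes.tsv --peaks rep1 peaks_rep1.bed --peaks rep2 peaks_rep2.bed
```

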