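# Methods

## Scope and conventions

All physical outputs are in micrometres and minutes and carry their
calibration; the defaults are 0.62 µm/px (a conventional value for a
20×/0.5 NA air objective — the calibration is configurable and nothing
downstream depends on the default) and 3 min per frame. Images follow
screen convention: x increases rightward, y downward. After orientation
the anterior end of the egg chamber is at the left, so the migration
axis is +x and the leading edge of the cluster faces +x. Angles are
measured counterclockwise on screen from +x, i.e. `atan2(-dy, dx)`
reduced to [0°, 360°).

## Segmentation

The cluster mask is the largest connected component above threshold.
The default threshold is Otsu's method, with an absolute-value override;
both are recorded, trading the original operator-drawn threshold for a
reproducible one. The mask is split into a cell body — the morphological
opening with a disk whose radius defaults to half the mask's equivalent
radius (a scale-free choice) — and extensions, the connected components
of mask − body with area ≥ 2 µm². Sub-threshold residue is folded back
into the body so that body ∪ extensions = mask holds exactly; this
partition is asserted by the `ClusterSegmentation` container itself.
If opening fragments the body, the largest fragment is kept and the rest
demoted to residue. Note that opening a rasterised shape with a large
rasterised disk can shave single-pixel boundary slivers; the 2 µm²
minimum extension area absorbs these at realistic calibrations.

## Protrusion sectors

Extensions are classified by the angle from the body centroid to the
extension centroid (the centroid, not the tip, because it is robust to
ragged masks): front [315°, 45°), side [45°, 135°) ∪ [225°, 315°), back
[135°, 225°), half-open and left-inclusive, so 45° is side, 135° back,
225° side, 315° front. Sector summaries pool extensions across frames
by default (per-frame totals are also reported).

## Tracking, speed, migration index

The track is the per-frame area centroid of the **body** mask. Using the
body rather than the full mask is a deliberate choice: protrusions are
transient appendages whose appearance and disappearance would add
~1 µm of frame-to-frame jitter to a full-mask centroid, an order of
magnitude above the body-centroid error (~0.07 µm RMS on synthetic
movies). Forward-directed speed is the mean of consecutive-frame x
displacements divided by the frame interval — algebraically the net
x displacement over elapsed time for the same window — positive toward
the posterior. The migration index is the percent of the
anterior-to-oocyte-boundary path traversed, clamped to [0, 100]
(positions beyond the boundary count as complete migration).

## Tumbling index

A frame *qualifies* when the cluster is rounded — circularity
4π·area/perimeter² ≥ 0.85, with the Crofton perimeter estimator; the
threshold is configurable since no operational value is standard — and
its cells rearrange. Rearrangement between consecutive frames is
detected from nuclei positions: nuclei are identity-matched by minimal
total displacement (Hungarian assignment, the injective form of
nearest-neighbour matching), each frame's matched nuclei are ordered by
angle around that frame's centroid, and the two cyclic orders are
compared after rotating both to a common anchor. Rigid translations
preserve the order; cells exchanging angular position do not. When
frames yield different nuclei counts, the matched common subset is
compared. A rearrangement event between frames t and t+1 marks **both**
frames as rearranging, since the positional change is visible in each;
with a one-sided convention the first (or last) first-half frame could
never qualify and a fully tumbling movie could not reach 100%.

A frame counts as tumbling only inside a run of ≥ 2 consecutive
qualifying frames. The index is 100 × tumbling frames / frames in the
first half of the movie, where "first half" defaults to the first
⌈T/2⌉ frames (an alternative split at migration index 50% can be
supplied as an explicit frame range).

Nuclei are detected as local intensity maxima inside the body mask,
separated by ≥ 1.8 µm and brighter than
median + 0.4·(max − median) of the body's intensities — spots must stand
clearly above the body plateau, not merely above its median, or plateau
noise maxima would register as nuclei.

## Line-scan polarity (BMF)

Profiles are sampled along a user-supplied anterior→posterior segment,
averaging 3 perpendicular samples (configurable) with bilinear
interpolation. Peaks are local maxima with prominence ≥ 10% of the
profile's dynamic range (default); each peak's support runs to the
higher of its flanking minima and is truncated at the midpoint to any
adjacent apex, so supports never overlap — a deterministic substitute
for interactive peak-analyzer baselining. Areas are trapezoidal
integrals above the linear baseline between the peak's bases (robust to
tilted backgrounds), with negative contributions clamped at zero. Each
peak contributes its whole area to the back, middle or front third of
the stated cluster extent according to its apex position, and the three
sums are normalised to percent of the per-scan total (per-scan
normalisation; a per-group alternative is a caller-side choice). With
zero total area the fractions are reported as missing, not zero.

## Mosaic and junction ratios

Region ratios use mean intensity by default (robust to unequal region
sizes) or raw integrated density (the plain sum over the mask). The fold
is reported on the ≥ 1 scale, control/test when the test region is
dimmer. Junction ratios are mean(inner)/mean(outer) and are invariant to
global intensity scaling.

## Promoter windows and peak assignment

Interval arithmetic is 0-based half-open throughout; BED input is used
as-is, and gene-table TSS values are read 1-based and converted. For a
+ strand gene with 0-based TSS t₀ the promoter window is
[t₀ − 1000, t₀ + 200); for a − strand gene it is the exact mirror
[t₀ − 199, t₀ + 1001), so −1000 lies upstream in the direction of
transcription — 1200 bases wide on both strands unless clamped at the
chromosome start. Strand-unaware assignment (all genes treated as
+ strand) is available behind a flag. A peak counts for **every** gene
whose window it intersects by at least one base; there is no
nearest-gene tie-break. Assignment uses an interval tree per chromosome
and is independent of peak input order; per-gene binding is summarised
as the number of replicates with ≥ 1 overlapping peak. Overlap equality
against a brute-force all-pairs oracle is asserted in the test suite on
fixtures of ~10⁴ intervals.

## Synthetic data: what it emulates, and what not

The generator renders Gaussian-blurred binary geometry plus additive
Gaussian noise: a bright body disk (default radius 10 µm, foreground
400, background 40, PSF σ 0.5 µm), protrusion lobes as rotated
rectangles sampled from configurable front/side/back weights (defaults
0.54/0.30/0.16, the front-biased distribution of a healthy migrating
cluster) with Poisson-distributed counts (mean 3/frame) and uniform
lengths 4–7 µm and widths 2.5–3.5 µm, and nuclear spots. Truth masks
are exact pre-blur geometry. All randomness flows through a single
seeded generator passed explicitly; identical seeds give bit-identical
outputs.

Nuclei sit on two rings (3 at 0.35·R, 3 at 0.75·R by default). The
distinct radii give each nucleus a positional identity signature.
During a tumbling transition, one angularly adjacent inner/outer pair
*crosses past its angular midpoint* (the smallest-gap pair with truly
different radii is preferred, overshoot 5°, and a 3 µm post-move
separation floor keeps nuclei resolvable). This changes the circular
order — the downstream rearrangement definition — while keeping
minimal-displacement identity matching unambiguous. A naive
"permute the slots" rearrangement would be undetectable in principle:
exchanging positions of identical-looking nuclei yields an (almost)
identical point set, and any displacement-based matcher silently pairs
the exchanged nuclei with each other. Tumbling frames render a rounded,
protrusion-suppressed body. Between consecutive non-tumbling frames the
nuclei translate rigidly with the cluster, so no rearrangement is
flagged there.

The generator does **not** model 3-D PSFs, photobleaching, spectral
bleed-through, cluster deformation, nuclear shape, or cell-autonomous
protrusion dynamics. Passing the recovery suites therefore shows that
the measurement chain is correct under the stated noise model, not that
segmentation or nuclei detection would be error-free on real confocal
data with debris, drift and uneven illumination.

## Problem sizes and tolerances in the test suite

Recovery suites use 20–60-frame movies on 192×192 px frames (noise SD 8,
i.e. SNR ≈ 45; the thresholding test uses SNR 10), which keeps the whole
suite under a minute while leaving ≥ 100 extensions for the
sector-fraction check (3 binomial SDs), ≤ 5% error bands for speed and
mosaic-fold recovery, and 2 percentage points for noise-free BMF
recovery. Speed recovery is tested with protrusion geometry held fixed
across frames, isolating the tracker from sampling noise in protrusion
placement; with stochastic protrusions the consecutive-difference
estimator inherits centroid noise at the few-percent level, a known
limitation stated above. Gaussian peak areas agree with the closed form
A·σ·√(2π) within 5% at ≥ 8 samples per σ.

## Replicate summaries

Descriptive statistics follow the replicate-means convention: the
reported mean is the grand mean of per-replicate means and the error is
SD(replicate means)/√(n replicates), so many measurements within one
replicate do not inflate the apparent n. SEM is undefined (reported
missing) for a single replicate. Pearson correlations are plain
product-moment coefficients; hypothesis tests are deliberately out of
scope.
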