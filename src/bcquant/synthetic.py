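"""Synthetic fluorescence data with machine-readable ground truth.

Every input the pipeline consumes can be generated here: fixed images
of a border-cell cluster with protrusions, time-lapse stacks with
directed motion and tumbling episodes, 1-D line-scan intensity
profiles, mosaic two-region images, and BED/gene fixtures for the
promoter module.

Intensity model: Gaussian-blurred binary geometry plus additive
Gaussian noise.  Truth masks are recorded before blur and noise.  All
randomness flows through one `numpy.random.Generator` constructed from
the explicit seed; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from bcquant.motility import classify_sector
from bcquant.types import CalibratedImage, ImageStack

#: conventional 20x-objective lateral sampling; the calibration is
#: carried on every output so nothing downstream depends on it
DEFAULT_PIXEL_SIZE_UM = 0.62
DEFAULT_FRAME_INTERVAL_MIN = 3.0

SECTOR_RANGES = {
    "front": [(315.0, 360.0), (0.0, 45.0)],
    "side": [(45.0, 135.0), (225.0, 315.0)],
    "back": [(135.0, 225.0)],
}


@dataclass
class ClusterSpec:
    """Geometry and intensity of the rendered cluster."""

    image_shape: tuple[int, int] = (192, 192)
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    body_radius_um: float = 10.0
    centroid_xy_um: tuple[float, float] | None = None  # default: image centre
    n_nuclei: int = 6
    intensity_fg: float = 400.0
    intensity_bg: float = 40.0
    noise_sd: float = 0.0
    psf_sigma_um: float = 0.5

    def __post_init__(self) -> None:
        if self.body_radius_um <= 0:
            raise ValueError("body_radius_um must be > 0")
        if not self.intensity_fg > self.intensity_bg >= 0:
            raise ValueError("require intensity_fg > intensity_bg >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.centroid_xy_um is None:
            h, w = self.image_shape
            self.centroid_xy_um = (w / 2 * self.pixel_size, h / 2 * self.pixel_size)


@dataclass
class ProtrusionSpec:
    """How protrusions are sampled around the cluster body."""

    sector_weights: tuple[float, float, float] = (0.54, 0.30, 0.16)  # front, side, back
    n_per_frame: float = 3.0
    length_um: tuple[float, float] = (4.0, 7.0)
    width_um: tuple[float, float] = (2.5, 3.5)
    explicit_angles_deg: list[float] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.sector_weights, dtype=float)
        if w.min() < 0 or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("sector_weights must be non-negative and sum to 1")
        if min(self.length_um) <= 0 or min(self.width_um) <= 0:
            raise ValueError("protrusion lengths and widths must be > 0")


@dataclass
class MotionSpec:
    """Cluster motion and tumbling schedule for a time-lapse."""

    forward_speed_um_per_min: float = 0.45
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN
    n_frames: int = 20
    tumbling_frames: frozenset[int] = frozenset()
    jitter_sd_um: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        self.tumbling_frames = frozenset(int(t) for t in self.tumbling_frames)
        if any(t < 0 or t >= self.n_frames for t in self.tumbling_frames):
            raise ValueError("tumbling_frames must lie in [0, n_frames)")


def max_tumbling_preset(n_frames: int = 20,
                        forward_speed_um_per_min: float = 0.09) -> MotionSpec:
    """Motion spec in which every first-half frame is a tumbling frame.

    Emulates a severely tumbling, slowly advancing mutant cluster; the
    analysis pipeline should report a tumbling index of 100% on movies
    generated with it.
    """
    half = (n_frames + 1) // 2
    return MotionSpec(forward_speed_um_per_min=forward_speed_um_per_min,
                      n_frames=n_frames, tumbling_frames=frozenset(range(half)))


@dataclass
class GroundTruth:
    """Machine-readable truth recorded by every generator."""

    body_masks: list[np.ndarray] = field(default_factory=list)
    extensions: list[dict] = field(default_factory=list)  # frame, angle_deg, area_um2, sector, mask
    track_xy_um: np.ndarray | None = None
    tumbling_flags: np.ndarray | None = None
    nuclei_xy_um: list[np.ndarray] = field(default_factory=list)
    peak_areas: dict | None = None
    mosaic_fold: float | None = None
    region_masks: dict | None = None
    overlap_table: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        """Sidecar JSON (masks summarised as pixel counts, not dumped)."""
        payload = {
            "n_frames": len(self.body_masks),
            "extensions": [
                {k: v for k, v in e.items() if k != "mask"} for e in self.extensions
            ],
            "track_xy_um": None if self.track_xy_um is None else self.track_xy_um.tolist(),
            "tumbling_flags": None if self.tumbling_flags is None else
                [bool(b) for b in self.tumbling_flags],
            "peak_areas": self.peak_areas,
            "mosaic_fold": self.mosaic_fold,
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _sample_angle(rng: np.random.Generator, weights: tuple[float, float, float]) -> float:
    """Draw a protrusion angle: pick a sector by weight, uniform within it."""
    sector = rng.choice(("front", "side", "back"), p=np.asarray(weights, dtype=float))
    ranges = SECTOR_RANGES[sector]
    spans = np.array([hi - lo for lo, hi in ranges])
    lo, hi = ranges[int(rng.choice(len(ranges), p=spans / spans.sum()))]
    return float(rng.uniform(lo, hi))


def _protrusion_polygon(angle_deg: float, length_um: float, width_um: float,
                        cluster: ClusterSpec) -> np.ndarray:
    """Rasterise one protrusion lobe as a rotated rectangle (bool mask).

    The rectangle runs radially from inside the body rim to
    body_radius + length; screen angles increase counterclockwise, so
    the y component is negated (array y grows downward).
    """
    px = cluster.pixel_size
    cx, cy = (c / px for c in cluster.centroid_xy_um)
    r0 = (cluster.body_radius_um * 0.6) / px
    r1 = (cluster.body_radius_um + length_um) / px
    h, w = cluster.image_shape
    if r1 >= min(cx, cy, w - cx, h - cy):
        raise ValueError(
            f"protrusion of length {length_um} µm at angle {angle_deg}° "
            "extends beyond the image; enlarge image_shape or shorten it"
        )
    th = math.radians(angle_deg)
    ux, uy = math.cos(th), -math.sin(th)       # radial unit vector (screen angle)
    nx, ny = -uy, ux                            # normal
    hw = (width_um / 2) / px
    corners = []
    for rr, ss in ((r0, -hw), (r1, -hw), (r1, hw), (r0, hw)):
        corners.append((cy + rr * uy + ss * ny, cx + rr * ux + ss * nx))
    rows, cols = draw_polygon([c[0] for c in corners], [c[1] for c in corners],
                              shape=cluster.image_shape)
    mask = np.zeros(cluster.image_shape, dtype=bool)
    mask[rows, cols] = True
    return mask


def _nuclei_offsets(cluster: ClusterSpec) -> np.ndarray:
    """Fixed polar offsets of nuclei within the body, as (x, y) µm.

    Nuclei sit at evenly spaced angular slots, alternating between an
    inner and an outer radius.  The distinct radii give each nucleus a
    positional signature, so identity matching across frames remains
    correct even when nuclei exchange angular slots during tumbling.
    """
    n = cluster.n_nuclei
    r_in, r_out = 0.35 * cluster.body_radius_um, 0.75 * cluster.body_radius_um
    slots = np.arange(n) * 360.0 / n
    radii = np.where(np.arange(n) % 2 == 0, r_in, r_out)
    th = np.radians(slots)
    return np.column_stack([radii * np.cos(th), -radii * np.sin(th)])


def _render_frame(cluster: ClusterSpec, body_mask: np.ndarray,
                  ext_masks: list[np.ndarray], nuclei_xy_um: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Blurred geometry + nuclei spots + noise -> float image."""
    px = cluster.pixel_size
    img = np.full(cluster.image_shape, float(cluster.intensity_bg))
    fg = body_mask.copy()
    for m in ext_masks:
        fg |= m
    img[fg] = cluster.intensity_fg
    # bright nuclear spots on top of the body signal
    yy, xx = np.mgrid[0: cluster.image_shape[0], 0: cluster.image_shape[1]]
    sig_px = 0.7 / px
    for x_um, y_um in nuclei_xy_um:
        d2 = (xx - x_um / px) ** 2 + (yy - y_um / px) ** 2
        img += 1.2 * cluster.intensity_fg * np.exp(-d2 / (2 * sig_px**2))
    if cluster.psf_sigma_um > 0:
        img = ndimage.gaussian_filter(img, cluster.psf_sigma_um / px)
    if cluster.noise_sd > 0:
        img = img + rng.normal(0.0, cluster.noise_sd, size=img.shape)
    return np.maximum(img, 0.0)


def _body_mask(cluster: ClusterSpec, centroid_xy_um: tuple[float, float]) -> np.ndarray:
    px = cluster.pixel_size
    mask = np.zeros(cluster.image_shape, dtype=bool)
    rows, cols = draw_disk((centroid_xy_um[1] / px, centroid_xy_um[0] / px),
                           cluster.body_radius_um / px, shape=cluster.image_shape)
    mask[rows, cols] = True
    return mask


def _make_cluster_frame(cluster: ClusterSpec, protrusions: ProtrusionSpec,
                        centroid_xy_um: tuple[float, float],
                        nuclei_xy_um: np.ndarray, rng: np.random.Generator,
                        suppress_protrusions: bool = False,
                        frame: int = 0) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Render one frame; returns (image, body_mask, extension truths)."""
    c = ClusterSpec(**{**asdict(cluster), "centroid_xy_um": centroid_xy_um})
    body = _body_mask(c, centroid_xy_um)
    ext_records: list[dict] = []
    ext_masks: list[np.ndarray] = []
    if not suppress_protrusions:
        if protrusions.explicit_angles_deg is not None:
            angles = list(protrusions.explicit_angles_deg)
        else:
            n = int(rng.poisson(protrusions.n_per_frame))
            angles = [_sample_angle(rng, protrusions.sector_weights) for _ in range(n)]
        occupied = body.copy()
        for ang in angles:
            length = float(rng.uniform(*protrusions.length_um))
            width = float(rng.uniform(*protrusions.width_um))
            lobe = _protrusion_polygon(ang, length, width, c)
            ext = lobe & ~occupied  # truth extensions disjoint from body and each other
            if not ext.any():
                continue
            occupied |= lobe
            ext_masks.append(ext)
            ext_records.append({
                "frame": frame,
                "angle_deg": float(ang % 360.0),
                "area_um2": float(np.count_nonzero(ext)) * c.pixel_size**2,
                "sector": classify_sector(ang),
                "mask": ext,
            })
    img = _render_frame(c, body, ext_masks, nuclei_xy_um, rng)
    return img, body, ext_records


def make_fixed_cluster_image(cluster: ClusterSpec, protrusions: ProtrusionSpec,
                             seed: int) -> tuple[CalibratedImage, GroundTruth]:
    """A single fixed-sample image of a cluster with protrusions.

    The image is background + blurred body disk + blurred protrusion
    lobes + Gaussian noise; truth masks are exact pre-blur geometry.
    """
    rng = np.random.default_rng(seed)
    nuclei = _nuclei_offsets(cluster) + np.asarray(cluster.centroid_xy_um)
    img, body, exts = _make_cluster_frame(
        cluster, protrusions, cluster.centroid_xy_um, nuclei, rng)
    truth = GroundTruth(body_masks=[body], extensions=exts,
                        nuclei_xy_um=[nuclei])
    image = CalibratedImage(img, cluster.pixel_size, oriented_anterior_left=True)
    return image, truth


def make_timelapse(cluster: ClusterSpec, protrusions: ProtrusionSpec,
                   motion: MotionSpec, seed: int) -> tuple[ImageStack, GroundTruth]:
    """A time-lapse of a migrating cluster with optional tumbling frames.

    The centroid advances along +x by forward_speed × frame_interval
    per frame plus optional jitter.  Tumbling frames render a rounded
    (protrusion-suppressed) body; between consecutive tumbling frames
    one inner/outer pair of nuclei exchanges angular slots, so the
    circular order of nuclei changes while every nucleus keeps its own
    radial signature.
    """
    rng = np.random.default_rng(seed)
    offsets = _nuclei_offsets(cluster)
    n = motion.n_frames
    step = motion.forward_speed_um_per_min * motion.frame_interval_min
    x0, y0 = cluster.centroid_xy_um

    frames, body_masks, all_ext, nuclei_list = [], [], [], []
    track = np.zeros((n, 2))
    flags = np.zeros(n, dtype=bool)
    # per-nucleus polar state: fixed radius, mutable angular slot
    radii = np.hypot(offsets[:, 0], offsets[:, 1])
    angles = np.degrees(np.arctan2(-offsets[:, 1], offsets[:, 0])) % 360.0

    for t in range(n):
        cx = x0 + t * step
        cy = y0
        if motion.jitter_sd_um > 0:
            cx += rng.normal(0.0, motion.jitter_sd_um)
            cy += rng.normal(0.0, motion.jitter_sd_um)
        h, w = cluster.image_shape
        margin = (cluster.body_radius_um + protrusions.length_um[1]
                  + max(cluster.psf_sigma_um * 3, 1.0))
        if not (margin <= cx <= w * cluster.pixel_size - margin and
                margin <= cy <= h * cluster.pixel_size - margin):
            raise ValueError(f"track leaves the image at frame {t} (x={cx:.1f} µm)")
        tumbling = t in motion.tumbling_frames
        flags[t] = tumbling
        if tumbling and t > 0 and (t - 1) in motion.tumbling_frames:
            # one angularly adjacent pair with different radii crosses
            # past its angular midpoint: the circular order of nuclei
            # changes, while each nucleus keeps its radial signature so
            # minimal-displacement identity matching stays unambiguous
            order = np.argsort(angles)
            ring_gap = 0.1 * cluster.body_radius_um  # rings must truly differ
            candidates = []
            for k in range(len(order)):
                i, j = order[k], order[(k + 1) % len(order)]
                if abs(radii[i] - radii[j]) > ring_gap:
                    candidates.append(((angles[j] - angles[i]) % 360.0, i, j))
            # narrow gaps keep the displacement small, so identity
            # matching by minimal displacement stays unambiguous
            candidates.sort(key=lambda c: c[0])
            best, best_sep = None, -np.inf
            for gap, i, j in candidates:
                mid = angles[i] + gap / 2.0
                trial = angles.copy()
                trial[i] = (mid + 5.0) % 360.0  # cross past the midpoint
                trial[j] = (mid - 5.0) % 360.0
                tth = np.radians(trial)
                pts = np.column_stack([radii * np.cos(tth), -radii * np.sin(tth)])
                d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
                sep = float(d[np.triu_indices(len(pts), k=1)].min())
                if sep > best_sep:
                    best, best_sep = trial, sep
                if sep >= 3.0:  # keep nuclei resolvable in the rendered image
                    break
            angles = best
        th = np.radians(angles)
        nuclei = np.column_stack([cx + radii * np.cos(th), cy - radii * np.sin(th)])
        img, body, exts = _make_cluster_frame(
            cluster, protrusions, (cx, cy), nuclei, rng,
            suppress_protrusions=tumbling, frame=t)
        frames.append(CalibratedImage(img, cluster.pixel_size, oriented_anterior_left=True))
        body_masks.append(body)
        all_ext.extend(exts)
        nuclei_list.append(nuclei)
        track[t] = (cx, cy)

    stack = ImageStack(frames, motion.frame_interval_min)
    truth = GroundTruth(body_masks=body_masks, extensions=all_ext,
                        track_xy_um=track, tumbling_flags=flags,
                        nuclei_xy_um=nuclei_list)
    return stack, truth


def make_line_profile(target_bmf: tuple[float, float, float],
                      peak_sigma_um: float = 2.0,
                      n_points: int = 400,
                      extent_um: float = 40.0,
                      baseline: float = 10.0,
                      noise_sd: float = 0.0,
                      seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """A 1-D anterior→posterior intensity profile with three Gaussian peaks.

    Peaks sit at the centres of the back, middle and front thirds of
    the extent, with analytic areas in the ``target_bmf`` ratios (a
    zero target omits that peak).  Returns a (position_um, intensity)
    table plus truth with the analytic areas.
    """
    bmf = np.asarray(target_bmf, dtype=float)
    if bmf.min() < 0 or not math.isclose(bmf.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("target_bmf must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, extent_um, n_points)
    centers = np.array([extent_um / 6, extent_um / 2, 5 * extent_um / 6])
    total_area = 600.0  # units·µm, arbitrary
    areas = bmf * total_area
    truth_warn: list[str] = []
    if 6 * peak_sigma_um > extent_um / 3:
        truth_warn.append("peaks overlap: sigma too large for the extent")
        warnings.warn(truth_warn[-1])
    y = np.full_like(x, baseline)
    for c, a in zip(centers, areas):
        if a <= 0:
            continue
        amp = a / (peak_sigma_um * math.sqrt(2 * math.pi))
        y = y + amp * np.exp(-((x - c) ** 2) / (2 * peak_sigma_um**2))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    profile = pd.DataFrame({"position_um": x, "intensity": np.maximum(y, 0.0)})
    truth = GroundTruth(peak_areas={"back": float(areas[0]), "middle": float(areas[1]),
                                    "front": float(areas[2]),
                                    "centers_um": centers.tolist(),
                                    "extent_um": float(extent_um)},
                        warnings=truth_warn)
    return profile, truth


def make_mosaic(fold: float, shape: tuple[int, int] = (128, 128),
                base_intensity: float = 200.0, noise_sd: float = 0.0,
                pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
                seed: int = 0) -> tuple[CalibratedImage, GroundTruth]:
    """A two-region mosaic image: control at I, test at I / fold.

    Emulates a mosaic cluster with a wild-type and a mutant sub-clone;
    truth records the region masks and the fold.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.zeros(shape, dtype=float)
    control = np.zeros(shape, dtype=bool)
    test = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk((h / 2, w * 0.3), min(h, w) * 0.2, shape=shape)
    control[rr, cc] = True
    rr, cc = draw_disk((h / 2, w * 0.7), min(h, w) * 0.2, shape=shape)
    test[rr, cc] = True
    img[control] = base_intensity
    img[test] = base_intensity / fold
    if noise_sd > 0:
        img = np.maximum(img + rng.normal(0.0, noise_sd, size=shape), 0.0)
    truth = GroundTruth(mosaic_fold=float(fold),
                        region_masks={"control": control, "test": test})
    return CalibratedImage(img, pixel_size), truth


def make_promoter_fixture(n_genes: int, n_peaks: int, seed: int,
                          n_replicates: int = 2,
                          chroms: tuple[str, ...] = ("chr2L", "chr2R", "chr3L", "chr3R", "chrX"),
                          chrom_length: int = 2_000_000,
                          out_dir: str | Path | None = None,
                          ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Random gene models and peak intervals with known promoter overlaps.

    Genes get random TSS (1-based) and strand; peaks are uniform random
    intervals, with a fraction deliberately placed flush against window
    edges to exercise the half-open boundary convention.  The truth
    overlap table is computed by brute-force all-pairs comparison
    against the strand-aware −1000..+200 promoter windows.

    Returns ``(peaks_by_replicate, gene_table, truth)``; if ``out_dir``
    is given, also writes one BED per replicate and a genes TSV.
    """
    from bcquant.chip import GeneModel, promoter_window  # deferred: avoid cycle

    rng = np.random.default_rng(seed)
    genes = pd.DataFrame({
        "gene_id": [f"gene{i:04d}" for i in range(n_genes)],
        "chrom": rng.choice(chroms, size=n_genes),
        "tss": rng.integers(5_000, chrom_length - 5_000, size=n_genes) + 1,
        "strand": rng.choice(["+", "-"], size=n_genes),
    })
    windows = [promoter_window(GeneModel(r.gene_id, r.chrom, int(r.tss), r.strand))
               for r in genes.itertuples()]

    peaks_by_rep: dict[str, pd.DataFrame] = {}
    rows = []
    for rep in range(n_replicates):
        rep_id = f"rep{rep + 1}"
        starts = rng.integers(0, chrom_length - 2_000, size=n_peaks)
        lengths = rng.integers(100, 1_500, size=n_peaks)
        chrom_col = rng.choice(chroms, size=n_peaks)
        starts = starts.astype(np.int64)
        ends = starts + lengths
        # pin some peaks flush to window edges (touching => no overlap)
        n_edge = min(n_peaks // 10, len(windows))
        for k in range(n_edge):
            wdw = windows[int(rng.integers(0, len(windows)))]
            chrom_col[k] = wdw.interval.chrom
            if k % 2 == 0:
                ends[k] = wdw.interval.start      # touches start: no hit
                starts[k] = max(0, ends[k] - int(lengths[k]))
            else:
                starts[k] = wdw.interval.end      # touches end: no hit
                ends[k] = starts[k] + int(lengths[k])
        peaks_by_rep[rep_id] = pd.DataFrame(
            {"chrom": chrom_col, "start": starts, "end": ends}
        ).astype({"start": np.int64, "end": np.int64})
        # brute-force truth
        for g, wdw in zip(genes.itertuples(), windows):
            hit = bool(np.any(
                (chrom_col == wdw.interval.chrom)
                & (starts < wdw.interval.end)
                & (ends > wdw.interval.start)
            ))
            rows.append({"gene_id": g.gene_id, "replicate_id": rep_id, "overlap": hit})
    truth = GroundTruth(overlap_table=pd.DataFrame(rows))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        genes.to_csv(out_dir / "genes.tsv", sep="\t", index=False)
        for rep_id, df in peaks_by_rep.items():
            df.to_csv(out_dir / f"peaks_{rep_id}.bed", sep="\t", index=False, header=False)
    return peaks_by_rep, genes, truth
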