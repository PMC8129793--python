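"""Protrusion sector classification and cluster motility metrics.

Angles are measured from the cluster body centroid to the extension
centroid, with 0° along +x (the posterior-pointing leading edge after
anterior-left orientation) and increasing counterclockwise on screen
(i.e. toward −y in array coordinates).  Sectors follow the standard
front (315–45°), side (45–135° and 225–315°), back (135–225°) split,
half-open and left-inclusive at each boundary.

Motility summaries: forward-directed speed is the mean frame-to-frame
x-displacement of the cluster centroid per minute; the migration index
is the percent of the anterior-to-oocyte-boundary path traversed; the
tumbling index is the percent of first-half frames in which the cluster
is rounded and its cells rearrange for two or more consecutive frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max
from skimage.measure import perimeter_crofton

from bcquant.imaging import mask_centroid_um, split_body_extensions, threshold_cluster
from bcquant.types import ClusterSegmentation, ImageStack

#: circularity at or above which a cluster counts as rounded
DEFAULT_ROUNDED_CIRCULARITY = 0.85

SECTORS = ("front", "side", "back")


@dataclass
class Extension:
    """A detected protrusion of the cluster."""

    frame: int
    area_um2: float
    angle_deg: float
    sector: str


@dataclass
class Track:
    """Per-frame cluster centroid positions in µm."""

    x_um: np.ndarray
    y_um: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if self.x_um.shape != self.y_um.shape or self.x_um.ndim != 1:
            raise ValueError("track coordinates must be matching 1-D arrays")
        if not (np.all(np.isfinite(self.x_um)) and np.all(np.isfinite(self.y_um))):
            raise ValueError("track coordinates must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0 min")

    def __len__(self) -> int:
        return self.x_um.size

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(len(self)) * self.frame_interval
        return pd.DataFrame({"frame": np.arange(len(self)), "t_min": t,
                             "x_um": self.x_um, "y_um": self.y_um})


@dataclass
class TumblingScore:
    """Per-frame tumbling flags and the summary index."""

    rounded: np.ndarray
    rearranged: np.ndarray
    tumbling_frames: np.ndarray | None = field(init=False, default=None)
    tumbling_index_pct: float | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.rounded = np.asarray(self.rounded, dtype=bool)
        self.rearranged = np.asarray(self.rearranged, dtype=bool)


def extension_angle(body_centroid_um: tuple[float, float],
                    ext_centroid_um: tuple[float, float]) -> float:
    """Angle in degrees [0, 360) from body centroid to extension centroid.

    0° points along +x (leading edge); angles increase counterclockwise
    on screen, so an extension above the centroid (−y in array
    coordinates) is at 90°.
    """
    dx = ext_centroid_um[0] - body_centroid_um[0]
    dy = ext_centroid_um[1] - body_centroid_um[1]
    return math.degrees(math.atan2(-dy, dx)) % 360.0


def classify_sector(angle_deg: float) -> str:
    """Assign an angle to the front/side/back sector.

    Intervals are half-open, left-inclusive: front [315°,45°),
    side [45°,135°) ∪ [225°,315°), back [135°,225°).  Input angles are
    reduced modulo 360.
    """
    a = float(angle_deg) % 360.0
    if a < 45.0 or a >= 315.0:
        return "front"
    if a < 135.0 or 225.0 <= a:
        return "side"
    return "back"


def sector_summary(extensions: list[Extension]) -> pd.DataFrame:
    """Per-sector counts, percentages and mean areas, pooled over frames.

    Percentages sum to 100 whenever at least one extension exists; with
    no extensions they are reported as missing (NaN), not zero.
    """
    rows = []
    n_total = len(extensions)
    n_frames = len({e.frame for e in extensions}) if extensions else 0
    for sector in SECTORS:
        sel = [e for e in extensions if e.sector == sector]
        n = len(sel)
        rows.append({
            "sector": sector,
            "n_extensions": n,
            "percent": 100.0 * n / n_total if n_total else np.nan,
            "mean_area_um2": float(np.mean([e.area_um2 for e in sel])) if sel else np.nan,
            "per_frame": n / n_frames if n_frames else np.nan,
        })
    return pd.DataFrame(rows)


def measure_extensions(seg: ClusterSegmentation, frame: int = 0) -> list[Extension]:
    """Angle/area/sector measurements for every extension of a segmentation."""
    body_c = mask_centroid_um(seg.body_mask, seg.pixel_size)
    out = []
    for ext_mask in seg.extensions:
        ext_c = mask_centroid_um(ext_mask, seg.pixel_size)
        ang = extension_angle(body_c, ext_c)
        out.append(Extension(frame=frame, area_um2=seg.area_um2(ext_mask),
                             angle_deg=ang, sector=classify_sector(ang)))
    return out


def track_centroid(masks: list[np.ndarray], pixel_size: float,
                   frame_interval: float) -> Track:
    """Area-centroid track of the full cluster mask, in µm."""
    xs, ys = [], []
    for m in masks:
        x, y = mask_centroid_um(m, pixel_size)
        xs.append(x)
        ys.append(y)
    return Track(np.array(xs), np.array(ys), frame_interval)


def forward_speed(track: Track, window: slice | None = None) -> float:
    """Forward-directed speed in µm/min along the migration (x) axis.

    Mean over consecutive frame pairs of (x[t+1] − x[t]) / frame
    interval; positive toward the posterior.  Equals net x-displacement
    divided by elapsed time over the same window.
    """
    x = track.x_um if window is None else track.x_um[window]
    if x.size < 2:
        raise ValueError("forward speed needs at least 2 frames")
    return float(np.mean(np.diff(x)) / track.frame_interval)


def percent_reduction(control: float, test: float) -> float:
    """Percent reduction of ``test`` relative to ``control`` (> 0)."""
    if control <= 0:
        raise ValueError("control value must be > 0")
    return 100.0 * (control - test) / control


def migration_index(cluster_x_um: float, start_x_um: float,
                    oocyte_boundary_x_um: float) -> float:
    """Percent of the path to the oocyte/nurse-cell boundary traversed.

    Clamped to [0, 100]: positions beyond the boundary count as
    complete migration.
    """
    if oocyte_boundary_x_um <= start_x_um:
        raise ValueError("oocyte boundary must lie posterior to the start position")
    frac = (cluster_x_um - start_x_um) / (oocyte_boundary_x_um - start_x_um)
    return float(np.clip(100.0 * frac, 0.0, 100.0))


def roundness(mask: np.ndarray) -> float:
    """Circularity 4π·area/perimeter², in (0, 1]; 1 for a disk.

    Perimeter uses the Crofton estimator, which is close to the true
    boundary length for smooth rasterised shapes.
    """
    mask = np.asarray(mask, dtype=bool)
    area = float(np.count_nonzero(mask))
    if area == 0:
        raise ValueError("empty mask has no roundness")
    perim = float(perimeter_crofton(mask, directions=4))
    if perim == 0:  # single pixel
        return 1.0
    return min(1.0, 4.0 * math.pi * area / perim**2)


def detect_nuclei(pixels: np.ndarray, body_mask: np.ndarray, pixel_size: float,
                  min_separation_um: float = 1.8) -> np.ndarray:
    """Detect nuclear spots inside the cluster body as (x, y) µm points.

    Local intensity maxima within the body mask, separated by at least
    ``min_separation_um`` and brighter than the body median — adequate
    for the bright, well-separated nuclear label the generator renders
    and for thresholded nuclear-GFP data.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    inside = pixels[body_mask]
    if inside.size == 0:
        return np.empty((0, 2))
    med = float(np.median(inside))
    # spots must stand clearly above the body plateau, not merely above
    # its median, or plateau noise maxima would count as nuclei
    thresh = med + 0.4 * (float(inside.max()) - med)
    min_dist = max(1, int(round(min_separation_um / pixel_size)))
    coords = peak_local_max(np.where(body_mask, pixels, 0.0),
                            min_distance=min_dist, threshold_abs=thresh,
                            exclude_border=False)
    # (row, col) -> (x, y) µm
    return coords[:, ::-1].astype(float) * pixel_size


def _match_points(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Identity matching between two point sets by minimal total displacement."""
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return linear_sum_assignment(d)


def detect_rearrangement(nuclei_t: np.ndarray, nuclei_t1: np.ndarray) -> bool:
    """True iff the circular order of nuclei about the centroid changes.

    Nuclei are identity-matched between frames by minimal total
    displacement (nearest-neighbour assignment); each frame's matched
    nuclei are then ordered by angle around that frame's centroid and
    the two cyclic orders compared.  Rigid translations preserve the
    order; cells exchanging angular position do not.  When the frames
    detect different nuclei counts, the comparison uses the matched
    common subset.
    """
    a = np.asarray(nuclei_t, dtype=float).reshape(-1, 2)
    b = np.asarray(nuclei_t1, dtype=float).reshape(-1, 2)
    n = min(len(a), len(b))
    if n < 3:
        return False
    ia, ib = _match_points(a, b)
    a, b = a[ia], b[ib]  # row k of a corresponds to row k of b

    def cyclic_order(pts: np.ndarray) -> list[int]:
        c = pts.mean(axis=0)
        ang = np.arctan2(-(pts[:, 1] - c[1]), pts[:, 0] - c[0])
        return list(np.argsort(ang))

    oa, ob = cyclic_order(a), cyclic_order(b)
    # compare as cyclic sequences: rotate both to start at identity 0
    oa = oa[oa.index(0):] + oa[:oa.index(0)]
    ob = ob[ob.index(0):] + ob[:ob.index(0)]
    return oa != ob


def tumbling_index(rounded: np.ndarray, rearranged: np.ndarray,
                   first_half: slice | None = None) -> TumblingScore:
    """Percent of first-half frames in qualifying tumbling runs.

    A frame qualifies when the cluster is rounded and rearranging; it
    counts as tumbling only when it belongs to a run of two or more
    consecutive qualifying frames.  The index is 100 × tumbling frames
    / frames in the first half (default: first ⌈T/2⌉ frames).
    """
    score = TumblingScore(rounded, rearranged)
    n = score.rounded.size
    if score.rearranged.size != n:
        raise ValueError("rounded and rearranged flags must have equal length")
    if first_half is None:
        first_half = slice(0, (n + 1) // 2)
    qualifying = score.rounded & score.rearranged
    tumbling = np.zeros(n, dtype=bool)
    run_start = None
    for i in range(n + 1):
        if i < n and qualifying[i]:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= 2:
                tumbling[run_start:i] = True
            run_start = None
    half_idx = np.arange(n)[first_half]
    if half_idx.size == 0:
        raise ValueError("first-half frame range is empty")
    score.tumbling_frames = tumbling
    score.tumbling_index_pct = float(100.0 * np.count_nonzero(tumbling[first_half]) / half_idx.size)
    return score


def analyze_timelapse(
    stack: ImageStack,
    rounded_circularity: float = DEFAULT_ROUNDED_CIRCULARITY,
    opening_radius_um: float | None = None,
    threshold_method: str = "otsu",
) -> dict:
    """Full motility analysis of an oriented time-lapse stack.

    Per frame: threshold the cluster, split body/extensions, measure
    extension angles and sectors, cluster roundness, and nuclei
    positions.  Across frames: centroid track, forward speed,
    rearrangement flags and the tumbling index.  A rearrangement event
    between consecutive frames marks both frames as rearranging (the
    positional change is visible in each).

    Returns a dict with the track, extensions list, sector summary,
    tumbling score and scalar metrics.
    """
    px_size = stack.pixel_size
    body_masks, all_ext, roundn, nuclei = [], [], [], []
    for t, frame in enumerate(stack.frames):
        mask = threshold_cluster(frame, method=threshold_method)
        seg = split_body_extensions(mask, px_size, opening_radius_um=opening_radius_um)
        # the cluster "center" is the cell-body centroid: protrusions are
        # transient appendages and would jitter a full-mask centroid
        body_masks.append(seg.body_mask)
        all_ext.extend(measure_extensions(seg, frame=t))
        roundn.append(roundness(mask))
        nuclei.append(detect_nuclei(frame.pixels, seg.body_mask, px_size))

    track = track_centroid(body_masks, px_size, stack.frame_interval)
    n = len(stack)
    rearranged = np.zeros(n, dtype=bool)
    for t in range(n - 1):
        if detect_rearrangement(nuclei[t], nuclei[t + 1]):
            rearranged[t] = True
            rearranged[t + 1] = True
    rounded = np.array(roundn) >= rounded_circularity
    score = tumbling_index(rounded, rearranged)
    return {
        "track": track,
        "extensions": all_ext,
        "sector_summary": sector_summary(all_ext),
        "roundness": np.array(roundn),
        "tumbling": score,
        "forward_speed_um_per_min": forward_speed(track),
        "tumbling_index_pct": score.tumbling_index_pct,
    }
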