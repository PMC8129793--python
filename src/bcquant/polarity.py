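"""Line-scan polarity profiling and mosaic intensity ratios.

A line scan through the centre of the cluster (anterior→posterior)
yields an intensity profile; peaks are detected, their areas integrated
above a local linear baseline, and the areas assigned to the back,
middle, or front third of the cluster extent and normalised to percent
of total — the BMF readout of cortical-vs-junctional polarity.

Mosaic quantification compares a marked sub-clone against its
wild-type sibling region using mean intensity or raw integrated
density (the plain sum of pixel intensities over the region).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from bcquant.types import CalibratedImage


@dataclass
class LineProfile:
    """Sampled intensities along an anterior→posterior scan line."""

    positions_um: np.ndarray
    intensities: np.ndarray
    scan_width_px: int = 1

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions_um.shape != self.intensities.shape:
            raise ValueError("positions and intensities must have equal length")
        if self.positions_um.size >= 2 and not np.all(np.diff(self.positions_um) > 0):
            raise ValueError("positions must be strictly increasing")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LineProfile":
        return cls(df["position_um"].to_numpy(), df["intensity"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position_um": self.positions_um, "intensity": self.intensities})


@dataclass
class Peak:
    """One detected peak with its support and integrated area."""

    apex_um: float
    left_base_um: float
    right_base_um: float
    prominence: float
    area: float = 0.0  # units·µm, filled by area_under_peaks


@dataclass
class BMFFractions:
    """Back/middle/front percentages of total peak area (sum to 100)."""

    back: float
    middle: float
    front: float


@dataclass
class MosaicRatio:
    """Test/control intensity ratio of a mosaic image."""

    numerator: float
    denominator: float
    ratio: float
    fold: float  # reported as the >= 1 fold change


def extract_line_profile(image: CalibratedImage, p0_um: tuple[float, float],
                         p1_um: tuple[float, float], width_px: int = 3,
                         n_samples: int | None = None) -> LineProfile:
    """Sample intensities along the segment p0→p1 (µm), averaging
    ``width_px`` perpendicular samples at each position.

    p0 should be the anterior end so positions run anterior→posterior.
    """
    from scipy.ndimage import map_coordinates

    px = image.pixel_size
    p0 = np.asarray(p0_um, dtype=float) / px
    p1 = np.asarray(p1_um, dtype=float) / px
    h, w = image.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= w - 1 and 0 <= p[1] <= h - 1):
            raise ValueError("scan endpoints must lie within the image")
    length_px = float(np.hypot(*(p1 - p0)))
    if length_px == 0:
        raise ValueError("scan line has zero length")
    if n_samples is None:
        n_samples = max(2, int(np.ceil(length_px)) + 1)
    ts = np.linspace(0.0, 1.0, n_samples)
    xy = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    direction = (p1 - p0) / length_px
    normal = np.array([-direction[1], direction[0]])
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    samples = np.zeros((len(offsets), n_samples))
    for i, off in enumerate(offsets):
        pts = xy + off * normal[None, :]
        samples[i] = map_coordinates(image.pixels, [pts[:, 1], pts[:, 0]],
                                     order=1, mode="nearest")
    positions = ts * length_px * px
    return LineProfile(positions, samples.mean(axis=0), scan_width_px=width_px)


def detect_peaks(profile: LineProfile, min_prominence: float | None = None) -> list[Peak]:
    """Local maxima with prominence above ``min_prominence``.

    Default prominence threshold is 10% of the profile's dynamic range.
    Each peak's support runs to the higher of the two flanking minima
    and is truncated at the midpoint to any adjacent apex, so supports
    never overlap.
    """
    y = profile.intensities
    x = profile.positions_um
    if np.ptp(y) == 0:
        return []
    if min_prominence is None:
        min_prominence = 0.10 * float(np.ptp(y))
    idx, _ = find_peaks(y, prominence=min_prominence)
    if idx.size == 0:
        return []
    prom, left_bases, right_bases = peak_prominences(y, idx)
    peaks: list[Peak] = []
    for k, apex in enumerate(idx):
        lb, rb = int(left_bases[k]), int(right_bases[k])
        if k > 0:
            lb = max(lb, int(round((idx[k - 1] + apex) / 2)))
        if k < idx.size - 1:
            rb = min(rb, int(round((idx[k + 1] + apex) / 2)))
        peaks.append(Peak(apex_um=float(x[apex]), left_base_um=float(x[lb]),
                          right_base_um=float(x[rb]), prominence=float(prom[k])))
    return peaks


def area_under_peaks(profile: LineProfile, peaks: list[Peak]) -> list[Peak]:
    """Trapezoidal area above a linear baseline for each peak support.

    The baseline runs between the profile values at the peak's bases;
    negative contributions are clamped to zero.  Returns new Peak
    records with areas filled in.
    """
    x, y = profile.positions_um, profile.intensities
    out: list[Peak] = []
    for p in peaks:
        sel = (x >= p.left_base_um) & (x <= p.right_base_um)
        xs, ys = x[sel], y[sel]
        if xs.size < 2:
            out.append(Peak(p.apex_um, p.left_base_um, p.right_base_um, p.prominence, 0.0))
            continue
        baseline = np.interp(xs, [xs[0], xs[-1]], [ys[0], ys[-1]])
        excess = np.maximum(ys - baseline, 0.0)
        out.append(Peak(p.apex_um, p.left_base_um, p.right_base_um, p.prominence,
                        float(np.trapezoid(excess, xs))))
    return out


def bmf_fractions(peaks: list[Peak], cluster_extent_um: tuple[float, float]) -> BMFFractions | None:
    """Assign peak areas to back/middle/front thirds and normalise.

    The anterior (back), interior (middle) and posterior (front) thirds
    of ``cluster_extent_um`` partition the scan; each peak contributes
    its whole area to the third containing its apex.  Returns None when
    the total area is zero (fractions undefined).
    """
    lo, hi = cluster_extent_um
    if hi <= lo:
        raise ValueError("cluster extent must have positive length")
    third = (hi - lo) / 3.0
    sums = {"back": 0.0, "middle": 0.0, "front": 0.0}
    for p in peaks:
        if p.apex_um < lo + third:
            sums["back"] += p.area
        elif p.apex_um < lo + 2 * third:
            sums["middle"] += p.area
        else:
            sums["front"] += p.area
    total = sum(sums.values())
    if total <= 0:
        return None
    return BMFFractions(back=100.0 * sums["back"] / total,
                        middle=100.0 * sums["middle"] / total,
                        front=100.0 * sums["front"] / total)


def middle_fold_shift(bmf_test: BMFFractions, bmf_control: BMFFractions) -> float:
    """Fold change of the middle (interior-junction) fraction, test/control."""
    if bmf_control.middle <= 0:
        raise ValueError("control middle fraction must be > 0")
    return bmf_test.middle / bmf_control.middle


def raw_integrated_density(image: CalibratedImage, mask: np.ndarray) -> float:
    """Sum of pixel intensities within the mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    return float(image.pixels[mask].sum())


def mosaic_ratio(image: CalibratedImage, region_test: np.ndarray,
                 region_control: np.ndarray, mode: str = "mean") -> MosaicRatio:
    """Test/control intensity ratio between two mosaic sub-regions.

    ``mode='mean'`` compares mean intensities (robust to unequal region
    sizes); ``mode='rid'`` compares raw integrated densities.  The fold
    is reported on the ≥1 scale: control/test when the test region is
    dimmer, test/control otherwise.
    """
    rt = np.asarray(region_test, dtype=bool)
    rc = np.asarray(region_control, dtype=bool)
    if not rt.any() or not rc.any():
        raise ValueError("both mosaic regions must be nonempty")
    if mode == "mean":
        num = float(image.pixels[rt].mean())
        den = float(image.pixels[rc].mean())
    elif mode == "rid":
        num = raw_integrated_density(image, rt)
        den = raw_integrated_density(image, rc)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if den <= 0 or num <= 0:
        raise ValueError("region intensities must be positive to form a ratio")
    ratio = num / den
    return MosaicRatio(num, den, ratio, fold=1.0 / ratio if ratio < 1 else ratio)


def junction_ratio(image: CalibratedImage, inner_mask: np.ndarray,
                   outer_mask: np.ndarray) -> float:
    """Mean intensity inside the cluster junctions over outside ones."""
    inner = np.asarray(inner_mask, dtype=bool)
    outer = np.asarray(outer_mask, dtype=bool)
    if not inner.any() or not outer.any():
        raise ValueError("both junction masks must be nonempty")
    return float(image.pixels[inner].mean() / image.pixels[outer].mean())
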