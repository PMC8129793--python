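"""Calibrated image containers shared across the pipeline.

All physical quantities downstream are expressed in micrometres (µm) and
minutes; the containers here carry the calibration needed to convert
from pixel/frame units.  Screen convention: x increases rightward
(anterior to posterior once oriented), y increases downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


@dataclass
class CalibratedImage:
    """A 2-D intensity grid with physical pixel calibration.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities.
    pixel_size
        Lateral calibration in µm per pixel (isotropic).
    oriented_anterior_left
        True once the egg chamber has been rotated/mirrored so the
        anterior end is at the left of the image.
    """

    pixels: np.ndarray
    pixel_size: float
    oriented_anterior_left: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0 µm/px, got {self.pixel_size}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("image intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, **kw) -> "CalibratedImage":
        return replace(self, pixels=pixels, **kw)

    def write_tiff(self, path) -> None:
        """Write as 16-bit TIFF with resolution metadata (pixels per µm)."""
        data = np.clip(np.round(self.pixels), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data, resolution=(1.0 / self.pixel_size, 1.0 / self.pixel_size))

    @classmethod
    def read_tiff(cls, path, pixel_size: float, oriented_anterior_left: bool = False) -> "CalibratedImage":
        return cls(tifffile.imread(path), pixel_size, oriented_anterior_left)


@dataclass
class ImageStack:
    """An ordered stack of frames sharing shape and calibration.

    The same container serves time series (``frame_interval`` in
    minutes) and z-stacks (``frame_interval`` irrelevant but kept
    positive).
    """

    frames: list[CalibratedImage] = field(default_factory=list)
    frame_interval: float = 3.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError(f"frame_interval must be > 0 min, got {self.frame_interval}")
        if self.frames:
            shape = self.frames[0].shape
            px = self.frames[0].pixel_size
            for i, f in enumerate(self.frames):
                if f.shape != shape:
                    raise ValueError(f"frame {i} shape {f.shape} differs from {shape}")
                if f.pixel_size != px:
                    raise ValueError(f"frame {i} pixel_size {f.pixel_size} differs from {px}")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> CalibratedImage:
        return self.frames[i]

    @property
    def pixel_size(self) -> float:
        if not self.frames:
            raise ValueError("empty stack has no calibration")
        return self.frames[0].pixel_size

    def as_array(self) -> np.ndarray:
        """Stack frames into a (T, H, W) array."""
        if not self.frames:
            raise ValueError("empty stack")
        return np.stack([f.pixels for f in self.frames])

    def write_tiff(self, path) -> None:
        data = np.clip(np.round(self.as_array()), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data)

    @classmethod
    def read_tiff(cls, path, pixel_size: float, frame_interval: float = 3.0,
                  oriented_anterior_left: bool = False) -> "ImageStack":
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        frames = [CalibratedImage(a, pixel_size, oriented_anterior_left) for a in arr]
        return cls(frames, frame_interval)


@dataclass
class ClusterSegmentation:
    """Partition of the thresholded cluster into body and extensions.

    Invariant: ``body_mask`` and the extension masks are pairwise
    disjoint and their union equals ``full_mask`` exactly.
    """

    full_mask: np.ndarray
    body_mask: np.ndarray
    extensions: list[np.ndarray]
    pixel_size: float

    def __post_init__(self) -> None:
        self.full_mask = np.asarray(self.full_mask, dtype=bool)
        self.body_mask = np.asarray(self.body_mask, dtype=bool)
        self.extensions = [np.asarray(e, dtype=bool) for e in self.extensions]
        union = self.body_mask.copy()
        for e in self.extensions:
            if np.any(union & e):
                raise ValueError("segmentation components overlap")
            union |= e
        if not np.array_equal(union, self.full_mask):
            raise ValueError("body and extensions do not partition the full mask")

    @property
    def px_area(self) -> float:
        """Area of one pixel in µm²."""
        return self.pixel_size**2

    def area_um2(self, mask: np.ndarray) -> float:
        return float(np.count_nonzero(mask)) * self.px_area
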