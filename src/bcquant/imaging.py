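"""Projection, orientation, background subtraction and cluster segmentation.

The live-imaging pipeline works on maximum projections of the GFP
channel; egg chambers are oriented anterior-left so the migration axis
is +x, the cluster is thresholded to a single binary mask, and the mask
is split into a cell body and protrusive extensions by morphological
opening.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening

from bcquant.types import CalibratedImage, ClusterSegmentation, ImageStack

#: smallest extension kept, in µm² — rejects single-pixel noise
DEFAULT_MIN_EXTENSION_AREA_UM2 = 2.0


def max_project(stack: ImageStack) -> CalibratedImage:
    """Maximum-intensity projection over the stack (z) axis.

    Each output pixel is the maximum of that pixel over all slices.
    """
    if len(stack) == 0:
        raise ValueError("cannot project an empty stack")
    proj = stack.as_array().max(axis=0)
    first = stack.frames[0]
    return CalibratedImage(proj, first.pixel_size, first.oriented_anterior_left)


def orient_anterior_left(image: CalibratedImage, anterior_side: str = "left") -> CalibratedImage:
    """Rotate/mirror so the anterior end of the egg chamber is at the left.

    Only lossless operations are used (multiples of 90° and mirrors).
    ``anterior_side`` names where the anterior currently is.
    """
    px = image.pixels
    if anterior_side == "left":
        out = px
    elif anterior_side == "right":
        out = px[:, ::-1]
    elif anterior_side == "top":
        # anterior at top -> rotate 90° clockwise brings it to the left
        out = np.rot90(px, k=-1)
    elif anterior_side == "bottom":
        out = np.rot90(px, k=1)
    else:
        raise ValueError(f"unknown anterior_side {anterior_side!r}")
    return CalibratedImage(out.copy(), image.pixel_size, oriented_anterior_left=True)


def subtract_background(
    image: CalibratedImage,
    method: str = "percentile",
    value: float = 5.0,
) -> tuple[CalibratedImage, float]:
    """Subtract a scalar background estimate, clamping at zero.

    ``method='constant'`` subtracts ``value`` directly;
    ``method='percentile'`` estimates background as the ``value``-th
    intensity percentile.  Returns the corrected image and the estimate
    used, for provenance logging.
    """
    if method == "constant":
        estimate = float(value)
    elif method == "percentile":
        if not 0 <= value <= 100:
            raise ValueError(f"percentile must be in [0, 100], got {value}")
        estimate = float(np.percentile(image.pixels, value))
    else:
        raise ValueError(f"unknown background method {method!r}")
    corrected = np.maximum(image.pixels - estimate, 0.0)
    return image.with_pixels(corrected), estimate


def threshold_cluster(
    image: CalibratedImage,
    method: str = "otsu",
    value: float | None = None,
) -> np.ndarray:
    """Threshold the cluster and keep the largest connected component.

    The imaged field contains a single border-cell cluster; smaller
    foreground blobs are debris and discarded.  ``method='absolute'``
    uses ``value`` as the threshold, ``method='otsu'`` picks it
    automatically.
    """
    px = image.pixels
    if method == "absolute":
        if value is None:
            raise ValueError("absolute thresholding requires a value")
        thresh = float(value)
    elif method == "otsu":
        if np.ptp(px) == 0:
            raise ValueError("no cluster found: image is constant")
        thresh = float(threshold_otsu(px))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    fg = px > thresh
    if not fg.any():
        raise ValueError("no cluster found: empty foreground after thresholding")
    labels, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def split_body_extensions(
    full_mask: np.ndarray,
    pixel_size: float,
    opening_radius_um: float | None = None,
    min_extension_area_um2: float = DEFAULT_MIN_EXTENSION_AREA_UM2,
) -> ClusterSegmentation:
    """Split the cluster mask into a cell body and extensions.

    The body is the morphological opening of the mask with a disk of
    ``opening_radius_um`` (default: half the equivalent radius of the
    mask, a scale-free choice).  Extensions are the connected components
    of mask − body with area ≥ ``min_extension_area_um2``; smaller
    residue is folded back into the body so body ∪ extensions equals
    the full mask exactly.
    """
    full_mask = np.asarray(full_mask, dtype=bool)
    n_px = int(np.count_nonzero(full_mask))
    if n_px == 0:
        raise ValueError("empty cluster mask")
    if opening_radius_um is None:
        equiv_radius_um = np.sqrt(n_px / np.pi) * pixel_size
        opening_radius_um = 0.5 * equiv_radius_um
    radius_px = max(1, int(round(opening_radius_um / pixel_size)))
    body = opening(full_mask, disk(radius_px))
    if not body.any():
        raise ValueError(
            f"opening with radius {opening_radius_um:.2f} µm removed the whole mask; "
            "use a smaller opening_radius_um"
        )
    # keep the body connected: opening of a single cluster can in
    # principle leave fragments; keep the largest and demote the rest
    labels, n = ndimage.label(body)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        body = labels == (int(np.argmax(sizes)) + 1)

    residue = full_mask & ~body
    ext_labels, n_ext = ndimage.label(residue)
    extensions: list[np.ndarray] = []
    min_px = min_extension_area_um2 / pixel_size**2
    for i in range(1, n_ext + 1):
        comp = ext_labels == i
        if np.count_nonzero(comp) >= min_px:
            extensions.append(comp)
        else:
            body = body | comp
    return ClusterSegmentation(full_mask, body, extensions, pixel_size)


def mask_centroid_um(mask: np.ndarray, pixel_size: float) -> tuple[float, float]:
    """Area centroid of a binary mask as (x, y) in µm."""
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if xs.size == 0:
        raise ValueError("empty mask has no centroid")
    return float(xs.mean()) * pixel_size, float(ys.mean()) * pixel_size
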