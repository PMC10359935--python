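"""Iris image preprocessing: centre the annulus and normalise its scale.

The raw captures place the iris at an arbitrary position, so the fraction of
iris in the frame varies widely.  The pipeline (a) masks the acquired image
by its ground-truth segmentation, (b) crops away everything outside the GT
bounding box, (c) measures the annulus width d1..d4 and the inner-border to
image-border distance x1..x4 along the four axis directions through the
pupil centroid, (d) pads each side i by max(d1..d4) - x_i + c background
pixels (c defaults to 20), which centres the pupil and equalises the margin,
and (e) resizes to a standard square (256×256 by default).  Directions are
indexed 1=top, 2=bottom, 3=left, 4=right; rows increase downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

DEFAULT_C = 20
DEFAULT_SIZE = 256


def segment_by_gt(acquired: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """Mask the acquired image by the binary GT (iris on black background)."""
    acquired = np.asarray(acquired)
    gt = np.asarray(gt)
    if gt.shape != acquired.shape[: gt.ndim]:
        raise ValueError(f"shape mismatch: image {acquired.shape}, gt {gt.shape}")
    m = (gt > 0)
    if acquired.ndim == 3 and gt.ndim == 2:
        m = m[..., None]
    return np.where(m, acquired, 0.0)


def crop_noniris(image: np.ndarray, gt: np.ndarray):
    """Crop image and GT to the tight bounding box of the GT's nonzero pixels."""
    gt = np.asarray(gt)
    rows = np.flatnonzero(gt.any(axis=1))
    cols = np.flatnonzero(gt.any(axis=0))
    if rows.size == 0:
        raise ValueError("GT mask is empty; nothing to crop to")
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    return np.asarray(image)[r0:r1, c0:c1], gt[r0:r1, c0:c1]


@dataclass(frozen=True)
class IrisExtents:
    """Per-direction annulus widths (d) and inner-border margins (x).

    Index order: 1=top, 2=bottom, 3=left, 4=right.
    """

    d1: int
    d2: int
    d3: int
    d4: int
    x1: int
    x2: int
    x3: int
    x4: int

    @property
    def d(self):
        return (self.d1, self.d2, self.d3, self.d4)

    @property
    def x(self):
        return (self.x1, self.x2, self.x3, self.x4)


def _hole_centroid(gt: np.ndarray):
    """Centroid of the pupil hole: interior zeros enclosed by the annulus."""
    filled = ndimage.binary_fill_holes(gt > 0)
    hole = filled & ~(gt > 0)
    if not hole.any():
        raise ValueError("GT mask has no interior hole (no pupil detectable)")
    r, c = np.nonzero(hole)
    return int(round(r.mean())), int(round(c.mean()))


def measure_extents(gt: np.ndarray) -> IrisExtents:
    """Walk the four axis rays through the pupil centroid.

    d_i counts mask pixels along the ray from the centroid to border i;
    x_i is the distance from the ray's inner-border crossing (first mask
    pixel met walking outward) to image border i.
    """
    gt = (np.asarray(gt) > 0)
    h, w = gt.shape
    r0, c0 = _hole_centroid(gt)
    rays = {
        1: gt[r0::-1, c0],   # toward the top (decreasing row)
        2: gt[r0:, c0],      # bottom
        3: gt[r0, c0::-1],   # left
        4: gt[r0, c0:],      # right
    }
    borders = {1: r0, 2: h - 1 - r0, 3: c0, 4: w - 1 - c0}
    d, x = {}, {}
    for i, ray in rays.items():
        ones = np.flatnonzero(ray)
        d[i] = int(ones.size)
        if ones.size:
            inner = int(ones[0])          # offset of the inner border crossing
            x[i] = int(borders[i] - inner)
        else:
            x[i] = 0
    return IrisExtents(d[1], d[2], d[3], d[4], x[1], x[2], x[3], x[4])


def center_pad(image: np.ndarray, extents: IrisExtents, c: int = DEFAULT_C):
    """Pad side i with max(d1..d4) - x_i + c background (zero) pixels.

    After the pad every inner-border crossing sits max(d) + c pixels from its
    border, which centres the pupil.  Negative pads are clamped to 0.
    """
    dmax = max(extents.d)
    pads = [max(0, dmax - xi + c) for xi in extents.x]
    top, bottom, left, right = pads
    pad_width = [(top, bottom), (left, right)]
    image = np.asarray(image)
    if image.ndim == 3:
        pad_width.append((0, 0))
    return np.pad(image, pad_width)


def standardize(image: np.ndarray, size: int = DEFAULT_SIZE,
                binary: bool = False) -> np.ndarray:
    """Bilinear resize to size×size (nearest + re-threshold for masks)."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    order = 0 if binary else 1
    out = sktransform.resize(image, (size, size) + image.shape[2:], order=order,
                             mode="edge", anti_aliasing=False,
                             preserve_range=True)
    if binary:
        out = (out > 0.5).astype(np.uint8)
    return out


def preprocess_pipeline(acquired: np.ndarray, gt: np.ndarray,
                        c: int = DEFAULT_C, size: int = DEFAULT_SIZE):
    """Full pipeline: segment → crop → measure → pad → resize.

    Returns the preprocessed (image, gt) pair, both size×size, with the
    pupil centred up to rasterisation.
    """
    seg = segment_by_gt(acquired, gt)
    seg, gt_c = crop_noniris(seg, gt)
    extents = measure_extents(gt_c)
    padded = center_pad(seg, extents, c)
    padded_gt = center_pad(gt_c.astype(np.uint8), extents, c)
    return (standardize(padded, size),
            standardize(padded_gt, size, binary=True))
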