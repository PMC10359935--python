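"""Seeded synthetic eye-image fixtures.

Real iris texture shows ridges arranged radially near the pupil and
circumferentially toward the outer boundary.  The generator emulates this
with band-limited harmonic noise synthesised in polar coordinates: a
"radial-ridge" field varying along the angular coordinate and a
"circumferential-ridge" field varying along the radial coordinate, blended
with a radius-dependent weight.  Occlusion masks come in the three styles
seen in real captures: an upper-eyelid arc, a lower-eyelid arc, and a bundle
of thin curved eyelash strokes.

Everything is a pure function of its spec (including the seed), so every
downstream stage is testable without any image download.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image as PILImage
from skimage import transform as sktransform
from skimage.draw import line as skline

MASK_KINDS = ("eyelid_upper", "eyelid_lower", "eyelash_strokes")
AUGMENT_MODES = tuple(range(1, 9))


@dataclass(frozen=True)
class IrisSpec:
    """Geometry and texture parameters of one synthetic iris."""

    image_size: int = 256
    center: tuple | None = None          # (row, col); None = image centre
    pupil_radius: float = 40.0
    iris_radius: float = 100.0
    texture_seed: int = 0
    texture_scale: int = 24              # number of harmonic bands
    radial_blend: float = 0.7            # 0 = circumferential everywhere
    channels: int = 1

    def resolved_center(self):
        if self.center is not None:
            return tuple(self.center)
        return ((self.image_size - 1) / 2.0, (self.image_size - 1) / 2.0)

    def validate(self):
        if not 0 < self.pupil_radius < self.iris_radius:
            raise ValueError(
                f"need 0 < pupil_radius < iris_radius, got "
                f"{self.pupil_radius}, {self.iris_radius}"
            )
        r0, c0 = self.resolved_center()
        for coord in (r0, c0):
            if coord - self.iris_radius < -0.5 or coord + self.iris_radius > self.image_size - 0.5:
                raise ValueError("iris annulus does not fit inside the image")
        if not 0.0 <= self.radial_blend <= 1.0:
            raise ValueError("radial_blend must be in [0, 1]")


@dataclass(frozen=True)
class MaskSpec:
    """One occlusion mask: kind, target coverage of the iris area, shape."""

    kind: str = "eyelid_upper"
    coverage_range: tuple = (0.1, 0.3)   # fraction of GT iris area occluded
    stroke_count: int = 12               # eyelash style only
    arc_curvature: float = 0.35          # eyelid arc sagitta / image width
    seed: int = 0

    def validate(self):
        if self.kind not in MASK_KINDS:
            raise ValueError(f"kind must be one of {MASK_KINDS}, got {self.kind!r}")
        lo, hi = self.coverage_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"invalid coverage_range {self.coverage_range}")


@dataclass
class TrainingTriplet:
    occluded: np.ndarray
    target: np.ndarray
    occlusion: np.ndarray
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# iris generation
# ---------------------------------------------------------------------------

def _harmonic(rng, t, n_bands):
    """Band-limited 2π-periodic noise: sum of cosines with random phases."""
    out = np.zeros_like(t)
    for k in range(1, n_bands + 1):
        amp = rng.normal() / np.sqrt(k)  # mild 1/f^0.5 spectral decay
        phase = rng.uniform(0, 2 * np.pi)
        out += amp * np.cos(k * t + phase)
    return out


def generate_iris(spec: IrisSpec):
    """Render one synthetic iris; returns (image, gt_mask).

    The image is float in [0, 1], nonzero only on the annulus
    {pupil_radius <= r <= iris_radius}; the mask is exactly that annulus.
    """
    spec.validate()
    n = spec.image_size
    r0, c0 = spec.resolved_center()
    rows, cols = np.mgrid[0:n, 0:n].astype(np.float64)
    r = np.hypot(rows - r0, cols - c0)
    theta = np.arctan2(rows - r0, cols - c0)
    gt = ((r >= spec.pupil_radius) & (r <= spec.iris_radius)).astype(np.uint8)

    rng = np.random.default_rng(spec.texture_seed)
    # radial ridges: intensity varies along theta (constant along a ray)
    radial_field = _harmonic(rng, theta * 1.0, spec.texture_scale)
    # circumferential ridges: intensity varies along r (constant on circles)
    band = max(spec.iris_radius - spec.pupil_radius, 1e-9)
    rnorm = np.clip((r - spec.pupil_radius) / band, 0.0, 1.0)
    circ_field = _harmonic(rng, 2 * np.pi * rnorm, spec.texture_scale)

    # blend weight: radial near the pupil, fading circumferential outward
    w = spec.radial_blend * (1.0 - rnorm)
    tex = w * radial_field + (1.0 - w) * circ_field
    lo, hi = tex.min(), tex.max()
    tex = 0.15 + 0.75 * (tex - lo) / max(hi - lo, 1e-12)
    img = tex * gt
    if spec.channels == 3:
        img = np.stack([img] * 3, axis=-1)
    return img.astype(np.float64), gt


# ---------------------------------------------------------------------------
# occlusion masks
# ---------------------------------------------------------------------------

def _eyelid_arc_mask(shape, depth, curvature, from_top: bool):
    """Region between the image edge and a parabolic arc of given depth."""
    h, w = shape
    cols = np.arange(w)
    x = (cols - (w - 1) / 2.0) / max((w - 1) / 2.0, 1)
    sag = curvature * h
    boundary = depth - sag * x**2  # arc row measured from the entering edge
    rows = np.arange(h)[:, None]
    if from_top:
        return (rows <= boundary[None, :]).astype(np.uint8)
    return (rows >= (h - 1) - boundary[None, :]).astype(np.uint8)


def _coverage(mask, gt, gt_area):
    return float(np.count_nonzero(mask & gt)) / gt_area


def _eyelid_mask(spec: MaskSpec, gt, gt_area, from_top: bool):
    lo, hi = spec.coverage_range
    target = (lo + hi) / 2.0
    h, w = gt.shape
    f = lambda depth: _coverage(
        _eyelid_arc_mask((h, w), depth, spec.arc_curvature, from_top), gt, gt_area
    )
    d_lo, d_hi = -spec.arc_curvature * h, float(2 * h)
    if f(d_hi) < lo:
        raise ValueError("coverage_range infeasible for this GT mask")
    for _ in range(60):  # bisect depth for the target coverage
        mid = 0.5 * (d_lo + d_hi)
        if f(mid) < target:
            d_lo = mid
        else:
            d_hi = mid
    mask = _eyelid_arc_mask((h, w), d_hi, spec.arc_curvature, from_top)
    if not lo <= _coverage(mask, gt, gt_area) <= hi:
        raise ValueError("coverage_range infeasible for this GT mask")
    return mask


def _eyelash_mask(spec: MaskSpec, gt, gt_area):
    """Union of thin curved strokes entering from the top, grown until the
    realized coverage lands inside coverage_range (the last stroke is
    trimmed pixel-by-pixel if it would overshoot)."""
    lo, hi = spec.coverage_range
    h, w = gt.shape
    rng = np.random.default_rng(spec.seed)
    mask = np.zeros_like(gt)
    max_strokes = max(spec.stroke_count * 40, 400)
    for _ in range(max_strokes):
        if _coverage(mask, gt, gt_area) >= lo:
            break
        # quadratic Bezier from the top edge curving downward
        c_start = rng.uniform(0.1 * w, 0.9 * w)
        c_ctrl = c_start + rng.normal(0, 0.08 * w)
        c_end = c_start + rng.normal(0, 0.2 * w)
        r_end = rng.uniform(0.45 * h, 0.95 * h)
        t = np.linspace(0, 1, 4 * h)
        rr = (1 - t) ** 2 * 0.0 + 2 * (1 - t) * t * (0.5 * r_end) + t**2 * r_end
        cc = (1 - t) ** 2 * c_start + 2 * (1 - t) * t * c_ctrl + t**2 * c_end
        pts = np.unique(
            np.stack([np.clip(rr, 0, h - 1).astype(int),
                      np.clip(cc, 0, w - 1).astype(int)], axis=1),
            axis=0,
        )
        stroke = np.zeros_like(gt)
        stroke[pts[:, 0], pts[:, 1]] = 1
        new = stroke & ~mask & gt
        budget = int(np.floor(hi * gt_area)) - np.count_nonzero(mask & gt)
        if np.count_nonzero(new) > budget:
            keep = np.argwhere(new)[:budget]
            stroke = np.zeros_like(gt)
            if len(keep):
                stroke[keep[:, 0], keep[:, 1]] = 1
        mask |= stroke
    cov = _coverage(mask, gt, gt_area)
    if not lo <= cov <= hi:
        raise ValueError(
            f"coverage_range {spec.coverage_range} infeasible for this GT mask "
            f"(reached {cov:.3f})"
        )
    return mask


def generate_mask(spec: MaskSpec, gt: np.ndarray) -> np.ndarray:
    """Binary occlusion mask whose overlap with ``gt`` lies in coverage_range."""
    spec.validate()
    gt = (np.asarray(gt) > 0).astype(np.uint8)
    gt_area = int(np.count_nonzero(gt))
    if gt_area == 0:
        raise ValueError("GT mask is empty")
    lo, hi = spec.coverage_range
    if hi == 0.0:
        return np.zeros_like(gt)
    if spec.kind == "eyelid_upper":
        return _eyelid_mask(spec, gt, gt_area, from_top=True)
    if spec.kind == "eyelid_lower":
        return _eyelid_mask(spec, gt, gt_area, from_top=False)
    return _eyelash_mask(spec, gt, gt_area)


def apply_occlusion(target: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Logical combination: target where mask == 0, black where mask == 1."""
    target = np.asarray(target)
    mask = np.asarray(mask)
    if mask.shape != target.shape[: mask.ndim]:
        raise ValueError(f"shape mismatch: image {target.shape}, mask {mask.shape}")
    m = (mask > 0)
    if target.ndim == 3 and mask.ndim == 2:
        m = m[..., None]
    return np.where(m, 0.0, target)


# ---------------------------------------------------------------------------
# 8-fold augmentation
# ---------------------------------------------------------------------------

def augment(image: np.ndarray, mode: int, angle: float = 10.0,
            shift_frac: float = 0.1, crop_ratio: float = 0.9,
            binary: bool = False) -> np.ndarray:
    """The eight deterministic expansion modes, output resized to input size.

    ====  ========================================
    mode  transform
    ====  ========================================
    1     clockwise rotation by ``angle`` degrees
    2     counterclockwise rotation
    3     horizontal flip
    4     shift up by ``shift_frac`` (crop + resize back)
    5     shift down
    6     shift left
    7     shift right
    8     centre crop at ``crop_ratio``, resized back
    ====  ========================================

    Rotation angle, shift fraction and crop ratio are configurable; the
    defaults (±10°, 0.1, 0.9) keep the iris annulus inside the frame.
    ``binary=True`` uses nearest-neighbour resampling and re-thresholds, for
    masks.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape[:2]
    order = 0 if binary else 1

    def _resize(img):
        return sktransform.resize(img, (h, w) + img.shape[2:], order=order,
                                  mode="edge", anti_aliasing=False,
                                  preserve_range=True)

    if mode == 1:
        out = sktransform.rotate(image, -angle, order=order, mode="constant",
                                 cval=0.0, preserve_range=True)
    elif mode == 2:
        out = sktransform.rotate(image, angle, order=order, mode="constant",
                                 cval=0.0, preserve_range=True)
    elif mode == 3:
        out = image[:, ::-1].copy()
    elif mode in (4, 5, 6, 7):
        d_h, d_w = int(round(shift_frac * h)), int(round(shift_frac * w))
        if mode == 4:    # content moves up: keep the lower window
            out = _resize(image[d_h:, :])
        elif mode == 5:  # content moves down
            out = _resize(image[: h - d_h, :])
        elif mode == 6:  # content moves left
            out = _resize(image[:, d_w:])
        else:            # content moves right
            out = _resize(image[:, : w - d_w])
    elif mode == 8:
        ch, cw = int(round(crop_ratio * h)), int(round(crop_ratio * w))
        r0, c0 = (h - ch) // 2, (w - cw) // 2
        out = _resize(image[r0 : r0 + ch, c0 : c0 + cw])
    else:
        raise ValueError(f"augmentation mode must be in 1..8, got {mode}")
    if binary:
        out = (out > 0.5).astype(np.uint8)
    return out


def augment_pair(image, gt, mode, **kwargs):
    return (augment(image, mode, **kwargs),
            augment(gt, mode, binary=True, **kwargs))


# ---------------------------------------------------------------------------
# dataset builder
# ---------------------------------------------------------------------------

def build_triplets(base_pairs, mask_specs=None, modes=AUGMENT_MODES,
                   seed: int = 0, **augment_kwargs):
    """Expand base (image, gt) pairs into training triplets.

    Each base image is augmented by every mode and combined with one mask of
    each kind, i.e. len(modes) × 3 triplets per base image (24 with the full
    eight-mode expansion).
    """
    if mask_specs is None:
        mask_specs = [MaskSpec(kind=k) for k in MASK_KINDS]
    rng = np.random.default_rng(seed)
    triplets = []
    for bi, (img, gt) in enumerate(base_pairs):
        for mode in modes:
            a_img, a_gt = augment_pair(img, gt, mode, **augment_kwargs)
            for ms in mask_specs:
                ms_seeded = MaskSpec(kind=ms.kind, coverage_range=ms.coverage_range,
                                     stroke_count=ms.stroke_count,
                                     arc_curvature=ms.arc_curvature,
                                     seed=int(rng.integers(0, 2**31 - 1)))
                occ_mask = generate_mask(ms_seeded, a_gt)
                triplets.append(TrainingTriplet(
                    occluded=apply_occlusion(a_img, occ_mask),
                    target=a_img,
                    occlusion=occ_mask,
                    meta=dict(base=bi, mask_kind=ms.kind, augmentation_mode=mode,
                              seed=ms_seeded.seed),
                ))
    return triplets


def save_png(path, image):
    """Write a float [0,1] or binary array as 8-bit PNG."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    PILImage.fromarray(arr).save(path)


def load_png(path):
    """Read an 8-bit PNG back to float in [0, 1] (grayscale kept 2-D)."""
    arr = np.asarray(PILImage.open(path))
    return arr.astype(np.float64) / 255.0


def write_dataset(triplets, out_dir):
    """Directory tree occluded/ target/ mask/ plus a TSV manifest."""
    for sub in ("occluded", "target", "mask"):
        os.makedirs(os.path.join(out_dir, sub), exist_ok=True)
    manifest = os.path.join(out_dir, "manifest.tsv")
    with open(manifest, "w") as fh:
        fh.write("id\tmask_kind\taugmentation_mode\tseed\n")
        for i, t in enumerate(triplets):
            name = f"{i:05d}.png"
            save_png(os.path.join(out_dir, "occluded", name), t.occluded)
            save_png(os.path.join(out_dir, "target", name), t.target)
            save_png(os.path.join(out_dir, "mask", name),
                     (t.occlusion * 255).astype(np.uint8))
            fh.write(f"{i:05d}\t{t.meta.get('mask_kind', '')}\t"
                     f"{t.meta.get('augmentation_mode', '')}\t"
                     f"{t.meta.get('seed', '')}\n")
    return manifest
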