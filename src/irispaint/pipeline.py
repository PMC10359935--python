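"""End-to-end wiring: dataset synthesis, miniature training, inpainting.

The demo exercises the whole method at desk scale: synthesize occluded iris
triplets, run the two-stage adversarial training on a miniature
configuration (64×64 images, channel widths divided by 4), inpaint a
held-out batch and report PSNR before/after together with the loss
trajectory.  One master seed fans out to fixed per-subsystem offsets so each
stage is independently reproducible.
"""

from __future__ import annotations

import numpy as np

from . import metrics
from .nn.models import init_params, scaled_widths
from .preprocess import preprocess_pipeline
from .synthetic import IrisSpec, MaskSpec, MASK_KINDS, build_triplets, generate_iris
from .training import TrainConfig, inpaint_batch, train

# fixed offsets fanning the master seed out to the subsystems
SEED_DATA, SEED_COARSE, SEED_FINE, SEED_DISC, SEED_TRAIN = 11, 23, 37, 53, 71


def make_synthetic_dataset(n_base: int = 6, size: int = 64, seed: int = 0,
                           modes=(1, 2, 3, 4, 5, 6, 7, 8),
                           coverage=(0.1, 0.3)):
    """Preprocessed synthetic triplets: n_base × len(modes) × 3 masks.

    Base irises are rendered at 2×size with randomised centre and radii,
    pushed through the preprocessing pipeline to size×size, then expanded by
    the augmentation modes and the three occlusion styles.
    """
    rng = np.random.default_rng(seed + SEED_DATA)
    pairs = []
    for _ in range(n_base):
        big = 2 * size
        iris_r = rng.uniform(0.30, 0.38) * big
        pupil_r = rng.uniform(0.35, 0.5) * iris_r
        margin = big / 2 - iris_r
        jitter = 0.5 * margin
        center = (big / 2 + rng.uniform(-jitter, jitter),
                  big / 2 + rng.uniform(-jitter, jitter))
        spec = IrisSpec(image_size=big, center=center, pupil_radius=pupil_r,
                        iris_radius=iris_r,
                        texture_seed=int(rng.integers(0, 2**31 - 1)))
        img, gt = generate_iris(spec)
        pairs.append(preprocess_pipeline(img, gt, c=8, size=size))
    mask_specs = [MaskSpec(kind=k, coverage_range=coverage) for k in MASK_KINDS]
    return build_triplets(pairs, mask_specs=mask_specs, modes=modes,
                          seed=seed + SEED_DATA)


def triplets_to_arrays(triplets):
    occ = np.stack([t.occluded for t in triplets]).astype(np.float32)
    tgt = np.stack([t.target for t in triplets]).astype(np.float32)
    return occ, tgt


def build_miniature_nets(seed: int = 0, width_factor: int = 4, in_ch: int = 1,
                         skip_mode: str = "dacc"):
    coarse = init_params("coarse", scaled_widths("coarse", width_factor),
                         seed=seed + SEED_COARSE, in_ch=in_ch)
    fine = init_params("fine", scaled_widths("fine", width_factor),
                       seed=seed + SEED_FINE, in_ch=in_ch, skip_mode=skip_mode)
    disc = init_params("discriminator", scaled_widths("discriminator", width_factor),
                       seed=seed + SEED_DISC, in_ch=in_ch)
    return coarse, fine, disc


def batch_psnr(a: np.ndarray, b: np.ndarray) -> float:
    """Mean PSNR (dB) over a batch of image pairs, peak 1.0."""
    a = np.asarray(a)
    b = np.asarray(b)
    return float(np.mean([metrics.psnr(x.squeeze(), y.squeeze())
                          for x, y in zip(a, b)]))


def end_to_end_demo(seed: int = 0, steps: int = 200, size: int = 64,
                    width_factor: int = 4, batch_size: int = 4,
                    n_train_base: int = 5, n_holdout_base: int = 1,
                    skip_mode: str = "dacc", fid_dim: int = 16):
    """Train the miniature configuration and evaluate on held-out triplets.

    Returns a report dict with the loss trajectory endpoints, the critic /
    generator update counters, PSNR of the occluded input, coarse output and
    fine (inpainted) output against the target, and a Fréchet score between
    inpainted and target sets under the seeded random-projection embedding.
    """
    triplets = make_synthetic_dataset(n_train_base + n_holdout_base, size=size,
                                      seed=seed)
    per_base = len(triplets) // (n_train_base + n_holdout_base)
    train_trips = triplets[: n_train_base * per_base]
    held_trips = triplets[n_train_base * per_base :]

    coarse, fine, disc = build_miniature_nets(seed, width_factor,
                                              skip_mode=skip_mode)
    cfg = TrainConfig(batch_size=batch_size, seed=seed + SEED_TRAIN)
    hist = train(triplets_to_arrays(train_trips), cfg, coarse, fine, disc,
                 steps=steps)

    occ, tgt = triplets_to_arrays(held_trips)
    out_c, out_f = inpaint_batch(occ, coarse, fine)
    # step-0 coarse L1 on the held-out batch, for the learning check
    coarse0, fine0, _ = build_miniature_nets(seed, width_factor,
                                             skip_mode=skip_mode)
    out_c0, _ = inpaint_batch(occ, coarse0, fine0)
    embed = metrics.RandomProjectionEmbedding(dim=fid_dim, seed=seed)
    report = {
        "n_train_triplets": len(train_trips),
        "n_holdout_triplets": len(held_trips),
        "steps": steps,
        "gd_ratio": cfg.gd_ratio,
        "n_disc_updates": hist.n_disc_updates,
        "n_gen_updates": hist.n_gen_updates,
        "coarse_l1_first": hist.coarse_l1[0],
        "coarse_l1_last": hist.coarse_l1[-1],
        "coarse_l1_holdout_step0": float(np.mean(np.abs(out_c0 - tgt[:, None]))),
        "coarse_l1_holdout": float(np.mean(np.abs(out_c - tgt[:, None]))),
        "d_loss_last": hist.d_loss[-1],
        "g_loss_last": hist.g_loss[-1],
        "gp_last": hist.gp[-1],
        "all_losses_finite": bool(
            np.all(np.isfinite(hist.coarse_l1))
            and np.all(np.isfinite(hist.d_loss))
            and np.all(np.isfinite(hist.g_loss))
            and np.all(np.isfinite(hist.gp))
        ),
        "psnr_occluded_db": batch_psnr(occ, tgt),
        "psnr_coarse_db": batch_psnr(out_c[:, 0], tgt),
        "psnr_inpainted_db": batch_psnr(out_f[:, 0], tgt),
        "fid_inpainted_vs_target": metrics.fid(out_f[:, 0], tgt, embed=embed),
        "fid_occluded_vs_target": metrics.fid(occ, tgt, embed=embed),
    }
    return report, hist, (coarse, fine, disc)
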