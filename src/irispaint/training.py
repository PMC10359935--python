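"""Two-stage adversarial training.

Stage 1 (coarse) minimises the L1 distance to the unoccluded target.  Stage 2
(fine) is a Wasserstein GAN with gradient penalty: the critic is updated
``gd_ratio`` times per generator update, and the penalty uses a smoothed
gradient norm sqrt(sum g^2 + C) with C > 0 so the norm is differentiable even
when the critic gradient vanishes (the unsmoothed norm has a NaN derivative
at zero).  The coarse generator's gradients come only from its L1 loss; the
adversarial loss updates the fine generator alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import tensor as T
from .nn.tensor import Tensor


@dataclass
class TrainConfig:
    """Training hyperparameters for the two-stage loop (full-scale defaults)."""

    lr_coarse: float = 5e-4
    lr_fine: float = 5e-4
    lr_disc: float = 5e-4
    beta1: float = 0.5          # Adam first-moment decay
    beta2: float = 0.9          # Adam second-moment decay
    batch_size: int = 8
    epochs: int = 100
    gd_ratio: int = 5           # critic updates per generator update
    gp_lambda: float = 10.0
    gp_smooth_C: float = 1e-8
    seed: int = 0

    def to_dict(self):
        return asdict(self)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def l1_loss(a: Tensor, b: Tensor) -> Tensor:
    """Mean absolute pixel difference."""
    if a.shape != b.shape:
        raise ValueError(f"l1_loss shape mismatch: {a.shape} vs {b.shape}")
    return T.mean(T.abs_(a - b))


def gradient_penalty(disc, real: Tensor, fake: Tensor, C: float = 1e-8,
                     eps=None, rng=None, smooth: bool = True) -> Tensor:
    """Smoothed WGAN-GP penalty mean((sqrt(sum g^2 + C) - 1)^2).

    ``g`` is the critic gradient at x_hat = eps*real + (1-eps)*fake with
    per-sample eps ~ U(0,1).  ``smooth=False`` uses the plain norm sqrt(sum
    g^2), whose gradient is NaN when g == 0 — the failure mode the smoothing
    constant exists to avoid.
    """
    if real.shape != fake.shape:
        raise ValueError("real/fake shape mismatch")
    n = real.shape[0]
    if eps is None:
        rng = rng if rng is not None else np.random.default_rng()
        eps = rng.random((n, 1, 1, 1))
    eps = np.asarray(eps, dtype=real.dtype).reshape(n, 1, 1, 1)
    x_hat = Tensor(eps * real.data + (1.0 - eps) * fake.data, requires_grad=True)
    score_sum = T.sum_(disc(x_hat))
    (g,) = T.grad(score_sum, [x_hat], create_graph=True)
    if g is None:  # critic constant in its input: zero gradient everywhere
        g = Tensor(np.zeros_like(x_hat.data))
    sq = T.sum_(g * g, axis=tuple(range(1, g.ndim)))
    norm = T.sqrt(sq + C) if smooth else T.sqrt(sq)
    return T.mean((norm - 1.0) ** 2)


def wgan_d_loss(real_scores: Tensor, fake_scores: Tensor, gp: Tensor | float = 0.0,
                gp_lambda: float = 10.0) -> Tensor:
    """Critic loss: mean(fake) - mean(real) + lambda * penalty."""
    real_scores, fake_scores = T.astensor(real_scores), T.astensor(fake_scores)
    return T.mean(fake_scores) - T.mean(real_scores) + gp_lambda * T.astensor(gp)


def wgan_g_loss(fake_scores: Tensor) -> Tensor:
    """Generator loss: -mean(critic score of generated images)."""
    return T.neg(T.mean(T.astensor(fake_scores)))


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr, beta1=0.5, beta2=0.9, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, (p, g) in enumerate(zip(self.params, grads)):
            if g is None:
                continue
            gd = g.data if isinstance(g, Tensor) else g
            self.m[i] = b1 * self.m[i] + (1 - b1) * gd
            self.v[i] = b2 * self.v[i] + (1 - b2) * gd * gd
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainHistory:
    steps: list = field(default_factory=list)
    coarse_l1: list = field(default_factory=list)
    d_loss: list = field(default_factory=list)
    g_loss: list = field(default_factory=list)
    gp: list = field(default_factory=list)
    n_disc_updates: int = 0
    n_gen_updates: int = 0

    def write_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("step\tcoarse_l1\td_loss\tg_loss\tgp\n")
            for row in zip(self.steps, self.coarse_l1, self.d_loss, self.g_loss,
                           self.gp):
                fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")


def _stack(batch_arrays, dtype):
    a = np.asarray(batch_arrays, dtype=dtype)
    if a.ndim == 3:  # (N,H,W) -> (N,1,H,W)
        a = a[:, None]
    return a


def train(dataset, config: TrainConfig, coarse, fine, disc, steps=None,
          callback=None):
    """Run the two-stage loop; returns a :class:`TrainHistory`.

    ``dataset`` is a pair of arrays-like (occluded, target), each (M, H, W)
    or (M, C, H, W).  One step = one coarse update + ``gd_ratio`` critic
    updates + one fine-generator update, all on the same sampled batch (the
    fine output fed to the critic updates is recomputed once per step).
    ``steps`` overrides the epoch-based step count.  Fully determined by
    ``config.seed``.
    """
    occluded, target = dataset
    dtype = coarse.parameters()[0].dtype
    occluded = _stack(occluded, dtype)
    target = _stack(target, dtype)
    m = occluded.shape[0]
    if m == 0:
        raise ValueError("empty dataset")
    bs = min(config.batch_size, m)
    if steps is None:
        steps = max(1, (m // bs)) * config.epochs
    rng = np.random.default_rng(config.seed)

    coarse.train(), fine.train(), disc.train()
    opt_c = Adam(coarse.parameters(), config.lr_coarse, config.beta1, config.beta2)
    opt_f = Adam(fine.parameters(), config.lr_fine, config.beta1, config.beta2)
    opt_d = Adam(disc.parameters(), config.lr_disc, config.beta1, config.beta2)
    c_params, f_params, d_params = (coarse.parameters(), fine.parameters(),
                                    disc.parameters())
    hist = TrainHistory()

    for step in range(steps):
        idx = rng.choice(m, size=bs, replace=False)
        occ = Tensor(occluded[idx])
        tgt = Tensor(target[idx])

        # stage 1: coarse repair, L1 to ground truth
        out_c = coarse(occ)
        loss_c = l1_loss(out_c, tgt)
        opt_c.step(T.grad(loss_c, c_params))
        coarse_in = out_c.detach()  # adversarial gradients never reach stage 1

        # critic updates (gd_ratio per generator update)
        with T.no_grad():
            fake_fixed = fine(coarse_in).detach()
        gp_val = d_val = float("nan")
        for _ in range(config.gd_ratio):
            gp = gradient_penalty(disc, tgt, fake_fixed, C=config.gp_smooth_C,
                                  rng=rng)
            d_loss = wgan_d_loss(disc(tgt), disc(fake_fixed), gp,
                                 config.gp_lambda)
            opt_d.step(T.grad(d_loss, d_params))
            hist.n_disc_updates += 1
            gp_val, d_val = gp.item(), d_loss.item()

        # stage 2 generator update
        out_f = fine(coarse_in)
        g_loss = wgan_g_loss(disc(out_f))
        opt_f.step(T.grad(g_loss, f_params))
        hist.n_gen_updates += 1

        vals = (loss_c.item(), d_val, g_loss.item(), gp_val)
        if not all(np.isfinite(v) for v in vals):
            raise TrainingDiverged(
                f"non-finite loss at step {step}: "
                f"coarse_l1={vals[0]}, d_loss={vals[1]}, g_loss={vals[2]}, gp={vals[3]}"
            )
        hist.steps.append(step)
        hist.coarse_l1.append(vals[0])
        hist.d_loss.append(vals[1])
        hist.g_loss.append(vals[2])
        hist.gp.append(vals[3])
        if callback is not None:
            callback(step, hist)
    return hist


def inpaint_batch(occluded, coarse, fine):
    """Inference: run both stages; returns (coarse_out, fine_out) arrays."""
    dtype = coarse.parameters()[0].dtype
    x = Tensor(_stack(occluded, dtype))
    was_c, was_f = coarse.training, fine.training
    coarse.eval(), fine.eval()
    try:
        with T.no_grad():
            out_c = coarse(x)
            out_f = fine(out_c)
    finally:
        coarse.train(was_c), fine.train(was_f)
    return out_c.data, out_f.data
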