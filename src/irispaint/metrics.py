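"""Objective image-quality and biometric verification metrics.

PSNR and the Fréchet distance grade inpainting quality against the
preprocessed (unoccluded) reference; ROC-derived metrics (EER, TAR at a
fixed FAR) grade a downstream verifier's genuine/impostor score sets.
Scores follow the convention higher = more likely genuine; EER and TAR are
reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PSNR_CAP_DB = 100.0  # sentinel for identical images (MSE = 0)


def psnr(reference: np.ndarray, test: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10*log10(peak^2 / MSE), in dB.

    ``peak`` is the maximum representable intensity (1.0 for float images,
    255 for 8-bit).  Identical images return the cap sentinel.
    """
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    mse = np.mean((reference - test) ** 2)
    if mse == 0:
        return PSNR_CAP_DB
    return float(min(10.0 * np.log10(peak**2 / mse), PSNR_CAP_DB))


# ---------------------------------------------------------------------------
# Fréchet distance
# ---------------------------------------------------------------------------

@dataclass
class GaussianStats:
    """Mean vector and covariance matrix of an embedded image set."""

    mean: np.ndarray
    cov: np.ndarray

    @classmethod
    def from_embeddings(cls, emb: np.ndarray) -> "GaussianStats":
        emb = np.asarray(emb, dtype=np.float64)
        if emb.ndim != 2 or emb.shape[0] < 2:
            raise ValueError("need a (n >= 2, d) embedding matrix")
        return cls(emb.mean(axis=0), np.cov(emb, rowvar=False))


def _psd_sqrt(mat: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition; small negative
    eigenvalues (numerical drift) are clipped, genuinely negative ones raise."""
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() < -tol * max(1.0, abs(vals.max())):
        raise ValueError(f"matrix is not PSD (min eigenvalue {vals.min():.3e})")
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def frechet_distance(a: GaussianStats, b: GaussianStats) -> float:
    """||mu_a - mu_b||^2 + tr(S_a + S_b - 2 (S_a S_b)^{1/2}).

    The cross term uses the similarity-transform trick
    (S_a S_b)^{1/2} ~ S_a^{1/2} (S_a^{1/2} S_b S_a^{1/2})^{1/2} S_a^{-1/2},
    whose trace equals tr((S_a^{1/2} S_b S_a^{1/2})^{1/2}).
    """
    mu_a, mu_b = np.atleast_1d(a.mean), np.atleast_1d(b.mean)
    cov_a, cov_b = np.atleast_2d(a.cov), np.atleast_2d(b.cov)
    if mu_a.shape != mu_b.shape:
        raise ValueError("dimension mismatch between the two Gaussian stats")
    diff = float(np.sum((mu_a - mu_b) ** 2))
    root_a = _psd_sqrt(cov_a)
    inner = _psd_sqrt(root_a @ cov_b @ root_a)
    val = diff + float(np.trace(cov_a) + np.trace(cov_b) - 2.0 * np.trace(inner))
    return max(val, 0.0)


class RandomProjectionEmbedding:
    """Fixed-seed random conv-stack embedding for desk-scale Fréchet scores.

    Three stride-2 valid convolutions with He-scaled random weights and a
    leaky-ReLU, global average pooling per channel, then a random linear
    projection to ``dim`` features.  Deterministic in ``seed``; a learned
    (e.g. Inception) embedding can be substituted via the ``embed`` hook of
    :func:`fid`.
    """

    def __init__(self, dim: int = 32, seed: int = 0, channels=(8, 16, 32)):
        self.dim, self.seed, self.channels = dim, seed, tuple(channels)
        self._rng = np.random.default_rng(seed)
        self._kernels = None
        self._proj = None

    def _build(self, in_ch):
        rng = np.random.default_rng(self.seed)
        kernels = []
        prev = in_ch
        for ch in self.channels:
            k = rng.normal(0, np.sqrt(2.0 / (prev * 9)), size=(ch, prev, 3, 3))
            kernels.append(k)
            prev = ch
        proj = rng.normal(0, 1.0 / np.sqrt(prev), size=(prev, self.dim))
        return kernels, proj

    @staticmethod
    def _conv_valid_s2(x, k):
        # x (N,C,H,W), k (O,C,3,3); stride-2 valid conv via windowed einsum
        v = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(2, 3))
        v = v[:, :, ::2, ::2]
        return np.einsum("nchwij,ocij->nohw", v, k)

    def __call__(self, images) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None]
        elif x.ndim == 4 and x.shape[-1] in (1, 3):
            x = np.moveaxis(x, -1, 1)
        if self._kernels is None:
            self._kernels, self._proj = self._build(x.shape[1])
        for k in self._kernels:
            x = self._conv_valid_s2(x, k)
            x = np.where(x > 0, x, 0.2 * x)
        feats = x.mean(axis=(2, 3))
        return feats @ self._proj


def fid(images_a, images_b, embed=None) -> float:
    """Fréchet distance between Gaussian summaries of embedded image sets.

    ``embed`` maps a stack of images to an (n, d) feature matrix; the
    default is the seeded :class:`RandomProjectionEmbedding`.
    """
    if embed is None:
        embed = RandomProjectionEmbedding()
    stats_a = GaussianStats.from_embeddings(embed(images_a))
    stats_b = GaussianStats.from_embeddings(embed(images_b))
    return frechet_distance(stats_a, stats_b)


# ---------------------------------------------------------------------------
# verification metrics
# ---------------------------------------------------------------------------

@dataclass
class ScoreSet:
    """Genuine (same identity) and impostor (different identity) scores."""

    genuine: np.ndarray
    impostor: np.ndarray

    def __post_init__(self):
        self.genuine = np.asarray(self.genuine, dtype=np.float64).ravel()
        self.impostor = np.asarray(self.impostor, dtype=np.float64).ravel()
        if self.genuine.size == 0 or self.impostor.size == 0:
            raise ValueError("both genuine and impostor score lists must be nonempty")


def roc(scores: ScoreSet):
    """Threshold sweep: (FAR, TAR) at every distinct score threshold.

    FAR = fraction of impostor scores >= t, TAR = fraction of genuine >= t.
    Returned in increasing-FAR order, with the (0, .) and (1, 1) endpoints.
    """
    thresholds = np.unique(np.concatenate([scores.genuine, scores.impostor]))
    far = [(scores.impostor >= t).mean() for t in thresholds[::-1]]
    tar = [(scores.genuine >= t).mean() for t in thresholds[::-1]]
    # add a reject-all endpoint (0, 0) and the accept-all endpoint (1, 1)
    far = np.concatenate([[0.0], far, [1.0]])
    tar = np.concatenate([[0.0], tar, [1.0]])
    order = np.argsort(far, kind="stable")
    return far[order], tar[order]


def eer(scores: ScoreSet) -> float:
    """Equal error rate (percent): where FAR equals FRR = 1 - TAR.

    Linear interpolation between the adjacent sweep points around the
    crossing of FAR(t) and FRR(t).
    """
    far, tar = roc(scores)
    frr = 1.0 - tar
    diff = far - frr
    idx = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    if idx.size == 0:
        k = np.argmin(np.abs(diff))
        return float(0.5 * (far[k] + frr[k]) * 100.0)
    k = idx[0]
    x0, x1 = diff[k], diff[k + 1]
    w = 0.0 if x1 == x0 else -x0 / (x1 - x0)
    rate = far[k] + w * (far[k + 1] - far[k])
    rate_frr = frr[k] + w * (frr[k + 1] - frr[k])
    return float(0.5 * (rate + rate_frr) * 100.0)


def tar_at_far(scores: ScoreSet, far_target: float = 0.001) -> float:
    """TAR (percent) at the given FAR budget.

    The operating point is the loosest threshold whose FAR does not exceed
    the budget (i.e. the maximal attainable TAR); when the budget falls
    strictly between two attained FAR values, TAR is linearly interpolated.
    """
    far, tar = roc(scores)
    j = int(np.searchsorted(far, far_target, side="right")) - 1
    if j < 0:
        return float(tar[0] * 100.0)
    val = tar[j]
    if far[j] < far_target and j + 1 < far.size and far[j + 1] > far[j]:
        w = (far_target - far[j]) / (far[j + 1] - far[j])
        val = tar[j] + w * (tar[j + 1] - tar[j])
    return float(val * 100.0)
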