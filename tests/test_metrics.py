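"""Metric closed forms, brute-force threshold-enumeration oracles for the
verification metrics, and distributional checks for the Fréchet distance."""

import numpy as np
import pytest

from irispaint.metrics import (
    GaussianStats,
    RandomProjectionEmbedding,
    ScoreSet,
    eer,
    fid,
    frechet_distance,
    psnr,
    roc,
    tar_at_far,
)


class TestPSNR:
    def test_identical_images_hit_cap_sentinel(self):
        x = np.random.default_rng(0).random((16, 16))
        assert psnr(x, x) == 100.0

    def test_uniform_difference_closed_form(self):
        a = np.zeros((8, 8))
        b = np.full((8, 8), 16.0)
        expect = 10 * np.log10(255**2 / 256)
        assert abs(psnr(a, b, peak=255) - expect) < 1e-12

    def test_full_scale_difference_is_zero_db(self):
        assert abs(psnr(np.zeros((4, 4)), np.ones((4, 4)), peak=1.0)) < 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_monotone_in_noise_level(self):
        rng = np.random.default_rng(1)
        ref = rng.random((64, 64))
        vals = []
        for sigma in (0.01, 0.03, 0.1, 0.3, 1.0):
            vals.append(psnr(ref, ref + sigma * rng.standard_normal(ref.shape)))
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestFrechet:
    def test_identical_stats_zero(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=4)
        a = rng.normal(size=(6, 4))
        cov = a.T @ a
        g = GaussianStats(m, cov)
        assert frechet_distance(g, g) < 1e-9

    def test_univariate_closed_form(self):
        g1 = GaussianStats(np.array([1.0]), np.array([[4.0]]))
        g2 = GaussianStats(np.array([3.0]), np.array([[9.0]]))
        assert abs(frechet_distance(g1, g2) - ((1 - 3) ** 2 + (2 - 3) ** 2)) < 1e-8

    def test_diagonal_closed_form(self):
        rng = np.random.default_rng(3)
        va, vb = rng.random(5) + 0.5, rng.random(5) + 0.5
        ma, mb = rng.normal(size=5), rng.normal(size=5)
        got = frechet_distance(GaussianStats(ma, np.diag(va)),
                               GaussianStats(mb, np.diag(vb)))
        expect = np.sum((ma - mb) ** 2 + (np.sqrt(va) - np.sqrt(vb)) ** 2)
        assert abs(got - expect) < 1e-8

    def test_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(4)
        def random_stats():
            a = rng.normal(size=(8, 3))
            return GaussianStats(rng.normal(size=3), a.T @ a / 8)
        for _ in range(5):
            ga, gb = random_stats(), random_stats()
            d1, d2 = frechet_distance(ga, gb), frechet_distance(gb, ga)
            assert d1 >= 0 and abs(d1 - d2) < 1e-8

    def test_non_psd_rejected(self):
        bad = GaussianStats(np.zeros(2), np.array([[1.0, 0.0], [0.0, -1.0]]))
        good = GaussianStats(np.zeros(2), np.eye(2))
        with pytest.raises(ValueError):
            frechet_distance(bad, good)

    def test_monte_carlo_matches_closed_form(self):
        """Sampled Gaussian embeddings vs the analytic Fréchet distance."""
        rng = np.random.default_rng(5)
        d = 4
        mu_a, mu_b = np.zeros(d), np.full(d, 0.5)
        sd_a, sd_b = np.full(d, 1.0), np.full(d, 1.5)
        n = 500
        ea = rng.normal(mu_a, sd_a, size=(n, d))
        eb = rng.normal(mu_b, sd_b, size=(n, d))
        got = frechet_distance(GaussianStats.from_embeddings(ea),
                               GaussianStats.from_embeddings(eb))
        expect = np.sum((mu_a - mu_b) ** 2 + (sd_a - sd_b) ** 2)
        assert abs(got - expect) / expect < 0.35  # sampling error at n=500


class TestFID:
    def test_same_set_zero(self):
        imgs = np.random.default_rng(6).random((6, 32, 32))
        assert fid(imgs, imgs) < 1e-9

    def test_positive_when_one_image_replaced(self):
        rng = np.random.default_rng(7)
        a = rng.random((6, 32, 32))
        b = a.copy()
        b[0] = rng.random((32, 32))
        assert fid(a, b) > 0

    def test_embedding_deterministic_and_pluggable(self):
        imgs = np.random.default_rng(8).random((4, 32, 32))
        e1 = RandomProjectionEmbedding(seed=3)(imgs)
        e2 = RandomProjectionEmbedding(seed=3)(imgs)
        assert np.array_equal(e1, e2)
        flat = lambda ims: np.asarray(ims).reshape(len(ims), -1)[:, :8]
        assert fid(imgs, imgs, embed=flat) < 1e-9


def brute_force_sweep(genuine, impostor):
    """Enumeration oracle: (FAR, TAR) at every candidate threshold."""
    pts = []
    for t in sorted(set(genuine) | set(impostor), reverse=True):
        far = sum(s >= t for s in impostor) / len(impostor)
        tar = sum(s >= t for s in genuine) / len(genuine)
        pts.append((t, far, tar))
    return pts


HAND_GENUINE = [0.9, 0.8, 0.4]
HAND_IMPOSTOR = [0.7, 0.3, 0.2]


class TestVerification:
    def test_roc_contains_enumerated_points(self):
        s = ScoreSet(HAND_GENUINE, HAND_IMPOSTOR)
        far, tar = roc(s)
        curve = set(zip(far.round(9), tar.round(9)))
        for _, f, t in brute_force_sweep(HAND_GENUINE, HAND_IMPOSTOR):
            assert (round(f, 9), round(t, 9)) in curve
        assert np.all(np.diff(far) >= 0) and np.all(np.diff(tar) >= 0)

    def test_roc_perfect_separation_contains_0_1(self):
        far, tar = roc(ScoreSet(np.ones(5), np.zeros(5)))
        assert any(f == 0 and t == 1 for f, t in zip(far, tar))

    def test_roc_chance_line_when_distributions_equal(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=2000)
        far, tar = roc(ScoreSet(x, x))
        np.testing.assert_allclose(far, tar, atol=1e-12)

    def test_eer_hand_set_matches_enumeration(self):
        # oracle: FAR == FRR == 1/3 exactly at threshold 0.7
        pts = brute_force_sweep(HAND_GENUINE, HAND_IMPOSTOR)
        crossing = [p for p in pts if abs(p[1] - (1 - p[2])) < 1e-12]
        assert crossing and abs(crossing[0][1] - 1 / 3) < 1e-12
        assert abs(eer(ScoreSet(HAND_GENUINE, HAND_IMPOSTOR)) - 100 / 3) < 1e-9

    def test_eer_extremes(self):
        assert eer(ScoreSet(np.ones(5), np.zeros(5))) == 0.0
        rng = np.random.default_rng(10)
        x = rng.normal(size=3000)
        assert abs(eer(ScoreSet(x, x)) - 50.0) < 2.0

    def test_tar_at_far_hand_set(self):
        # oracle: at threshold 0.4, FAR = 1/3 and every genuine is accepted
        s = ScoreSet(HAND_GENUINE, HAND_IMPOSTOR)
        assert abs(tar_at_far(s, 1 / 3) - 100.0) < 1e-9

    def test_tar_at_far_extremes(self):
        perfect = ScoreSet(np.ones(5), np.zeros(5))
        assert tar_at_far(perfect, 0.001) == 100.0
        assert tar_at_far(perfect, 1.0) == 100.0

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        s = ScoreSet(rng.normal(1, 1, 200), rng.normal(0, 1, 300))
        warped = ScoreSet(np.tanh(s.genuine) * 3 + 1, np.tanh(s.impostor) * 3 + 1)
        assert abs(eer(s) - eer(warped)) < 1e-9
        assert abs(tar_at_far(s, 0.01) - tar_at_far(warped, 0.01)) < 1e-9

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            ScoreSet([], [1.0])
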