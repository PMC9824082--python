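"""Feature extractors against brute-force oracles and their invariants."""

import numpy as np
import pytest
import scipy.fft

from thermact import features as ft
from thermact import preprocess as pp


def _tensor(maps, labels=None):
    maps = np.asarray(maps)
    if labels is None:
        labels = np.array([f"L{i % 2}" for i in range(len(maps))])
    return pp.DatasetTensor(maps, np.asarray(labels))


class TestSVD:
    def test_basis_is_orthonormal(self, rng):
        data = _tensor(19 + rng.normal(0, 1, size=(30, 40, 64)))
        model = ft.svd_fit(data, k=10)
        np.testing.assert_allclose(model.basis.T @ model.basis, np.eye(10), atol=1e-9)

    def test_exact_low_rank_data_fully_explained(self, rng):
        basis = rng.normal(size=(3, 2560))
        coeff = rng.normal(size=(25, 3))
        maps = (coeff @ basis).reshape(25, 40, 64)
        model = ft.svd_fit(_tensor(maps), k=3)
        assert model.explained_variance_ratio.sum() > 1 - 1e-9

    def test_reconstruction_error_matches_discarded_singular_values(self, rng):
        # Eckart-Young on a 20-sample toy set, against a full decomposition
        maps = rng.normal(size=(20, 40, 64))
        data = _tensor(maps)
        k = 5
        model = ft.svd_fit(data, k=k)
        Z = ft.svd_transform(model, data).X
        recon = Z @ model.basis.T + model.mean
        err = ((data.vectors() - recon) ** 2).sum() / 20
        Xc = data.vectors() - data.vectors().mean(axis=0)
        s = np.linalg.svd(Xc, compute_uv=False)
        np.testing.assert_allclose(err, (s[k:] ** 2).sum() / 20, rtol=1e-9)

    def test_transform_centers_with_training_mean(self, rng):
        data = _tensor(19 + rng.normal(0, 1, size=(12, 40, 64)))
        model = ft.svd_fit(data, k=4)
        mean_map = model.mean.reshape(1, 40, 64)
        out = ft.svd_transform(model, _tensor(mean_map, ["x"]))
        np.testing.assert_allclose(out.X, 0.0, atol=1e-9)
        assert out.X.shape == (1, 4)

    def test_projection_matches_matrix_product(self, rng):
        train = _tensor(rng.normal(size=(15, 40, 64)))
        batch = _tensor(rng.normal(size=(4, 40, 64)), ["a", "b", "c", "d"])
        model = ft.svd_fit(train, k=6)
        out = ft.svd_transform(model, batch)
        np.testing.assert_allclose(
            out.X, (batch.vectors() - model.mean) @ model.basis, atol=1e-9
        )

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            ft.svd_fit(_tensor(rng.normal(size=(10, 40, 64))), k=11)


class TestFisher:
    def test_fifteen_classes_give_fourteen_components(self, fisher15):
        assert fisher15.n_components == 14

    def test_transform_dimension_bounded_by_classes(self, fisher15, large15):
        out = ft.fisher_transform(fisher15, large15.subset(np.arange(10)))
        assert out.X.shape == (10, 14)

    def test_two_separated_gaussians_project_far_apart(self, rng):
        mu = rng.normal(size=2560)
        delta = rng.normal(size=2560)
        delta *= 30.0 / np.linalg.norm(delta)
        a = mu + rng.normal(size=(20, 2560))
        b = mu + delta + rng.normal(size=(20, 2560))
        maps = np.concatenate([a, b]).reshape(40, 40, 64)
        data = _tensor(maps, ["a"] * 20 + ["b"] * 20)
        model = ft.fisher_fit(data)
        assert model.n_components == 1
        z = ft.fisher_transform(model, data).X[:, 0]
        za, zb = z[:20], z[20:]
        pooled = np.sqrt(0.5 * (za.var(ddof=1) + zb.var(ddof=1)))
        assert abs(za.mean() - zb.mean()) > 5 * pooled

    def test_identical_class_means_give_null_leading_eigenvalue(self, rng):
        base = rng.normal(size=(20, 2560))
        maps = np.concatenate([base, base]).reshape(40, 40, 64)
        data = _tensor(maps, ["a"] * 20 + ["b"] * 20)
        model = ft.fisher_fit(data)
        assert model.eigenvalues[0] < 1e-6

    def test_duplicate_samples_map_identically(self, rng):
        maps = rng.normal(size=(12, 40, 64))
        maps[5] = maps[2]
        data = _tensor(maps, ["a"] * 6 + ["b"] * 6)
        model = ft.fisher_fit(data)
        out = ft.fisher_transform(model, data)
        np.testing.assert_allclose(out.X[5], out.X[2], atol=1e-9)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            ft.fisher_fit(_tensor(rng.normal(size=(6, 40, 64)), ["a"] * 6))


def _brute_dct_patch(patch):
    """Direct orthonormal type-II DCT via basis-function sums."""
    N = 8
    out = np.zeros((N, N))
    for u in range(N):
        for v in range(N):
            au = np.sqrt(1 / N) if u == 0 else np.sqrt(2 / N)
            av = np.sqrt(1 / N) if v == 0 else np.sqrt(2 / N)
            s = 0.0
            for m in range(N):
                for n in range(N):
                    s += (patch[m, n]
                          * np.cos(np.pi * (2 * m + 1) * u / (2 * N))
                          * np.cos(np.pi * (2 * n + 1) * v / (2 * N)))
            out[u, v] = au * av * s
    return out


ZIGZAG6 = [(0, 0), (0, 1), (1, 0), (2, 0), (1, 1), (0, 2)]


class TestDCT:
    def test_length_is_240(self, random_map):
        assert ft.dct_features(random_map).shape == (240,)

    def test_constant_patch_has_only_dc(self):
        m = np.full((40, 64), 2.5)
        f = ft.dct_features(m)
        per_patch = f.reshape(40, 6)
        np.testing.assert_allclose(per_patch[:, 0], 8 * 2.5, atol=1e-12)
        np.testing.assert_allclose(per_patch[:, 1:], 0.0, atol=1e-12)

    def test_zero_map_gives_zero_vector(self):
        assert np.all(ft.dct_features(np.zeros((40, 64))) == 0)

    def test_matches_brute_force_basis_sums(self, rng):
        m = rng.normal(20, 2, size=(40, 64))
        f = ft.dct_features(m)
        for p_idx, (pr, pc) in enumerate([(0, 0), (2, 3), (4, 7)]):
            patch = m[pr * 8:(pr + 1) * 8, pc * 8:(pc + 1) * 8]
            C = _brute_dct_patch(patch)
            expected = [C[u, v] for u, v in ZIGZAG6]
            flat_idx = pr * 8 + pc
            np.testing.assert_allclose(f[flat_idx * 6:(flat_idx + 1) * 6], expected, atol=1e-9)

    def test_constant_shift_changes_only_patch_dc(self, rng):
        m = rng.normal(20, 2, size=(40, 64))
        f1 = ft.dct_features(m)
        f2 = ft.dct_features(m + 4.0)
        diff = (f2 - f1).reshape(40, 6)
        np.testing.assert_allclose(diff[:, 0], 32.0, atol=1e-9)  # 8 * 4.0
        np.testing.assert_allclose(diff[:, 1:], 0.0, atol=1e-9)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            ft.dct_features(np.zeros((8, 8)))


def _brute_glcm_stats(patch, d, angle_idx, levels=8):
    """Exhaustive symmetric co-occurrence counting.

    Offsets follow the package's convention: each component of the
    (row, col) displacement is the rounded projection of the distance onto
    the angle, so 0 deg -> (0, d), 45 deg -> (round(d/sqrt(2)),) * 2 and
    90 deg -> (d, 0)."""
    diag = int(np.round(d / np.sqrt(2)))
    dr, dc = [(0, d), (diag, diag), (d, 0)][angle_idx]
    H, W = patch.shape
    counts = np.zeros((levels, levels))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                counts[patch[r, c], patch[r2, c2]] += 1
                counts[patch[r2, c2], patch[r, c]] += 1
    P = counts / counts.sum()
    i = np.arange(levels)[:, None] * np.ones((1, levels))
    j = i.T
    contrast = (P * (i - j) ** 2).sum()
    dissim = (P * np.abs(i - j)).sum()
    energy = np.sqrt((P ** 2).sum())
    mi, mj = (P * i).sum(), (P * j).sum()
    si = np.sqrt((P * (i - mi) ** 2).sum())
    sj = np.sqrt((P * (j - mj) ** 2).sum())
    corr = 0.0 if si * sj == 0 else (P * (i - mi) * (j - mj)).sum() / (si * sj)
    return {"correlation": corr, "contrast": contrast, "dissimilarity": dissim,
            "energy": energy}


class TestGLCM:
    def test_length_is_120(self, random_map):
        assert ft.glcm_features(random_map).shape == (120,)

    def test_constant_map_conventions(self):
        f = ft.glcm_features(np.full((40, 64), 19.0)).reshape(5, 2, 3, 4)
        # order per (patch, distance, angle): correlation, contrast, dissimilarity, energy
        np.testing.assert_allclose(f[..., 0], 0.0)  # correlation by convention
        np.testing.assert_allclose(f[..., 1], 0.0)  # contrast
        np.testing.assert_allclose(f[..., 2], 0.0)  # dissimilarity
        np.testing.assert_allclose(f[..., 3], 1.0)  # energy

    def test_stripe_pattern_matches_exhaustive_counting(self):
        # 2-level vertical stripes; quantization maps {0, 7} -> {0, 7}
        m = np.zeros((40, 64))
        m[:, ::2] = 7.0
        f = ft.glcm_features(m).reshape(5, 2, 3, 4)
        q = (m[:8] * 8 / 7).astype(int).clip(0, 7)
        for di, d in enumerate((1, 3)):
            for ai in range(3):
                ref = _brute_glcm_stats(q, d, ai)
                got = dict(zip(("correlation", "contrast", "dissimilarity", "energy"),
                               f[0, di, ai]))
                for stat, val in ref.items():
                    assert got[stat] == pytest.approx(val, abs=1e-9), (d, ai, stat)

    def test_random_map_matches_exhaustive_counting(self, rng):
        m = rng.normal(20, 1.5, size=(40, 64))
        f = ft.glcm_features(m).reshape(5, 2, 3, 4)
        q = ft._quantize(m, 8)
        for p in (1, 4):
            patch = q[p * 8:(p + 1) * 8, :]
            for di, d in enumerate((1, 3)):
                for ai in range(3):
                    ref = _brute_glcm_stats(patch, d, ai)
                    got = dict(zip(("correlation", "contrast", "dissimilarity", "energy"),
                                   f[p, di, ai]))
                    for stat, val in ref.items():
                        assert got[stat] == pytest.approx(val, abs=1e-9), (p, d, ai, stat)

    def test_statistic_ranges(self, rng):
        for _ in range(3):
            f = ft.glcm_features(rng.normal(20, 1, size=(40, 64))).reshape(5, 2, 3, 4)
            assert np.all(f[..., 0] >= -1 - 1e-9) and np.all(f[..., 0] <= 1 + 1e-9)
            assert np.all(f[..., 1] >= 0) and np.all(f[..., 2] >= 0)
            assert np.all(f[..., 3] > 0) and np.all(f[..., 3] <= 1 + 1e-9)


class TestDimensions:
    """Feature dimensions are fixed per extractor configuration."""

    def test_all_extractor_dimensions(self, rng, large15, fisher15):
        sub = large15.subset(np.arange(0, 450, 15))
        svd = ft.svd_fit(sub, k=12)
        assert ft.svd_transform(svd, sub).X.shape[1] == 12
        assert ft.fisher_transform(fisher15, sub).X.shape[1] == 14
        assert ft.extract_features(sub, "dct").X.shape[1] == 240
        assert ft.extract_features(sub, "glcm").X.shape[1] == 120
        assert sub.vectors().shape[1] == 2560
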