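"""Texture module tests: brute-force pair-enumeration oracles and invariants."""

import math

import numpy as np
import pytest

from tendonquant.texture import (
    DEFAULT_DISPLACEMENTS,
    glcm,
    glcm_features,
    glcm_homogeneity,
    glds,
    glds_features,
    haar_features,
    quantize,
    texture_vector,
)

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_oracle(region, levels, distance=1, angles=(0, 45, 90, 135)):
    """Explicit pair enumeration, symmetrize, normalize, average over angles."""
    rows, cols = region.shape
    mats = []
    for ang in angles:
        dr, dc = (d * distance for d in OFFSETS[ang])
        counts = np.zeros((levels, levels))
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    counts[region[r, c], region[r2, c2]] += 1
        sym = counts + counts.T
        mats.append(sym / sym.sum())
    return np.mean(mats, axis=0)


def glcm_features_oracle(p):
    """Naive double-sum implementation of the six features."""
    ng = p.shape[0]
    contrast = sum(p[i, j] * (i - j) ** 2 for i in range(ng) for j in range(ng))
    psum = np.zeros(2 * ng - 1)
    pdiff = np.zeros(ng)
    for i in range(ng):
        for j in range(ng):
            psum[i + j] += p[i, j]
            pdiff[abs(i - j)] += p[i, j]
    sum_average = sum(k * psum[k] for k in range(2 * ng - 1))
    px = p.sum(axis=1)
    mu = sum(i * px[i] for i in range(ng))
    ssq = sum(p[i, j] * (i - mu) ** 2 for i in range(ng) for j in range(ng))
    dmean = sum(k * pdiff[k] for k in range(ng))
    dvar = sum((k - dmean) ** 2 * pdiff[k] for k in range(ng))
    sigma2 = sum(i * i * px[i] for i in range(ng)) - mu**2
    corr = math.nan if sigma2 <= 1e-15 else (sum(i * j * p[i, j] for i in range(ng) for j in range(ng)) - mu * mu) / sigma2
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    return dict(
        glcm_contrast=contrast, glcm_sum_average=sum_average, glcm_ssq_variance=ssq,
        glcm_difference_variance=dvar, glcm_correlation=corr, glcm_idm=idm,
    )


def glds_oracle(region, levels, displacements=DEFAULT_DISPLACEMENTS):
    rows, cols = region.shape
    counts = np.zeros(levels)
    for dr, dc in displacements:
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    counts[abs(int(region[r, c]) - int(region[r2, c2]))] += 1
    return counts / counts.sum()


def haar_oracle(region):
    """Explicit per-block averages/differences (orthonormal one-level Haar)."""
    region = np.asarray(region, dtype=float)
    rows, cols = (region.shape[0] // 2) * 2, (region.shape[1] // 2) * 2
    coefs = []
    for r in range(0, rows, 2):
        for c in range(0, cols, 2):
            a, b = region[r, c], region[r, c + 1]
            cc, d = region[r + 1, c], region[r + 1, c + 1]
            coefs += [(a + b - cc - d) / 2, (a - b + cc - d) / 2, (a - b - cc + d) / 2]
    mags = np.abs(coefs)
    return mags.mean(), mags.var()


class TestQuantize:
    def test_top_bin(self):
        assert quantize(np.array([[255, 255], [255, 255]]), 32).max() == 31

    @pytest.mark.parametrize("levels", [2, 8, 32, 256])
    def test_zero_maps_to_zero(self, levels):
        assert quantize(np.zeros((2, 2), dtype=np.uint8), levels).max() == 0

    def test_identity_at_256_levels(self, rng):
        region = rng.integers(0, 256, size=(16, 16))
        np.testing.assert_array_equal(quantize(region, 256), region)

    def test_levels_out_of_range(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((2, 2)), 1)


class TestGlcm:
    def test_constant_region_single_entry(self):
        q = quantize(np.full((6, 6), 128, dtype=np.uint8), 8)
        m = glcm(q, 8)
        c = q[0, 0]
        assert m.p[c, c] == pytest.approx(1.0)
        assert m.p.sum() == pytest.approx(1.0)

    def test_two_pixel_pair(self):
        m = glcm(np.array([[0, 1]]), levels=2, angles=(0,))
        assert m.p[0, 1] == pytest.approx(0.5)
        assert m.p[1, 0] == pytest.approx(0.5)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(20):
            region = rng.integers(0, 4, size=(6, 6))
            m = glcm(region, levels=4)
            np.testing.assert_allclose(m.p, glcm_oracle(region, 4), atol=1e-12)

    def test_normalization_property(self, rng):
        for _ in range(200):
            region = rng.integers(0, 8, size=rng.integers(2, 12, size=2))
            assert glcm(region, 8).p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_exact_symmetry(self, rng):
        region = rng.integers(0, 16, size=(9, 7))
        p = glcm(region, 16).p
        assert np.max(np.abs(p - p.T)) == 0.0

    def test_no_pairs_raises(self):
        with pytest.raises(ValueError):
            glcm(np.array([[1]]), levels=2)


class TestGlcmFeatures:
    def test_constant_region_degenerate_values(self):
        q = quantize(np.full((8, 8), 100, dtype=np.uint8), 32)
        c = int(q[0, 0])
        f = glcm_features(glcm(q, 32))
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_idm"] == pytest.approx(1.0)
        assert f["glcm_sum_average"] == pytest.approx(2 * c)
        assert f["glcm_ssq_variance"] == pytest.approx(0.0)
        assert f["glcm_difference_variance"] == pytest.approx(0.0)
        assert math.isnan(f["glcm_correlation"])

    def test_checkerboard_contrast(self):
        ng = 4
        region = np.indices((8, 8)).sum(axis=0) % 2 * (ng - 1)
        f = glcm_features(glcm(region, ng, angles=(0,)))
        assert f["glcm_contrast"] == pytest.approx((ng - 1) ** 2)

    @pytest.mark.parametrize("levels", [4, 8, 32])
    def test_matches_double_sum_oracle(self, rng, levels):
        for _ in range(25):
            region = quantize(rng.integers(0, 256, size=(8, 8)), levels)
            m = glcm(region, levels)
            got = glcm_features(m)
            want = glcm_features_oracle(m.p)
            for k in want:
                if math.isnan(want[k]):
                    assert math.isnan(got[k])
                else:
                    assert got[k] == pytest.approx(want[k], abs=1e-10)

    def test_bone_homogeneity_differs_from_idm(self, rng):
        region = quantize(rng.integers(0, 256, size=(8, 8)), 8)
        m = glcm(region, 8)
        hom = glcm_homogeneity(m)
        idm = glcm_features(m)["glcm_idm"]
        oracle = sum(m.p[i, j] / (1 + abs(i - j)) for i in range(8) for j in range(8))
        assert hom == pytest.approx(oracle, abs=1e-12)
        assert hom != pytest.approx(idm)  # |i-j| vs (i-j)^2 weighting


class TestGlds:
    def test_constant_region(self):
        h = glds(np.full((5, 5), 3), levels=8)
        assert h.q[0] == pytest.approx(1.0)
        assert h.q[1:].sum() == pytest.approx(0.0)

    def test_horizontal_ramp(self):
        region = np.tile(np.arange(6), (4, 1))
        h = glds(region, levels=8, displacements=((0, 1),))
        assert h.q[1] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            region = rng.integers(0, 8, size=(7, 9))
            h = glds(region, 8)
            np.testing.assert_allclose(h.q, glds_oracle(region, 8), atol=1e-12)


class TestGldsFeatures:
    def test_degenerate_histogram(self):
        h = glds(np.full((4, 4), 1), levels=4)
        f = glds_features(h)
        assert f == {
            "glds_homogeneity": pytest.approx(1.0),
            "glds_contrast": pytest.approx(0.0),
            "glds_asm": pytest.approx(1.0),
            "glds_entropy": pytest.approx(0.0),
            "glds_mean": pytest.approx(0.0),
        }

    def test_uniform_two_bins_closed_form(self):
        # q = [0.5, 0.5]: ASM 0.5, entropy ln2, mean 0.5, contrast 0.5, homogeneity 0.75
        region = np.array([[0, 1], [0, 1]])
        h = glds(region, levels=2, displacements=((0, 1), (1, 0)))
        assert h.q[0] == pytest.approx(0.5) and h.q[1] == pytest.approx(0.5)
        f = glds_features(h)
        assert f["glds_asm"] == pytest.approx(0.5)
        assert f["glds_entropy"] == pytest.approx(math.log(2))
        assert f["glds_mean"] == pytest.approx(0.5)
        assert f["glds_contrast"] == pytest.approx(0.5)
        assert f["glds_homogeneity"] == pytest.approx(0.75)

    def test_matches_direct_summation(self, rng):
        for _ in range(20):
            region = rng.integers(0, 16, size=(8, 8))
            h = glds(region, 16)
            f = glds_features(h)
            k = np.arange(16)
            assert f["glds_contrast"] == pytest.approx(float((k**2 * h.q).sum()), abs=1e-12)
            assert f["glds_mean"] == pytest.approx(float((k * h.q).sum()), abs=1e-12)
            assert f["glds_asm"] == pytest.approx(float((h.q**2).sum()), abs=1e-12)


class TestHaar:
    def test_constant_region_no_gradients(self):
        assert haar_features(np.full((6, 6), 77)) == (0.0, 0.0)

    def test_vertical_step_edge(self):
        region = np.zeros((8, 8))
        region[:, 4:] = 200
        mean, _ = haar_features(region)
        assert mean == 0.0  # step aligned with block boundary: no intra-block gradient
        region2 = np.zeros((8, 8))
        region2[:, 3:] = 200
        mean2, _ = haar_features(region2)
        assert mean2 > 0.0

    def test_matches_block_filter_oracle(self, rng):
        for _ in range(20):
            region = rng.integers(0, 256, size=(8, 8))
            got = haar_features(region)
            want = haar_oracle(region)
            assert got[0] == pytest.approx(want[0], abs=1e-10)
            assert got[1] == pytest.approx(want[1], abs=1e-10)

    def test_odd_sizes_truncated(self, rng):
        region = rng.integers(0, 256, size=(9, 7))
        assert haar_features(region) == haar_features(region[:8, :6])

    def test_too_small(self):
        with pytest.raises(ValueError):
            haar_features(np.zeros((1, 5)))


class TestTextureVector:
    def test_thirteen_features(self, rng):
        tf = texture_vector(rng.integers(0, 256, size=(16, 16)))
        assert len(tf.as_dict()) == 13

    def test_constant_roi_flagged_correlation(self):
        tf = texture_vector(np.full((8, 8), 50, dtype=np.uint8))
        assert math.isnan(tf.glcm_correlation)
        assert tf.glcm_contrast == 0.0

    def test_determinism(self, rng):
        region = rng.integers(0, 256, size=(12, 12))
        assert texture_vector(region).as_dict() == texture_vector(region).as_dict()

    def test_noise_monotonicity(self):
        """glds_contrast strictly rises and homogeneity strictly falls with noise amplitude."""
        # amplitudes chosen so 128 +/- 3 sd stays inside [0, 255]: clipping
        # saturates the difference histogram and would flatten the trend
        amplitudes = [3, 8, 15, 25, 40]
        wins = 0
        trials = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            contrasts, homogeneities = [], []
            for amp in amplitudes:
                region = np.clip(128 + g.normal(0, amp, size=(32, 32)), 0, 255).astype(np.uint8)
                tf = texture_vector(region)
                contrasts.append(tf.glds_contrast)
                homogeneities.append(tf.glds_homogeneity)
            for i in range(len(amplitudes) - 1):
                trials += 2
                wins += contrasts[i + 1] > contrasts[i]
                wins += homogeneities[i + 1] < homogeneities[i]
        assert wins / trials >= 0.95

    def test_translation_stability_on_stationary_texture(self):
        """Feature spread across shifted ROIs in a stationary texture stays small."""
        g = np.random.default_rng(99)
        tex = np.clip(120 * g.rayleigh(scale=1.0, size=(128, 256)) / np.sqrt(np.pi / 2), 0, 255).astype(np.uint8)
        contrasts = []
        for k in range(20):
            roi = tex[32 : 32 + 48, 8 + 9 * k : 8 + 9 * k + 48]
            contrasts.append(texture_vector(roi).glds_contrast)
        contrasts = np.asarray(contrasts)
        assert contrasts.std() / contrasts.mean() < 0.1
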