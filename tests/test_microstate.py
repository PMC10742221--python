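import itertools

import numpy as np
import pytest

from skillstate import microstate as ms
from skillstate.io import ValidationError


def orthonormal_maps(k, n_ch=32, seed=0):
    """k orthonormal zero-mean topographies."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_ch, k + 1))
    X -= X.mean(axis=0)
    q, _ = np.linalg.qr(X)
    q = q[:, :k].T
    q -= q.mean(axis=1, keepdims=True)
    return q / np.linalg.norm(q, axis=1, keepdims=True)


class TestGFP:
    def test_constant_sample_is_zero(self):
        assert ms.gfp(np.full((1, 8), 3.3))[0] == 0.0

    def test_two_channel_example(self):
        assert ms.gfp(np.array([[1.0, -1.0]]))[0] == 1.0

    def test_homogeneity(self, rng):
        x = rng.standard_normal((20, 16))
        np.testing.assert_allclose(ms.gfp(-2.5 * x), 2.5 * ms.gfp(x))


class TestPeakPicking:
    def test_sd_rejection_arithmetic(self):
        """Peak GFPs {1,1,1,10}: mean 3.25, SD 3.897 -> threshold 7.147
        rejects the 10."""
        g = np.zeros(41)
        for pos, v in zip([5, 15, 25, 35], [1.0, 1.0, 1.0, 10.0]):
            g[pos] = v
        vals = np.array([1.0, 1.0, 1.0, 10.0])
        assert vals.mean() + vals.std(ddof=0) == pytest.approx(7.147, abs=1e-3)
        peaks = ms.pick_gfp_peaks(g, fs=1000.0, min_distance_ms=1)
        np.testing.assert_array_equal(g[peaks], [1.0, 1.0, 1.0])

    def test_min_distance_keeps_larger_peak(self):
        g = np.zeros(30)
        g[10], g[11] = 1.0, 2.0  # 4 ms apart at 250 Hz
        peaks = ms.pick_gfp_peaks(
            np.concatenate([g, [0.0]]), fs=250.0, reject_sd=10
        )
        assert list(peaks) == [11]

    def test_monotone_series_has_no_peaks(self):
        with pytest.raises(ValidationError):
            ms.pick_gfp_peaks(np.arange(100.0), fs=250.0)

    def test_subsampling_deterministic(self, rng):
        g = np.abs(rng.standard_normal(5000)) + 0.1
        a = ms.pick_gfp_peaks(g, 250.0, n_peaks=50, seed=3)
        b = ms.pick_gfp_peaks(g, 250.0, n_peaks=50, seed=3)
        np.testing.assert_array_equal(a, b)
        assert len(a) == 50


class TestModifiedKmeans:
    def test_single_state_noiseless_recovery(self):
        protos = orthonormal_maps(1)
        rng = np.random.default_rng(0)
        c = rng.uniform(0.5, 2, 50) * rng.choice([-1, 1], 50)
        X = c[:, None] * protos
        model = ms.modified_kmeans(X, 1, n_init=3, seed=0)
        assert abs((model.prototypes @ protos.T).item()) == pytest.approx(1.0)
        assert model.gev_total == pytest.approx(1.0)

    def test_global_sign_flip_leaves_prototypes_unchanged(self):
        protos = orthonormal_maps(2)
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 60)
        c = rng.uniform(0.5, 2, 60) * rng.choice([-1, 1], 60)
        X = c[:, None] * protos[labels] + 0.01 * rng.standard_normal((60, 32))
        a = ms.modified_kmeans(X, 2, n_init=5, seed=0)
        b = ms.modified_kmeans(-X, 2, n_init=5, seed=0)
        match = np.abs(a.prototypes @ b.prototypes.T)
        assert match.max(axis=1) == pytest.approx(np.ones(2))

    def test_matches_exhaustive_labeling_on_12_maps(self):
        """Brute force over all 2^12 labelings (optimal prototype per
        cluster = dominant eigenvector) agrees with the fitted model."""
        protos = orthonormal_maps(2, seed=2)
        rng = np.random.default_rng(2)
        gen = np.array([0, 0, 0, 1, 1, 1, 0, 1, 0, 1, 1, 0])
        c = rng.uniform(0.8, 1.5, 12) * rng.choice([-1, 1], 12)
        X = c[:, None] * protos[gen] + 1e-3 * rng.standard_normal((12, 32))
        Xn = X - X.mean(axis=1, keepdims=True)
        Xn = Xn / np.linalg.norm(Xn, axis=1, keepdims=True)

        def residual(labels):
            total = 0.0
            for k in (0, 1):
                members = Xn[np.array(labels) == k]
                if len(members) == 0:
                    return np.inf
                S = members.T @ members
                total += len(members) - np.linalg.eigvalsh(S)[-1]
            return total

        best = min(
            itertools.product([0, 1], repeat=12), key=residual
        )
        model = ms.modified_kmeans(X, 2, n_init=10, seed=0)
        fitted = ms.backfit(X, model).labels
        agree = max(
            np.mean(fitted == np.array(best)),
            np.mean(fitted == 1 - np.array(best)),
        )
        assert agree == 1.0
        assert np.mean(np.array(best) == gen) in (0.0, 1.0)

    def test_k_exceeding_maps_rejected(self):
        with pytest.raises(ValidationError):
            ms.modified_kmeans(np.zeros((3, 8)), 4)

    def test_single_init_fixed_seed_bit_reproducible(self):
        protos = orthonormal_maps(3, seed=4)
        rng = np.random.default_rng(4)
        X = protos[rng.integers(0, 3, 40)] + 0.05 * rng.standard_normal((40, 32))
        a = ms.modified_kmeans(X, 3, n_init=1, seed=9)
        b = ms.modified_kmeans(X, 3, n_init=1, seed=9)
        np.testing.assert_array_equal(a.prototypes, b.prototypes)


class TestGEV:
    def test_noiseless_prototype_data_is_one(self):
        protos = orthonormal_maps(2, seed=5)
        labels = np.array([0, 1, 0, 1, 1])
        X = np.array([3, -2, 1, 0.5, -1])[:, None] * protos[labels]
        assert ms.gev(X, protos, labels) == pytest.approx(1.0)

    def test_orthogonal_assignment_is_zero(self):
        protos = orthonormal_maps(2, seed=6)
        X = np.array([1.0, -2.0])[:, None] * protos  # sample i = proto i
        wrong = np.array([1, 0])  # assign each to the orthogonal map
        assert ms.gev(X, protos, wrong) == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_independent_formula(self, rng):
        """GEV equals a direct evaluation of
        sum_t (GFP_t corr_t)^2 / sum_t GFP_t^2."""
        protos = orthonormal_maps(3, seed=7)
        X = rng.standard_normal((20, 32))
        X -= X.mean(axis=1, keepdims=True)
        labels = rng.integers(0, 3, 20)
        num = 0.0
        den = 0.0
        for t in range(20):
            g = X[t].std()
            a = protos[labels[t]]
            corr = np.corrcoef(X[t], a)[0, 1]
            num += (g * corr) ** 2
            den += g**2
        assert ms.gev(X, protos, labels) == pytest.approx(num / den)

    def test_invariant_to_sign_and_gain(self, rng):
        protos = orthonormal_maps(2, seed=8)
        X = rng.standard_normal((15, 32))
        labels = rng.integers(0, 2, 15)
        base = ms.gev(X, protos, labels)
        assert ms.gev(-X, protos, labels) == pytest.approx(base)
        assert ms.gev(4.2 * X, protos, labels) == pytest.approx(base)


class TestCVCriterion:
    def _six_state_data(self, seed=0, n=3000, noise=0.3):
        protos = orthonormal_maps(6, seed=seed)
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 6, n)
        c = rng.uniform(0.8, 1.6, n) * rng.choice([-1, 1], n)
        X = c[:, None] * protos[labels]
        X += noise * rng.standard_normal((n, 32)) / np.sqrt(32)
        return X - X.mean(axis=1, keepdims=True)

    def test_minimum_at_planted_k(self):
        X = self._six_state_data()
        cvs = {}
        for K in range(2, 9):
            m = ms.modified_kmeans(X, K, n_init=5, seed=0)
            cvs[K] = ms.cv_criterion(X, m)
        assert min(cvs, key=cvs.get) == 6

    def test_correction_diverges_near_channel_count(self):
        protos = orthonormal_maps(5, seed=1)
        X = self._six_state_data(seed=1, n=200)
        small = ms.cv_criterion(X, protos[:5])
        # same residuals, K close to C-1 -> correction factor explodes
        assert ms.cv_criterion(X[:, :7], orthonormal_maps(5, 7, seed=2)) > 0
        assert np.isinf(
            ms.cv_criterion(X[:, :6], orthonormal_maps(5, 6, seed=2))
        )
        assert small < 1.0

    def test_pure_noise_has_no_deep_minimum(self, rng):
        X = rng.standard_normal((1500, 32))
        X -= X.mean(axis=1, keepdims=True)
        cvs = []
        for K in (2, 4, 6, 8):
            m = ms.modified_kmeans(X, K, n_init=3, seed=0)
            cvs.append(ms.cv_criterion(X, m))
        # larger K never improves on the smallest model
        assert int(np.argmin(cvs)) == 0


class TestSelectModel:
    def test_single_k_range_returns_that_fit(self, rng):
        X = rng.standard_normal((800, 16)) * 5
        model = ms.select_model(X, fs=250.0, K_range=[3], n_init=3, seed=0)
        assert model.K == 3 and model.sorted

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValidationError):
            ms.select_model(rng.standard_normal((100, 8)), 250.0, K_range=[])

    def test_prototypes_sorted_by_decreasing_gev(self, rng):
        X = rng.standard_normal((800, 16)) * 5
        model = ms.select_model(X, fs=250.0, K_range=[4], n_init=3, seed=0)
        assert np.all(np.diff(model.gev_per_state) <= 1e-12)


class TestBackfit:
    def test_noiseless_sequence_recovered_exactly(self):
        protos = orthonormal_maps(3, seed=9)
        labels = np.repeat([0, 1, 2, 1], 25)
        rng = np.random.default_rng(9)
        c = rng.uniform(0.5, 2, 100) * rng.choice([-1, 1], 100)
        X = c[:, None] * protos[labels]
        seg = ms.backfit(X, protos)
        np.testing.assert_array_equal(seg.labels, labels)
        assert ms.gev(X, protos, seg.labels) == pytest.approx(1.0)

    def test_single_sample_intrusion_removed_by_smoothing(self):
        protos = orthonormal_maps(2, seed=10)
        labels = np.zeros(100, dtype=int)
        labels[50] = 1  # 4 ms intrusion at 250 Hz
        X = protos[labels] * 1.0
        seg = ms.backfit(X, protos, smooth={"window_ms": 30}, fs=250.0)
        assert seg.labels[50] == 0
        assert np.all(seg.labels == 0)

    def test_no_smoothing_is_idempotent_argmax(self):
        protos = orthonormal_maps(2, seed=11)
        rng = np.random.default_rng(11)
        X = rng.standard_normal((50, 32))
        a = ms.backfit(X, protos).labels
        b = ms.backfit(X, protos).labels
        np.testing.assert_array_equal(a, b)

    def test_channel_mismatch_rejected(self):
        protos = orthonormal_maps(2, seed=12)
        with pytest.raises(ValidationError):
            ms.backfit(np.zeros((10, 16)), protos)


def test_gev_nondecreasing_in_k_on_average():
    """Across seeds, mean GEV grows (weakly) with the number of states."""
    protos = orthonormal_maps(4, seed=13)
    rng = np.random.default_rng(13)
    labels = rng.integers(0, 4, 400)
    X = protos[labels] + 0.3 * rng.standard_normal((400, 32)) / np.sqrt(32)
    means = []
    for K in (2, 3, 4, 5):
        vals = [
            ms.modified_kmeans(X, K, n_init=2, seed=s).gev_total
            for s in range(10)
        ]
        means.append(np.mean(vals))
    assert np.all(np.diff(means) > -1e-3)
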