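import numpy as np
import pytest
from scipy import stats as sps

from oracles import correlation_t_by_hand, pearson_by_hand

from megfc.connectivity import (
    FCMatrix,
    correlation_t,
    effective_sample_count,
    fc_matrix,
    pair_correlation,
    r_threshold,
    threshold_network,
)
from megfc.errors import UndefinedCorrelationError
from megfc.preprocess import AnalysisSegment, band_by_name, bandpass_array
from megfc.synth import CouplingSpec, gen_background, inject_coupling


def make_segment(data, fs=1000.0, band=None, period="ictal"):
    n = data.shape[0]
    labels = [f"ch{i}" for i in range(n)]
    return AnalysisSegment(
        period=period,
        band=band or band_by_name("gamma"),
        data=np.asarray(data, dtype=float),
        fs=fs,
        channel_labels=labels,
        region_of={c: "frontal" for c in labels},
    )


class TestPairCorrelation:
    def test_self_correlation(self, rng):
        x = rng.standard_normal(100)
        assert pair_correlation(x, x) == pytest.approx(1.0)

    def test_sign_flip(self, rng):
        x = rng.standard_normal(100)
        assert pair_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # covariance/sd formula evaluated by hand: 10 / sqrt(10 * 14.8)
        r = pair_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert r == pytest.approx(10 / np.sqrt(148), abs=1e-12)
        assert r == pytest.approx(0.822, abs=5e-4)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pair_correlation(np.ones(10), np.arange(10.0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pair_correlation([1.0, 2.0], [3.0, 4.0])

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        r = pair_correlation(x, y)
        assert pair_correlation(3.2 * x + 7, y) == pytest.approx(r, abs=1e-12)
        assert pair_correlation(x, 0.1 * y - 4) == pytest.approx(r, abs=1e-12)

    def test_matches_hand_oracle(self, rng):
        for _ in range(100):
            x = rng.standard_normal(20)
            y = rng.standard_normal(20)
            assert pair_correlation(x, y) == pytest.approx(
                pearson_by_hand(x, y), abs=1e-10
            )


class TestFcMatrix:
    def test_identical_channels(self, rng):
        x = rng.standard_normal(100)
        fc = fc_matrix(make_segment(np.vstack([x, x])))
        assert fc.R[0, 1] == pytest.approx(1.0)

    def test_matches_pairwise_bruteforce(self, rng):
        for _ in range(50):
            data = rng.standard_normal((4, 30))
            fc = fc_matrix(make_segment(data))
            for i in range(4):
                for j in range(i + 1, 4):
                    assert fc.R[i, j] == pytest.approx(
                        pearson_by_hand(data[i], data[j]), abs=1e-10
                    )

    def test_symmetric_unit_diagonal(self, rng):
        fc = fc_matrix(make_segment(rng.standard_normal((5, 40))))
        assert np.array_equal(fc.R, fc.R.T)
        assert np.allclose(np.diag(fc.R), 1.0)

    def test_independent_noise_is_weak(self, rng):
        data = rng.standard_normal((4, 18000))
        fc = fc_matrix(make_segment(data))
        off = np.abs(fc.R[np.triu_indices(4, 1)])
        assert off.mean() < 0.02  # sampling error ~ 1/sqrt(K)

    def test_flat_channel_named_in_error(self, rng):
        data = rng.standard_normal((3, 50))
        data[1] = 2.0
        with pytest.raises(UndefinedCorrelationError, match="ch1"):
            fc_matrix(make_segment(data))


class TestCorrelationT:
    def test_zero_correlation(self):
        assert correlation_t(0.0, 1000) == 0.0

    def test_hand_value(self):
        # 0.5 * 3 / sqrt(0.75)
        assert correlation_t(0.5, 11) == pytest.approx(np.sqrt(3), abs=1e-12)
        assert correlation_t(0.5, 11) == pytest.approx(1.732, abs=5e-4)

    def test_odd_in_r(self, rng):
        for r in rng.uniform(-0.99, 0.99, 50):
            assert correlation_t(-r, 100) == pytest.approx(-correlation_t(r, 100))

    def test_monotone_in_k_and_r(self):
        assert correlation_t(0.3, 200) > correlation_t(0.3, 100)
        assert correlation_t(0.5, 100) > correlation_t(0.3, 100)

    def test_matches_hand_oracle(self, rng):
        for r in rng.uniform(-0.95, 0.95, 100):
            k = int(rng.integers(3, 500))
            assert correlation_t(r, k) == pytest.approx(
                correlation_t_by_hand(r, k), abs=1e-10
            )

    def test_boundary_errors(self):
        with pytest.raises(ValueError):
            correlation_t(1.0, 100)
        with pytest.raises(ValueError):
            correlation_t(0.5, 2)


class TestRThreshold:
    def test_value_at_study_scale(self):
        # invert t_crit = 1.9600 at df = 17998
        assert r_threshold(18000, 0.05) == pytest.approx(0.0146, abs=2e-4)

    def test_consistency_with_correlation_t(self):
        for k, alpha in [(100, 0.05), (1000, 0.01), (18000, 0.05)]:
            r_star = r_threshold(k, alpha)
            t_crit = sps.t.ppf(1 - alpha / 2, df=k - 2)
            assert correlation_t(r_star, k) == pytest.approx(t_crit, abs=1e-9)

    def test_monotone_decreasing_in_k(self):
        assert r_threshold(100, 0.05) > r_threshold(1000, 0.05)

    def test_alpha_to_one_limit(self):
        assert r_threshold(100, 0.999) < 1e-3

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            r_threshold(3, 0.05)
        with pytest.raises(ValueError):
            r_threshold(100, 0.0)


class TestThresholdNetwork:
    def small_fc(self, R, K=100):
        R = np.asarray(R, dtype=float)
        n = R.shape[0]
        labels = [f"ch{i}" for i in range(n)]
        return FCMatrix(R=R, K=K, band=band_by_name("gamma"), period="ictal", fs=1000.0,
                        channel_labels=labels, region_of={c: "frontal" for c in labels})

    def test_all_zero_gives_empty_network(self):
        R = np.eye(4)
        net = threshold_network(self.small_fc(R))
        assert net.n_edges == 0

    def test_negative_edge_labeled_inhibitory(self):
        R = np.eye(2)
        R[0, 1] = R[1, 0] = -0.9
        net = threshold_network(self.small_fc(R, K=100))
        assert net.adjacency[0, 1]
        assert net.sign_label(0, 1) == "inhibitory"

    def test_matches_bruteforce_filter(self, rng):
        for _ in range(50):
            A = rng.uniform(-1, 1, size=(5, 5)) * 0.9
            R = (A + A.T) / 2
            np.fill_diagonal(R, 1.0)
            K = int(rng.integers(10, 500))
            net = threshold_network(self.small_fc(R, K=K))
            r_star = r_threshold(K, 0.05)
            for i in range(5):
                for j in range(i + 1, 5):
                    assert net.adjacency[i, j] == (abs(R[i, j]) >= r_star)

    def test_effective_sample_count(self):
        # 3-s gamma segment: 2 * 50 Hz * 3 s = 300 effective samples
        assert effective_sample_count(3600, 1200.0, band_by_name("gamma")) == 300
        assert effective_sample_count(18000, 6000.0, band_by_name("gamma")) == 300

    def test_bandwidth_mode_uses_stricter_threshold(self, rng):
        fc = self.small_fc(np.eye(3), K=3600)  # 3.6 s at fs=1000
        nominal = threshold_network(fc, sample_mode="nominal")
        bandwidth = threshold_network(fc, sample_mode="bandwidth")
        assert bandwidth.r_threshold > nominal.r_threshold
        assert bandwidth.k_used == 2 * 50 * 3600 // 1000  # 2 B T


class TestNullCalibration:
    def test_independent_noise_retention_near_alpha(self, rng):
        # light version of the full calibration check: unfiltered independent
        # samples, nominal K, alpha 0.05
        retained = total = 0
        for seed in range(5):
            data = np.random.default_rng(seed).standard_normal((10, 18000))
            net = threshold_network(fc_matrix(make_segment(data)), alpha=0.05)
            retained += net.n_edges
            total += 45
        assert 0.02 < retained / total < 0.09


class TestPlantedRetention:
    def test_weak_coupling_always_detected(self):
        band = band_by_name("gamma")
        for seed in range(10):
            rec = gen_background(2, 3.0, 6000, seed=seed)
            out = inject_coupling(
                rec, CouplingSpec(band, frozenset({0, 1}), 0.2, (0.0, 3.0)), seed=seed
            )
            filt = bandpass_array(out.data, band, 6000)
            net = threshold_network(fc_matrix(make_segment(filt, fs=6000.0)), alpha=0.05)
            assert net.adjacency[0, 1]
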