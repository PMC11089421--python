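"""Deep clustering: autoencoder, exemplars, two-stage k-means, temporal metrics."""

import numpy as np
import pytest

from dynconn.autoencoder import Autoencoder, AutoencoderSpec, standardize_features
from dynconn.states import (
    cluster_states,
    elbow_select_k,
    match_states,
    select_exemplars,
    state_metrics,
    within_between_ratio,
)
from dynconn.windows import WindowSpec

SMALL = AutoencoderSpec(encoder_units=(32, 16, 5), epochs=120, batch_size=32, seed=0)


def planted_clusters(rng, k=4, n_per=120, dim=12, sep=8.0):
    centers = sep * rng.normal(size=(k, dim))
    x = np.vstack([c + rng.normal(size=(n_per, dim)) for c in centers])
    labels = np.repeat(np.arange(1, k + 1), n_per)
    return x, labels, centers


class TestAutoencoder:
    def test_linear_subspace_reconstruction(self, rng):
        """Data in a 5-dim subspace: reconstruction MSE < 5% of data variance."""
        z = rng.normal(size=(600, 5))
        mix = rng.normal(size=(5, 20))
        x, _, _ = standardize_features(z @ mix)
        ae = Autoencoder(20, SMALL).fit(x)
        mse = np.mean((ae.reconstruct(x) - x) ** 2)
        assert mse < 0.05 * x.var()

    def test_full_capacity_near_identity(self, rng):
        x, _, _ = standardize_features(rng.normal(size=(400, 6)))
        spec = AutoencoderSpec(encoder_units=(16, 8), epochs=150, batch_size=32, seed=1)
        ae = Autoencoder(6, spec).fit(x)  # bottleneck 8 >= input 6
        assert ae.final_mse < 0.05 * x.var()

    def test_no_collapse_on_standardized_features(self, rng):
        x, _, _ = standardize_features(rng.normal(size=(500, 10)) ** 3)
        ae = Autoencoder(10, SMALL).fit(x)
        out_var = ae.reconstruct(x).var()
        assert out_var < 2 * x.var()
        assert out_var > 0.1 * x.var()

    def test_reproducible_from_seed(self, rng):
        x, _, _ = standardize_features(rng.normal(size=(200, 8)))
        spec = AutoencoderSpec(encoder_units=(8, 4), epochs=10, batch_size=50, seed=3)
        a = Autoencoder(8, spec).fit(x)
        b = Autoencoder(8, spec).fit(x)
        np.testing.assert_array_equal(a.encode(x), b.encode(x))

    def test_exploding_loss_aborts(self, rng):
        x, _, _ = standardize_features(rng.normal(size=(200, 8)))
        spec = AutoencoderSpec(
            encoder_units=(8, 4), epochs=5, batch_size=50, seed=0,
            learning_rate=1e12,
        )
        with pytest.raises(FloatingPointError):
            Autoencoder(8, spec).fit(x)


class TestExemplars:
    @staticmethod
    def windows_with_variance(var_values):
        """Rows whose across-feature variance equals the requested values."""
        return np.array([[np.sqrt(v), -np.sqrt(v)] for v in var_values])

    def test_strict_local_maxima(self):
        w = self.windows_with_variance([1, 3, 2, 5, 4])
        idx, fell_back = select_exemplars(w)
        assert idx.tolist() == [1, 3]
        assert not fell_back

    def test_brute_force_oracle(self, rng):
        vals = rng.uniform(0.1, 10, size=40)
        w = self.windows_with_variance(vals)
        idx, _ = select_exemplars(w)
        expect = [
            i for i in range(1, 39)
            if vals[i] > vals[i - 1] and vals[i] > vals[i + 1]
        ]
        assert idx.tolist() == expect

    def test_monotone_series_falls_back(self):
        w = self.windows_with_variance(np.arange(1.0, 13.0))
        idx, fell_back = select_exemplars(w)
        assert fell_back
        assert len(idx) >= 3

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            select_exemplars(np.zeros((2, 5)))


class TestClusterStates:
    def test_planted_clusters_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        x, labels, _ = planted_clusters(rng)
        model = cluster_states(x, x[::5], 4, seed=0)
        assert adjusted_rand_score(labels, model.assignments) > 0.95

    def test_duplication_invariance(self, rng):
        x, _, _ = planted_clusters(rng, k=3)
        m1 = cluster_states(x, x[::4], 3, seed=0)
        m2 = cluster_states(np.vstack([x, x]), x[::4], 3, seed=0)
        perm, cors = match_states(m2.centroids, m1.centroids)
        np.testing.assert_allclose(
            m2.centroids[perm], m1.centroids, atol=1e-6
        )

    def test_k1_centroid_is_mean(self, rng):
        x = rng.normal(size=(50, 4))
        model = cluster_states(x, x[:10], 1, seed=0)
        np.testing.assert_allclose(model.centroids[0], x.mean(axis=0))

    def test_k_exceeding_exemplars_rejected(self, rng):
        x = rng.normal(size=(50, 4))
        with pytest.raises(ValueError, match="exemplar"):
            cluster_states(x, x[:3], 5, seed=0)


class TestElbow:
    def test_selects_planted_four(self, rng):
        x, _, _ = planted_clusters(rng, k=4)
        k, ratios, models, confident = elbow_select_k(x, x[::5], range(2, 9), seed=0)
        assert k == 4
        assert confident

    def test_selects_planted_two(self, rng):
        x, _, _ = planted_clusters(rng, k=2, n_per=200)
        k, *_ = elbow_select_k(x, x[::5], range(2, 7), seed=0)
        assert k == 2

    def test_single_blob_low_confidence(self, rng):
        x = rng.normal(size=(500, 8))
        k, ratios, models, confident = elbow_select_k(x, x[::7], range(2, 9), seed=0)
        assert not confident

    def test_too_few_candidates_rejected(self, rng):
        x = rng.normal(size=(100, 4))
        with pytest.raises(ValueError):
            elbow_select_k(x, x[::5], range(2, 4), seed=0)


class TestStateMetrics:
    spec = WindowSpec()

    def test_run_length_example(self):
        labels = {"s": np.array([1, 1, 1, 2, 2, 1, 1])}
        m = state_metrics(labels, self.spec, k=2)
        assert m.dwell_time.loc["s", "state_1"] == pytest.approx(2.5 * 0.906)
        assert m.dwell_time.loc["s", "state_2"] == pytest.approx(2.0 * 0.906)
        assert m.fractional_occupancy.loc["s", "state_1"] == pytest.approx(5 / 7)

    def test_constant_labels(self):
        labels = {"s": np.full(100, 3)}
        m = state_metrics(labels, self.spec, k=3)
        assert m.dwell_time.loc["s", "state_3"] == pytest.approx(100 * 0.906)
        assert m.fractional_occupancy.loc["s", "state_3"] == 1.0
        assert not m.visited.loc["s", "state_1"]
        assert np.isnan(m.dwell_time.loc["s", "state_1"])

    def test_alternating_labels(self):
        labels = {"s": np.array([1, 2] * 20)}
        m = state_metrics(labels, self.spec, k=2)
        assert m.dwell_time.loc["s", "state_1"] == pytest.approx(0.906)
        assert m.fractional_occupancy.loc["s"].tolist() == [0.5, 0.5]

    def test_brute_force_run_length_oracle(self, rng):
        labels = rng.integers(1, 4, size=200)
        m = state_metrics({"s": labels}, self.spec, k=3)
        # brute force: walk the sequence
        for s in (1, 2, 3):
            runs, cur = [], 0
            for v in labels:
                if v == s:
                    cur += 1
                elif cur:
                    runs.append(cur)
                    cur = 0
            if cur:
                runs.append(cur)
            if runs:
                assert m.dwell_time.loc["s", f"state_{s}"] == pytest.approx(
                    np.mean(runs) * 0.906
                )
            assert m.fractional_occupancy.loc["s", f"state_{s}"] == pytest.approx(
                (labels == s).mean()
            )

    def test_occupancies_sum_to_one(self, rng):
        labels = {f"s{i}": rng.integers(1, 5, size=100) for i in range(5)}
        m = state_metrics(labels, self.spec, k=4)
        np.testing.assert_allclose(m.fractional_occupancy.sum(axis=1), 1.0)

    def test_label_permutation_invariance(self, rng):
        labels = rng.integers(1, 4, size=150)
        perm = {1: 3, 2: 1, 3: 2}
        permuted = np.vectorize(perm.get)(labels)
        m1 = state_metrics({"s": labels}, self.spec, k=3)
        m2 = state_metrics({"s": permuted}, self.spec, k=3)
        for s in (1, 2, 3):
            a = m1.dwell_time.loc["s", f"state_{s}"]
            b = m2.dwell_time.loc["s", f"state_{perm[s]}"]
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)


def test_match_states_permutation(rng):
    ref = rng.normal(size=(4, 30))
    perm = [2, 3, 0, 1]
    est = ref[perm] + 0.01 * rng.normal(size=(4, 30))
    p, cors = match_states(est, ref)
    # p[j] is the estimated row matched to reference row j
    assert [perm[i] for i in p.tolist()] == [0, 1, 2, 3] or cors.min() > 0.99
    assert cors.min() > 0.99
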