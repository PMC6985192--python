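import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lucmap import (
    build_feature_matrix,
    evaluate_samples,
    filter_samples,
    label_neurons,
    reduction_percentage,
    train_som,
)
from lucmap.som_qc import SampleReliability, default_grid_side

from conftest import make_cluster_samples, make_constant_sample


class TestTrainSom:
    def test_single_neuron_contracts_to_single_input(self):
        x = np.full((1, 92), 0.4)
        som = train_som(x, 1, 1, epochs=200, seed=0)
        np.testing.assert_allclose(som.weights[0], x[0], atol=1e-3)

    def test_determinism(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (30, 92))
        a = train_som(X, 3, 3, epochs=10, seed=5)
        b = train_som(X, 3, 3, epochs=10, seed=5)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_two_clusters_recovered_by_2x1_grid(self):
        # k-means-style oracle: each neuron should sit near one cluster mean
        sd = 0.02
        samples = make_cluster_samples(
            {"cerrado": -0.5, "forest": 0.5}, 40, sd, seed=1
        )
        X = build_feature_matrix(samples)
        som = train_som(X, 2, 1, epochs=50, seed=2)
        means = np.array([[-0.5], [0.5]]) * np.ones((2, 92))
        d = np.linalg.norm(som.weights[:, None, :] - means[None], axis=2)
        nearest = d.min(axis=1)
        assert np.all(nearest < 3 * sd * np.sqrt(92))
        assert set(d.argmin(axis=1)) == {0, 1}  # clusters distinct

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            train_som(np.empty((0, 92)), 2, 2)
        with pytest.raises(ValueError):
            train_som(np.ones((3, 92)), 0, 2)


class TestLabelNeurons:
    def test_majority_vote(self):
        samples = [make_constant_sample(0.5, "pasture") for _ in range(3)]
        samples.append(make_constant_sample(0.5, "forest"))
        X = build_feature_matrix(samples)
        som = train_som(X, 1, 1, epochs=5, seed=0)
        som = label_neurons(som, samples, X)
        assert som.neuron_labels[0] == "pasture"

    def test_tie_broken_by_global_count(self):
        # neuron sees 2 pasture + 2 cerrado; cerrado globally more frequent
        near = [make_constant_sample(0.5, "pasture") for _ in range(2)]
        near += [make_constant_sample(0.5, "cerrado") for _ in range(2)]
        far = [make_constant_sample(-0.5, "cerrado") for _ in range(3)]
        samples = near + far
        X = build_feature_matrix(samples)
        som = train_som(X, 2, 1, epochs=50, seed=1)
        som = label_neurons(som, samples, X)
        bmu_near = som.bmu(X[:1])[0]
        assert som.neuron_labels[int(bmu_near)] == "cerrado"

    def test_unmapped_neuron_stays_unlabelled(self):
        samples = [make_constant_sample(0.5, "forest") for _ in range(5)]
        X = build_feature_matrix(samples)
        som = train_som(X, 3, 3, epochs=5, seed=0)
        som = label_neurons(som, samples, X)
        bmus = set(int(b) for b in som.bmu(X))
        for i in range(som.n_neurons):
            if i not in bmus:
                assert som.neuron_labels[i] is None


class TestEvaluateSamples:
    def test_single_class_dataset_full_reliability(self):
        samples = make_cluster_samples({"forest": 0.5}, 12, 0.01, seed=0)
        rels = evaluate_samples(samples, n_runs=3, epochs=10, seed=1)
        for r in rels:
            assert r.own_frequency() == 1.0

    def test_separable_clusters_full_reliability(self):
        samples = make_cluster_samples(
            {"cerrado": 0.2, "pasture": 0.5, "forest": 0.8}, 50, 0.01, seed=2
        )
        rels = evaluate_samples(samples, n_runs=10, epochs=20, seed=3)
        assert all(r.own_frequency() == 1.0 for r in rels)

    def test_relabelled_sample_has_low_own_frequency(self):
        samples = make_cluster_samples(
            {"cerrado": 0.2, "pasture": 0.5, "forest": 0.8}, 50, 0.01, seed=2
        )
        samples[0].label = "forest"  # series stays from the 0.2 cluster
        rels = evaluate_samples(samples, n_runs=10, epochs=20, seed=3)
        assert rels[0].own_frequency() <= 0.2

    def test_frequencies_sum_to_one(self):
        samples = make_cluster_samples(
            {"cerrado": 0.1, "forest": 0.7}, 20, 0.05, seed=4
        )
        rels = evaluate_samples(samples, n_runs=5, epochs=10, seed=5)
        for r in rels:
            assert sum(r.label_frequency.values()) == pytest.approx(1.0, abs=1e-9)


class TestFilterSamples:
    def _reliability(self, sid, freqs):
        return SampleReliability(sid, "pasture", freqs)

    def test_published_reliability_examples(self):
        """Three pasture samples at 100%, 52% and 5% own-label frequency."""
        rels = [
            self._reliability(1, {"pasture": 1.0}),
            self._reliability(
                2,
                {"pasture": 0.52, "cerrado": 0.41, "forest": 0.02,
                 "soy-corn": 0.02, "soy-cotton": 0.02, "fallow-cotton": 0.01},
            ),
            self._reliability(
                3, {"cerrado": 0.94, "pasture": 0.05, "forest": 0.01}
            ),
        ]
        for r in rels:
            assert sum(r.label_frequency.values()) == pytest.approx(1.0)
        samples = [make_constant_sample(0.5, "pasture") for _ in range(3)]
        retained, removed, report = filter_samples(rels, 0.8, samples)
        assert len(retained) == 1 and len(removed) == 2
        assert [row["retained"] for row in report.rows] == [True, False, False]

    def test_exact_threshold_retained(self):
        rels = [self._reliability(0, {"pasture": 0.80, "cerrado": 0.20})]
        samples = [make_constant_sample(0.5, "pasture")]
        retained, removed, _ = filter_samples(rels, 0.8, samples)
        assert len(retained) == 1

    def test_partition(self):
        rels = [
            self._reliability(i, {"pasture": f, "cerrado": 1 - f})
            for i, f in enumerate([0.1, 0.5, 0.9, 1.0])
        ]
        samples = [make_constant_sample(0.5, "pasture") for _ in rels]
        retained, removed, _ = filter_samples(rels, 0.8, samples)
        assert len(retained) + len(removed) == len(samples)
        assert not (set(map(id, retained)) & set(map(id, removed)))

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_threshold_monotonicity(self, freqs):
        rels = [
            self._reliability(i, {"pasture": f, "cerrado": 1 - f})
            for i, f in enumerate(freqs)
        ]
        samples = [make_constant_sample(0.5, "pasture") for _ in freqs]
        kept = [
            len(filter_samples(rels, thr, samples)[0])
            for thr in (0.2, 0.5, 0.8, 1.0)
        ]
        assert kept == sorted(kept, reverse=True)

    def test_report_csv(self, tmp_path):
        rels = [self._reliability(0, {"pasture": 1.0})]
        samples = [make_constant_sample(0.5, "pasture")]
        _, _, report = filter_samples(rels, 0.8, samples)
        path = tmp_path / "report.csv"
        report.write_csv(path)
        assert "sample_id" in path.read_text().splitlines()[0]


def test_reduction_percentage_arithmetic():
    assert reduction_percentage(2115, 1892) == 10.5
    assert reduction_percentage(100, 100) == 0.0


def test_default_grid_side_heuristic():
    assert default_grid_side(1) >= 1
    assert default_grid_side(900) == 13
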