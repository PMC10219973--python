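import numpy as np
import pytest

from uromics import (IntensityMatrix, auc, correlation_network, plsda,
                     two_block_pls)
from uromics.errors import ParameterError, ValidationError
from uromics.integrate import _standardize


def mk(values, kind="volatile", prefix="F"):
    values = np.asarray(values, float)
    return IntensityMatrix(values, [f"{prefix}{i}" for i in range(values.shape[0])],
                           [f"s{j}" for j in range(values.shape[1])], kind)


def separable_classes(n_per_class=10, n_feat=50, n_informative=3, delta=5.0,
                      seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(10, 1, (n_feat, 2 * n_per_class))
    X[:n_informative, n_per_class:] += delta
    labels = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    return mk(np.abs(X)), labels


class TestAuc:
    def test_perfect_separation(self):
        assert auc([3, 4, 5, 1, 2], [True, True, True, False, False]) == 1.0

    def test_enumeration_three_quarters(self):
        # positives {3, 1}? no: M scores 1,3; F scores 2,4 -> 3 of 4 pairs
        assert auc([1, 3, 2, 4], [False, False, True, True]) == 0.75

    def test_all_ties_half(self):
        assert auc([2, 2, 2, 2], [True, False, True, False]) == 0.5

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(0, 1, 30)
        labels = rng.random(30) > 0.5
        base = auc(scores, labels)
        assert auc(np.exp(scores), labels) == pytest.approx(base)
        assert auc(scores ** 3, labels) == pytest.approx(base)

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            auc([1, 2], [True, True])


class TestPlsda:
    def test_separable_classes_auc_one(self):
        m, labels = separable_classes()
        res = plsda(m, labels, n_components=2)
        assert res.auc_per_component()[0] == 1.0

    def test_sparse_support_recovers_planted_features(self):
        m, labels = separable_classes()
        res = plsda(m, labels, n_components=1, keep=3)
        support = {m.feature_ids[i] for i in res.kept_features[0]}
        assert support == {"F0", "F1", "F2"}

    def test_permuted_labels_near_chance_cross_validated(self):
        from uromics.integrate import cross_validated_auc
        m, labels = separable_classes(n_informative=0, delta=0.0)
        rng = np.random.default_rng(1)
        aucs = []
        for i in range(20):
            perm = rng.permutation(labels)
            aucs.append(cross_validated_auc(m, perm, n_components=1, seed=i))
        assert 0.35 <= np.median(aucs) <= 0.65

    def test_informative_signal_survives_cross_validation(self):
        from uromics.integrate import cross_validated_auc
        m, labels = separable_classes()
        assert cross_validated_auc(m, labels, n_components=1, seed=0) > 0.9

    def test_scaling_invariance(self):
        # internal standardization runs exactly once: feeding pre-standardized
        # data (shifted to stay nonnegative) gives identical scores
        m, labels = separable_classes()
        res_raw = plsda(m, labels, n_components=2)
        X, _, _ = _standardize(m.values.T)          # samples x features
        pre = (X - X.min()).T                       # unit-variance columns
        res_scaled = plsda(m.copy_with(pre), labels, n_components=2)
        np.testing.assert_allclose(res_scaled.scores_x, res_raw.scores_x,
                                   atol=1e-8)

    def test_score_orthogonality(self):
        m, labels = separable_classes(seed=3)
        res = plsda(m, labels, n_components=3)
        G = res.scores_x.T @ res.scores_x
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_class_means_separate(self):
        m, labels = separable_classes()
        res = plsda(m, labels, n_components=1)
        cm = res.class_means()
        assert cm["B"][0] > cm["A"][0]

    def test_parameter_validation(self):
        m, labels = separable_classes()
        with pytest.raises(ParameterError):
            plsda(m, labels, n_components=0)
        with pytest.raises(ParameterError):
            plsda(m, labels, keep=999)
        with pytest.raises(ValidationError):
            plsda(m, np.repeat("A", m.n_samples))


class TestTwoBlock:
    def test_identical_blocks_correlation_one(self):
        rng = np.random.default_rng(2)
        x = mk(rng.lognormal(3, 1, (20, 15)), "protein")
        y = mk(x.values.copy(), "volatile", prefix="V")
        res = two_block_pls(x, y, n_components=1)
        assert res.component_correlation[0] == pytest.approx(1.0, abs=1e-9)

    def test_component_one_matches_svd_of_cross_covariance(self):
        rng = np.random.default_rng(3)
        x = mk(rng.lognormal(3, 1, (25, 18)), "protein")
        y = mk(rng.lognormal(3, 1, (30, 18)), "volatile", prefix="V")
        res = two_block_pls(x, y, n_components=1)
        X, _, _ = _standardize(x.values.T)
        Y, _, _ = _standardize(y.values.T)
        U, S, Vt = np.linalg.svd(X.T @ Y, full_matrices=False)
        wx = res.weights_x[:, 0]
        wy = res.weights_y[:, 0]
        assert min(np.linalg.norm(wx - U[:, 0]), np.linalg.norm(wx + U[:, 0])) < 1e-6
        assert min(np.linalg.norm(wy - Vt[0]), np.linalg.norm(wy + Vt[0])) < 1e-6

    def test_sample_mismatch_names_difference(self):
        x = mk(np.ones((3, 4)), "protein")
        y = IntensityMatrix(np.ones((3, 4)), ["V0", "V1", "V2"],
                            ["s0", "s1", "s2", "zz"], "volatile")
        with pytest.raises(ValidationError, match="zz"):
            two_block_pls(x, y)

    def test_shared_signal_high_component_correlation(self, sim_default):
        protein, volatile, ann, _ = sim_default
        spec = ann.specimen_ids()
        vol_s = volatile.subset_samples(spec)
        lp = np.log2(protein.values + 1)
        lv = np.log2(vol_s.values + 1)
        res = two_block_pls(protein.copy_with(lp),
                            IntensityMatrix(lv, vol_s.feature_ids, spec,
                                            "volatile"), n_components=2)
        assert res.component_correlation[0] >= 0.8


class TestNetwork:
    def test_planted_pairs_recovered(self, sim_default):
        protein, volatile, ann, truth = sim_default
        spec = ann.specimen_ids()
        lp = protein.copy_with(np.log2(protein.values + 1))
        vs = volatile.subset_samples(spec)
        lv = IntensityMatrix(np.log2(vs.values + 1), vs.feature_ids, spec,
                             "volatile")
        edges = correlation_network(lp, lv, r_threshold=0.62)
        found = {(r.source, r.target) for r in edges.itertuples()}
        recall = sum((p, v) in found for p, v, _ in truth.pairs) / len(truth.pairs)
        assert recall >= 0.9

    def test_threshold_monotonicity_and_bound(self):
        rng = np.random.default_rng(5)
        x = mk(rng.normal(10, 2, (10, 12)), "protein")
        y = mk(rng.normal(10, 2, (10, 12)), "volatile", prefix="V")
        sizes = [len(correlation_network(x, y, r)) for r in (0.2, 0.5, 0.8)]
        assert sizes == sorted(sizes, reverse=True)
        assert len(correlation_network(x, y, 0.999)) == 0

    def test_duplicated_feature_inherits_edges(self):
        rng = np.random.default_rng(6)
        base = rng.normal(10, 2, (5, 12))
        x = mk(base, "protein")
        x2 = IntensityMatrix(np.vstack([base, base[:1]]),
                             [f"F{i}" for i in range(5)] + ["F0_twin"],
                             x.sample_ids, "protein")
        y = mk(rng.normal(10, 2, (6, 12)), "volatile", prefix="V")
        e1 = correlation_network(x, y, 0.5)
        e2 = correlation_network(x2, y, 0.5)
        f0_edges = {(r.target, round(r.r, 9)) for r in e1.itertuples()
                    if r.source == "F0"}
        twin_edges = {(r.target, round(r.r, 9)) for r in e2.itertuples()
                      if r.source == "F0_twin"}
        assert twin_edges == f0_edges

    def test_constant_feature_excluded(self):
        x = mk(np.vstack([np.full(8, 3.0), np.arange(8.0)]), "protein")
        y = mk(np.arange(8.0).reshape(1, 8), "volatile", prefix="V")
        edges = correlation_network(x, y, 0.5)
        assert set(edges["source"]) == {"F1"}
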