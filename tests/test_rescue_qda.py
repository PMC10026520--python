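import numpy as np
import pytest
from scipy.stats import multivariate_normal

from snapshot_ccre import abundance_filter, indexing
from snapshot_ccre.indexing import NULL_INDEX, IndexSet
from snapshot_ccre.rescue_qda import finalize_index_sets, fit_qda, rescue

from conftest import planted_index_strings


def _sets(features, labels):
    return [
        IndexSet(index=str(lab), member_ids=np.flatnonzero(labels == lab), status="abundant")
        for lab in np.unique(labels)
    ]


@pytest.fixture
def gaussian_classes():
    rng = np.random.default_rng(9)
    mus = np.array([[0.0, 0.0, 0.0], [5.0, 5.0, 0.0], [0.0, 5.0, 5.0]])
    covs = [np.eye(3), np.diag([1.0, 2.0, 0.5]), 0.5 * np.eye(3)]
    xs, labels = [], []
    for i, (mu, cov) in enumerate(zip(mus, covs)):
        xs.append(rng.multivariate_normal(mu, cov, size=2000))
        labels.append(np.full(2000, i))
    return np.vstack(xs), np.concatenate(labels), mus, covs


class TestFitQda:
    def test_equal_sizes_equal_priors(self):
        features = np.vstack([np.random.default_rng(0).normal(size=(10, 2)) + off
                              for off in (0, 10)])
        model = fit_qda(features, _sets(features, np.repeat([0, 1], 10)))
        np.testing.assert_allclose(model.priors, [0.5, 0.5])

    def test_identical_vectors_ridge_only_covariance(self):
        features = np.tile([2.0, 3.0], (10, 1))
        model = fit_qda(features, _sets(features, np.zeros(10)), ridge=1e-4)
        # zero sample variance: covariance is the ridge term alone
        np.testing.assert_allclose(model.covariances[0], 1e-4 * np.eye(2))

    def test_mean_recovery_within_3_se(self, gaussian_classes):
        features, labels, mus, covs = gaussian_classes
        model = fit_qda(features, _sets(features, labels))
        for i, (mu, cov) in enumerate(zip(mus, covs)):
            se = np.sqrt(np.diag(cov) / 2000)
            assert (np.abs(model.means[i] - mu) < 3 * se).all()

    def test_small_class_pools_covariance(self):
        rng = np.random.default_rng(2)
        big = rng.normal(size=(100, 3))
        small = rng.normal(size=(3, 3)) + 10  # < d + 2 members
        features = np.vstack([big, small])
        labels = np.array([0] * 100 + [1] * 3)
        ridge = 1e-6
        model = fit_qda(features, _sets(features, labels), ridge=ridge)
        # expected: size-weighted pooled covariance + the ridge term
        covs = [np.cov(big, rowvar=False), np.cov(small, rowvar=False)]
        w = np.array([100, 3]) / 103
        pooled = w[0] * covs[0] + w[1] * covs[1]
        expected = pooled + ridge * np.trace(pooled) / 3 * np.eye(3)
        np.testing.assert_allclose(model.covariances[1], expected, rtol=1e-9)


class TestRescue:
    def test_at_class_mean_wins(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(50, 2))
        b = rng.normal(size=(50, 2)) + 8
        features = np.vstack([a, b, [a.mean(axis=0)]])
        sets = _sets(features[:100], np.repeat([0, 1], 50))
        model = fit_qda(features, sets)
        assigned, post = rescue(model, features, np.array([100]))
        assert assigned[0] == "0" and post[0] > 0.5

    def test_equidistant_boundary_is_assigned(self):
        # two classes with identical covariance and priors; x exactly between
        features = np.vstack(
            [
                np.array([[0.0, 0.0], [0.0, 2.0], [2.0, 0.0], [2.0, 2.0]]),
                np.array([[10.0, 0.0], [10.0, 2.0], [12.0, 0.0], [12.0, 2.0]]),
                [[6.0, 1.0]],  # midpoint
            ]
        )
        sets = _sets(features[:8], np.repeat([0, 1], 4))
        model = fit_qda(features, sets)
        assigned, post = rescue(model, features, np.array([8]))
        assert post[0] == pytest.approx(0.5)
        assert assigned[0] != NULL_INDEX  # exactly 0.5 passes the '< 0.5' null rule

    def test_posteriors_sum_to_one(self, gaussian_classes):
        features, labels, *_ = gaussian_classes
        model = fit_qda(features, _sets(features, labels))
        post = model.posteriors(features[:100])
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_feature_length_mismatch(self, gaussian_classes):
        features, labels, *_ = gaussian_classes
        model = fit_qda(features, _sets(features, labels))
        with pytest.raises(ValueError, match="feature length"):
            model.discriminant_scores(np.zeros((1, 5)))

    def test_oracle_log_density_equivalence(self):
        """Discriminant == MVN log-density + log prior, up to (d/2)ln(2pi)."""
        rng = np.random.default_rng(4)
        d = 4
        features = np.vstack([rng.normal(size=(40, d)) + off for off in (0, 3, 6)])
        labels = np.repeat([0, 1, 2], 40)
        model = fit_qda(features, _sets(features, labels), ridge=1e-8)
        x = rng.normal(size=(20, d)) + 3
        scores = model.discriminant_scores(x)
        const = 0.5 * d * np.log(2 * np.pi)
        for i in range(3):
            oracle = (
                multivariate_normal(model.means[i], model.covariances[i]).logpdf(x)
                + np.log(model.priors[i])
                + const
            )
            np.testing.assert_allclose(scores[:, i], oracle, atol=1e-9)

    def test_flipped_members_rescued(self):
        """One bit flipped in 10% of members -> >=90% rescued to planted IS."""
        from snapshot_ccre.synthetic import FixtureConfig, generate

        fx = generate(FixtureConfig(seed=3, bit_flip_rate=0.10, max_flip_bits=1))
        bm = indexing.binarize(fx.master, fx.peak_lists, fx.tree)
        sets = indexing.group_into_index_sets(bm)
        abundance_filter.apply_filter(sets)
        abundant = [s for s in sets if s.status == "abundant"]
        assert {s.index for s in abundant} == planted_index_strings(fx)
        model = fit_qda(fx.signal, abundant)
        filtered_ids = np.concatenate(
            [s.member_ids for s in sets if s.status == "filtered"]
        )
        assigned, _ = rescue(model, fx.signal, filtered_ids)
        truth = fx.truth.set_index("ccre_id").loc[filtered_ids]
        flipped = truth["flipped"].to_numpy()
        recovered = (assigned[flipped] == truth["true_index"].to_numpy()[flipped]).mean()
        assert recovered >= 0.90


class TestFinalize:
    @pytest.fixture
    def simple_catalog(self):
        rng = np.random.default_rng(0)
        features = rng.normal(size=(20, 2))
        sets = [
            IndexSet(index="1_0", member_ids=np.arange(0, 10), status="abundant"),
            IndexSet(index="0_1", member_ids=np.arange(10, 18), status="abundant"),
            IndexSet(index="1_1", member_ids=np.arange(18, 20), status="filtered"),
        ]
        return features, sets

    def test_zero_filtered_unchanged_plus_empty_null(self, simple_catalog):
        features, sets = simple_catalog
        final = finalize_index_sets(
            sets[:2], np.array([], dtype=object), np.array([], dtype=int), features
        )
        assert [s.index for s in final] == ["1_0", "0_1", NULL_INDEX]
        assert final[-1].size == 0

    def test_conservation(self, simple_catalog):
        features, sets = simple_catalog
        assigned = np.array(["1_0", NULL_INDEX], dtype=object)
        final = finalize_index_sets(sets, assigned, np.array([18, 19]), features)
        assert sum(s.size for s in final) == 20
        assert final[0].size == 11  # grew by the rescued member

    def test_abundant_membership_preserved(self, simple_catalog):
        features, sets = simple_catalog
        assigned = np.array(["0_1", "0_1"], dtype=object)
        final = finalize_index_sets(sets, assigned, np.array([18, 19]), features)
        by_index = {s.index: set(s.member_ids) for s in final}
        assert set(range(10)) <= by_index["1_0"]
        assert set(range(10, 18)) <= by_index["0_1"]

    def test_mean_signal_recomputed(self, simple_catalog):
        features, sets = simple_catalog
        assigned = np.array(["1_0", "1_0"], dtype=object)
        final = finalize_index_sets(sets, assigned, np.array([18, 19]), features)
        members = final[0].member_ids
        np.testing.assert_allclose(final[0].mean_signal, features[members].mean(axis=0))
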