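"""Arcsine transform, Ward clustering vs a brute-force oracle, two-group CVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f as f_dist

from gutshift import (ValidationError, arcsine_transform, dfa_two_group,
                      ward_two_clusters)


class TestArcsine:
    def test_anchor_points(self):
        assert arcsine_transform(0.0) == 0.0
        assert arcsine_transform(100.0) == pytest.approx(np.pi / 2)
        assert arcsine_transform(50.0) == pytest.approx(np.pi / 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            arcsine_transform(101.0)
        with pytest.raises(ValidationError):
            arcsine_transform(-0.1)


def brute_force_ward_increments(x):
    """Greedy Ward agglomeration computed from first principles: at each
    step merge the pair of clusters with the smallest increase in total
    within-cluster sum of squares; return the increments in merge order."""
    clusters = [[i] for i in range(len(x))]
    increments = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = x[clusters[i]], x[clusters[j]]
                na, nb = len(a), len(b)
                d2 = ((a.mean(0) - b.mean(0)) ** 2).sum()
                delta = na * nb / (na + nb) * d2
                if best is None or delta < best[0]:
                    best = (delta, i, j)
        delta, i, j = best
        increments.append(delta)
        clusters = ([clusters[k] for k in range(len(clusters))
                     if k not in (i, j)] + [clusters[i] + clusters[j]])
    return np.array(increments)


class TestWard:
    @pytest.mark.parametrize("n,p,seed", [(5, 2, 0), (6, 3, 1), (7, 4, 2),
                                          (7, 2, 3)])
    def test_heights_equal_brute_force_variance_increments(self, n, p, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, p))
        profiles = pd.DataFrame(x, index=[f"F{i}" for i in range(n)])
        labels = pd.Series(["x"] * (n // 2) + ["y"] * (n - n // 2),
                           index=profiles.index)
        res = ward_two_clusters(profiles, labels)
        ref = brute_force_ward_increments(x)
        np.testing.assert_allclose(res.heights, ref, rtol=1e-10)
        assert (np.diff(res.linkage[:, 2]) >= -1e-12).all()

    def test_separated_blobs_recover_labels(self, rng):
        a = rng.normal(0, 0.2, size=(8, 3))
        b = rng.normal(5, 0.2, size=(7, 3)) + [0, 5, 0]
        profiles = pd.DataFrame(np.vstack([a, b]),
                                index=[f"F{i}" for i in range(15)])
        labels = pd.Series(["juv"] * 8 + ["mat"] * 7, index=profiles.index)
        res = ward_two_clusters(profiles, labels)
        assert res.misclassified == {"juv": 0, "mat": 0}
        assert res.crosstab.to_numpy().sum() == 15

    def test_identical_profiles_deterministic_degenerate(self):
        profiles = pd.DataFrame(np.ones((4, 2)),
                                index=[f"F{i}" for i in range(4)])
        labels = pd.Series(["x", "x", "y", "y"], index=profiles.index)
        r1 = ward_two_clusters(profiles, labels)
        r2 = ward_two_clusters(profiles, labels)
        assert r1.degenerate
        assert (r1.assignment == r2.assignment).all()

    def test_duplicate_ids_rejected(self):
        profiles = pd.DataFrame(np.eye(3), index=["F1", "F1", "F2"])
        with pytest.raises(ValidationError, match="duplicate"):
            ward_two_clusters(profiles, pd.Series(["x", "x", "y"],
                                                  index=profiles.index))


def _two_group_data(rng, n1=20, n2=25, p=4, delta=0.0):
    x = np.vstack([rng.normal(0, 1, size=(n1, p)),
                   rng.normal(delta, 1, size=(n2, p))])
    profiles = pd.DataFrame(x, index=[f"F{i}" for i in range(n1 + n2)])
    labels = pd.Series(["a"] * n1 + ["b"] * n2, index=profiles.index)
    return profiles, labels


class TestDfa:
    def test_wilks_eigenvalue_identity(self, rng):
        profiles, labels = _two_group_data(rng, delta=0.8)
        res = dfa_two_group(profiles, labels)
        assert res.wilks * (1 + res.eigenvalue) == pytest.approx(1.0, abs=1e-10)
        assert 0 < res.wilks <= 1 and res.eigenvalue >= 0
        assert (res.structure_corr.abs() <= 1 + 1e-12).all()

    def test_null_case_flat(self, rng):
        profiles, labels = _two_group_data(rng, n1=200, n2=200, delta=0.0)
        res = dfa_two_group(profiles, labels)
        assert res.eigenvalue < 0.05
        assert res.wilks > 0.95 and res.f < 2.5

    def test_f_equals_hotelling_t2_f(self, rng):
        """The Lambda-based F must equal the two-sample Hotelling T^2 F."""
        profiles, labels = _two_group_data(rng, n1=15, n2=18, p=3, delta=0.7)
        res = dfa_two_group(profiles, labels)
        x = profiles.to_numpy()
        g = labels.to_numpy()
        x1, x2 = x[g == "a"], x[g == "b"]
        n1, n2 = len(x1), len(x2)
        s = ((n1 - 1) * np.cov(x1.T) + (n2 - 1) * np.cov(x2.T)) / (n1 + n2 - 2)
        d = x1.mean(0) - x2.mean(0)
        t2 = (n1 * n2 / (n1 + n2)) * d @ np.linalg.solve(s, d)
        p = 3
        f_ref = (n1 + n2 - p - 1) / ((n1 + n2 - 2) * p) * t2
        assert res.f == pytest.approx(f_ref, abs=1e-8)
        assert res.p == pytest.approx(
            float(f_dist.sf(f_ref, p, n1 + n2 - p - 1)), abs=1e-10)

    def test_f_to_remove_reconstruction_arithmetic(self):
        # with Lambda=0.46, Lambda_without=0.62 and N-p-1=52 the published
        # per-variable F is reproduced within rounding of the inputs
        assert (0.62 / 0.46 - 1) * 52 == pytest.approx(18.36, abs=0.3)

    def test_classification_near_perfect_for_separated_groups(self, rng):
        # Mahalanobis distance 6 between group means
        profiles, labels = _two_group_data(rng, n1=60, n2=60, p=4, delta=3.0)
        res = dfa_two_group(profiles, labels)
        assert res.pct_correct > 99.0
        assert res.classification.to_numpy().sum() == 120

    def test_matches_sklearn_lda_predictions(self, rng):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        profiles, labels = _two_group_data(rng, n1=25, n2=30, p=4, delta=1.0)
        res = dfa_two_group(profiles, labels)
        lda = LinearDiscriminantAnalysis(solver="svd")
        lda.fit(profiles.to_numpy(), labels.to_numpy())
        pred = lda.predict(profiles.to_numpy())
        # compare confusion tables (rule equivalence up to numerics)
        ref = pd.crosstab(labels.to_numpy(), pred)
        assert (res.classification.to_numpy() == ref.to_numpy()).all()

    def test_singular_scatter_rejected(self, rng):
        profiles, labels = _two_group_data(rng, n1=10, n2=10, p=3)
        profiles[3] = 1.0  # constant variable -> zero within-group scatter row
        with pytest.raises(ValidationError, match="singular|collinear"):
            dfa_two_group(profiles, labels)

    def test_too_few_observations_rejected(self, rng):
        profiles, labels = _two_group_data(rng, n1=3, n2=3, p=5)
        with pytest.raises(ValidationError, match="N > p"):
            dfa_two_group(profiles, labels)
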