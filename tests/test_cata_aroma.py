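import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from sourscope.cata_aroma import (
    CataMatrix,
    DistanceMatrix,
    jaccard_matrix,
    mantel,
    numeric_predictor_distance,
    pcoa,
    permanova,
    top_features,
)
from sourscope.errors import (
    InsufficientDataError,
    UndefinedCorrelationError,
)


def cata_from_array(arr, ids=None):
    ids = ids or [f"S{i}" for i in range(len(arr))]
    cols = [f"d{j}" for j in range(np.asarray(arr).shape[1])]
    return CataMatrix(pd.DataFrame(arr, index=ids, columns=cols))


def dist_from_points(points):
    d = squareform(pdist(np.asarray(points, dtype=float)))
    return DistanceMatrix(d, [f"S{i}" for i in range(len(points))])


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_permanova_p(d2, codes, n_groups):
    """Exhaustive permutation p, identity included (independent of the package)."""

    def f_stat(c):
        n = len(c)
        ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
        ss_within = 0.0
        for g in range(n_groups):
            idx = [i for i in range(n) if c[i] == g]
            if len(idx) < 2:
                continue
            ss_within += sum(
                d2[i, j] for i in idx for j in idx if i < j
            ) / len(idx)
        ss_b = ss_total - ss_within
        return (ss_b / (n_groups - 1)) / (ss_within / (n - n_groups))

    f_obs = f_stat(codes)
    perms = list(itertools.permutations(codes))
    hits = sum(1 for p in perms if f_stat(p) >= f_obs - 1e-12)
    return hits / len(perms), f_obs


def brute_force_mantel_p(a, b, method="pearson"):
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr

    def r_of(perm):
        bp = b[np.ix_(perm, perm)]
        return corr(a[iu], bp[iu])[0]

    r_obs = r_of(tuple(range(n)))
    perms = list(itertools.permutations(range(n)))
    hits = sum(1 for p in perms if abs(r_of(p)) >= abs(r_obs) - 1e-12)
    return hits / len(perms), r_obs


# ---------------------------------------------------------------------------


class TestJaccard:
    def test_identical_vectors_zero(self):
        m = jaccard_matrix(cata_from_array([[1, 1, 0], [1, 1, 0]]))
        assert m.values[0, 1] == 0.0

    def test_disjoint_vectors_one(self):
        m = jaccard_matrix(cata_from_array([[1, 0, 0], [0, 1, 1]]))
        assert m.values[0, 1] == 1.0

    def test_hand_set_arithmetic(self):
        # (1,1,0) vs (1,0,1): intersection 1, union 3 -> d = 2/3
        m = jaccard_matrix(cata_from_array([[1, 1, 0], [1, 0, 1]]))
        assert m.values[0, 1] == pytest.approx(2 / 3)

    def test_all_zero_rows_convention(self):
        m = jaccard_matrix(cata_from_array([[0, 0, 0], [0, 0, 0], [1, 0, 1]]))
        assert m.values[0, 1] == 0.0
        assert m.values[0, 2] == 1.0

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            CataMatrix(pd.DataFrame([[0, 2], [1, 0]]))

    def test_matches_scipy(self, rng):
        X = rng.integers(0, 2, size=(15, 20))
        X[0] = 1  # avoid all-zero rows (scipy convention differs there)
        ours = jaccard_matrix(cata_from_array(X)).values
        ref = squareform(pdist(X.astype(bool), metric="jaccard"))
        assert np.allclose(ours, ref)


class TestPcoa:
    def test_equilateral_triangle(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(d, ["a", "b", "c"]))
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])
        assert np.allclose(res.proportion_explained, [0.5, 0.5])

    def test_duplicated_sample_identical_rows(self):
        pts = [[0, 0], [1, 0], [1, 0], [0, 2]]
        res = pcoa(dist_from_points(pts))
        assert np.allclose(res.coordinates.iloc[1], res.coordinates.iloc[2], atol=1e-10)

    def test_collinear_points_single_axis(self):
        pts = [[0.0], [1.0], [3.0], [7.0]]
        res = pcoa(dist_from_points(pts))
        assert res.proportion_explained[0] == pytest.approx(1.0)
        assert res.coordinates.shape[1] == 1

    def test_distance_reconstruction_metric_case(self, rng):
        pts = rng.normal(0, 1, (8, 3))
        dm = dist_from_points(pts)
        res = pcoa(dm)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rec, dm.values, atol=1e-8)

    def test_proportions_sum_to_one(self, rng):
        X = rng.integers(0, 2, size=(12, 10))
        X[:, 0] = 1
        res = pcoa(jaccard_matrix(cata_from_array(X)))
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_negative_eigenvalues_reported_not_corrected(self, rng):
        X = rng.integers(0, 2, size=(20, 6))
        X[0] = 1
        res = pcoa(jaccard_matrix(cata_from_array(X)))
        assert res.negative_eigenvalue_report["n_negative"] >= 0
        assert (res.proportion_explained > 0).all()

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            pcoa(DistanceMatrix(np.zeros((2, 2)), ["a", "b"]))

    def test_matches_scikit_bio(self, rng):
        # metric configuration: no negative eigenvalues, so the variance
        # denominators of both implementations coincide
        from skbio.stats.ordination import pcoa as skbio_pcoa

        dm = dist_from_points(rng.normal(0, 1, (15, 4)))
        ours = pcoa(dm)
        ref = skbio_pcoa(dm.values, number_of_dimensions=2)
        assert abs(ours.proportion_explained[0] - ref.proportion_explained.iloc[0]) < 1e-8
        assert abs(abs(ours.coordinates.iloc[0, 0]) - abs(ref.samples.iloc[0, 0])) < 1e-6


class TestPermanova:
    def test_two_blobs_max_separation(self, rng):
        pts = np.vstack([rng.normal(0, 0.05, (6, 2)), rng.normal(10, 0.05, (6, 2))])
        dm = dist_from_points(pts)
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=dm.ids)
        f, r2, p = permanova(dm, groups, n_perm=199, seed=1)
        assert r2 > 0.9
        assert p == pytest.approx(1 / 200)

    def test_exact_matches_brute_force(self, rng):
        pts = rng.normal(0, 1, (6, 2))
        dm = dist_from_points(pts)
        groups = pd.Series(["a", "a", "a", "b", "b", "b"], index=dm.ids)
        f, r2, p = permanova(dm, groups, n_perm="exact")
        codes = tuple(0 if g == "a" else 1 for g in groups)
        p_ref, f_ref = brute_force_permanova_p(dm.values**2, codes, 2)
        assert f == pytest.approx(f_ref)
        assert p == pytest.approx(p_ref)

    def test_label_renaming_invariance(self, rng):
        pts = rng.normal(0, 1, (8, 2))
        dm = dist_from_points(pts)
        g1 = pd.Series(["a"] * 4 + ["b"] * 4, index=dm.ids)
        g2 = g1.map({"a": "zebra", "b": "ant"})
        r1 = permanova(dm, g1, n_perm=99, seed=5)
        r2 = permanova(dm, g2, n_perm=99, seed=5)
        assert r1[0] == pytest.approx(r2[0])
        assert r1[2] == pytest.approx(r2[2])

    def test_small_levels_dropped_then_skip(self, rng):
        pts = rng.normal(0, 1, (6, 2))
        dm = dist_from_points(pts)
        groups = pd.Series(["a", "a", "a", "a", "b", "b"], index=dm.ids)
        assert permanova(dm, groups, n_perm=99, min_level_size=3) is None

    def test_null_p_roughly_uniform(self, rng):
        pts = rng.normal(0, 1, (12, 2))
        dm = dist_from_points(pts)
        ps = []
        for rep in range(60):
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            groups = pd.Series(labels, index=dm.ids)
            ps.append(permanova(dm, groups, n_perm=99, seed=rep)[2])
        assert 0.2 < np.mean(ps) < 0.8

    def test_matches_scikit_bio(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        pts = rng.normal(0, 1, (12, 3))
        pts[6:] += 1.5
        dm = dist_from_points(pts)
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=dm.ids)
        ours = permanova(dm, groups, n_perm=999, seed=0)
        ref = skbio_permanova(SkbioDM(dm.values, ids=dm.ids), groups.to_numpy(),
                              permutations=999)
        assert ours[0] == pytest.approx(ref["test statistic"], rel=1e-9)
        assert abs(ours[2] - ref["p-value"]) < 0.06


class TestMantel:
    def test_self_correlation_one(self, rng):
        pts = rng.normal(0, 1, (6, 2))
        dm = dist_from_points(pts)
        for method in ("pearson", "spearman"):
            r, _ = mantel(dm, dm, method, n_perm=49, seed=0)
            assert r == pytest.approx(1.0)

    def test_affine_transform_pearson_one(self, rng):
        pts = rng.normal(0, 1, (6, 2))
        dm = dist_from_points(pts)
        dm2 = DistanceMatrix(2.5 * dm.values, dm.ids)
        r, _ = mantel(dm, dm2, "pearson", n_perm=49, seed=0)
        assert r == pytest.approx(1.0)

    def test_exact_matches_brute_force(self, rng):
        a = dist_from_points(rng.normal(0, 1, (5, 2)))
        b = dist_from_points(rng.normal(0, 1, (5, 2)))
        for method in ("pearson", "spearman"):
            r, p = mantel(a, b, method, n_perm="exact")
            p_ref, r_ref = brute_force_mantel_p(a.values, b.values, method)
            assert r == pytest.approx(r_ref)
            assert p == pytest.approx(p_ref)

    def test_zero_variance_error(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        dm = DistanceMatrix(d, ["a", "b", "c"])
        with pytest.raises(UndefinedCorrelationError):
            mantel(dm, dm, "pearson", n_perm=9)

    def test_dynamic_sample_exclusion(self, rng):
        pts = rng.normal(0, 1, (6, 2))
        dm = dist_from_points(pts)
        vals = pd.Series([1.0, 2.0, np.nan, 4.0, 2.5, 0.5], index=dm.ids)
        pdm = numeric_predictor_distance(vals)
        assert len(pdm.ids) == 5
        r, p = mantel(dm, pdm, "pearson", n_perm=99, seed=0)
        assert np.isfinite(r)

    def test_matches_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        a = dist_from_points(rng.normal(0, 1, (10, 2)))
        b = dist_from_points(rng.normal(0, 1, (10, 2)))
        r_ours, _ = mantel(a, b, "pearson", n_perm=99, seed=0)
        r_ref, _, _ = skbio_mantel(SkbioDM(a.values), SkbioDM(b.values),
                                   method="pearson", permutations=0)
        assert r_ours == pytest.approx(r_ref)


class TestTopFeatures:
    def test_constructed_descriptor_ranked_first(self, rng):
        n = 30
        X = rng.integers(0, 2, size=(n, 8))
        cata = cata_from_array(X)
        dm = jaccard_matrix(cata)
        res = pcoa(dm)
        # plant a descriptor that follows the sign of PC1
        planted = (res.coordinates["PC1"].to_numpy() > 0).astype(int)
        X2 = np.column_stack([X, planted])
        cata2 = cata_from_array(X2)
        ranked = top_features(cata2, res, k=3)
        assert ranked.iloc[0]["descriptor"] == "d8"

    def test_constant_descriptor_excluded(self, rng):
        X = rng.integers(0, 2, size=(12, 5))
        X[:, 2] = 1
        cata = cata_from_array(X)
        res = pcoa(jaccard_matrix(cata))
        ranked = top_features(cata, res, k=10)
        assert "d2" not in set(ranked["descriptor"])

    def test_k_validated(self, rng):
        X = rng.integers(0, 2, size=(10, 4))
        cata = cata_from_array(X)
        res = pcoa(jaccard_matrix(cata))
        with pytest.raises(ValueError):
            top_features(cata, res, k=0)

    def test_recovery_of_planted_sour_rye(self):
        """Planted sour-cluster/rye association surfaces in the top-10 descriptors."""
        from sourscope.cli_report import build_cata_matrix
        from sourscope.harmonize import integrate
        from sourscope.synthetic_data import GeneratorConfig, PlantedEffect, generate_study

        effects = [
            PlantedEffect("aroma_association", d, "grain_base", "rye", 0.55)
            for d in ("sour", "vinegar", "lactic acid", "tangy")
        ]
        cfg = GeneratorConfig(n_participants=400, seed=21, effect_registry=effects,
                              aroma_prevalence_range=(0.05, 0.25))
        reg, res, lab, _ = generate_study(cfg)
        table = integrate(reg, res, lab).data
        cata = build_cata_matrix(table)
        dm = jaccard_matrix(cata)
        ordn = pcoa(dm)
        ranked = top_features(cata, ordn, k=10)
        assert "sour" in set(ranked["descriptor"])
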