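"""glog transform, PCA, clustering, Kruskal-Wallis/Dunn and correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phycofa.stats_multivariate import (
    GlogTransformer,
    assign_letters,
    correlate,
    glog,
    glog_transform,
    hierarchical_clustering,
    is_monophyletic,
    kruskal_dunn,
    letters_to_pairs,
    run_pca,
    to_newick,
)


# ---------------------------------------------------------------------------
# glog


class TestGlog:
    def test_zero_maps_to_minus_one_at_unit_lambda(self):
        assert glog(0.0, 1.0) == pytest.approx(-1.0)

    def test_approaches_log2_for_large_values(self):
        x = np.array([100.0, 500.0, 1e4])
        rel = np.abs(glog(x, 1.0) - np.log2(x)) / np.abs(np.log2(x))
        assert (rel < 1e-3).all()

    def test_strictly_increasing(self):
        x = np.linspace(0, 50, 400)
        assert (np.diff(glog(x, 0.3)) > 0).all()

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            glog(1.0, 0.0)

    def test_default_lambda_is_smallest_positive(self):
        df = pd.DataFrame([[0.0, 0.4], [2.0, 5.0]])
        assert glog_transform(df).lam == 0.4

    def test_sklearn_transformer(self):
        X = np.array([[0.0, 1.0], [3.0, 9.0]])
        tr = GlogTransformer().fit(X)
        assert tr.lam_ == 1.0
        assert tr.transform(X) == pytest.approx(glog(X, 1.0))


# ---------------------------------------------------------------------------
# PCA


def random_matrix(seed, n=5, p=4):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"f{j}" for j in range(p)],
    )


class TestPca:
    def test_variance_fractions_sum_to_one(self):
        res = run_pca(random_matrix(0))
        assert res.variance_fraction.sum() == pytest.approx(1.0)
        assert (np.diff(res.variance_fraction) <= 1e-12).all()  # non-increasing

    def test_rank_one_data_loads_on_single_component(self):
        u = np.outer([1.0, 2.0, 3.0, 4.0], [0.5, -1.0, 2.0])
        df = pd.DataFrame(u)
        res = run_pca(df)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_matches_covariance_eigenvalue_oracle(self):
        df = random_matrix(42)
        res = run_pca(df)
        eigvals = np.linalg.eigvalsh(np.cov(df.to_numpy(), rowvar=False))[::-1]
        eigvals = eigvals[: len(res.variance_fraction)]
        assert res.variance_fraction == pytest.approx(
            eigvals / eigvals.sum(), abs=1e-12
        )

    def test_row_permutation_leaves_fractions_unchanged(self):
        df = random_matrix(7)
        res1 = run_pca(df)
        res2 = run_pca(df.iloc[::-1])
        assert res1.variance_fraction == pytest.approx(res2.variance_fraction)

    def test_sign_convention_largest_loading_positive(self):
        res = run_pca(random_matrix(3))
        for comp in res.loadings.columns:
            v = res.loadings[comp].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_degenerate_matrix_yields_no_components(self):
        df = pd.DataFrame(np.ones((4, 3)))
        res = run_pca(df)
        assert len(res.variance_fraction) == 0


# ---------------------------------------------------------------------------
# clustering


class TestClustering:
    def test_identical_leaves_merge_at_zero_height(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]], index=list("abc"))
        tree = hierarchical_clustering(df)
        assert tree.linkage[0, 2] == pytest.approx(0.0)

    def test_duplicated_rows_have_all_zero_heights(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]] * 4, index=list("abcd"))
        tree = hierarchical_clustering(df)
        assert tree.linkage[:, 2] == pytest.approx(np.zeros(3))

    def test_heights_nondecreasing(self):
        tree = hierarchical_clustering(random_matrix(5, n=8))
        assert (np.diff(tree.linkage[:, 2]) >= -1e-12).all()

    def test_monophyly_detection(self):
        df = pd.DataFrame(
            [[0.0], [0.1], [5.0], [5.1]], index=["a1", "a2", "b1", "b2"]
        )
        tree = hierarchical_clustering(df)
        assert is_monophyletic(tree, ["a1", "a2"])
        assert is_monophyletic(tree, ["b1", "b2"])
        assert not is_monophyletic(tree, ["a1", "b1"])

    def test_newick_contains_all_leaves_and_balanced_parens(self):
        df = random_matrix(11, n=6)
        tree = hierarchical_clustering(df)
        nwk = to_newick(tree)
        assert nwk.endswith(";")
        assert nwk.count("(") == nwk.count(")") == 5
        for leaf in df.index:
            assert leaf in nwk


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn


def _dunn_oracle(groups):
    """Hand-computed mean ranks and Dunn z, written independently."""
    names = list(groups)
    pooled = sorted(
        (v, g) for g in names for v in groups[g]
    )
    # average ranks with ties
    values = [v for v, _ in pooled]
    ranks = []
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and values[j] == values[i]:
            j += 1
        avg = (i + 1 + j) / 2.0
        ranks.extend([avg] * (j - i))
        i = j
    rank_by_group = {g: [] for g in names}
    for (v, g), r in zip(pooled, ranks):
        rank_by_group[g].append(r)
    n_total = len(values)
    # tie correction
    tie = 0.0
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and values[j] == values[i]:
            j += 1
        t = j - i
        tie += t**3 - t
        i = j
    var = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    out = {}
    for g1, g2 in itertools.combinations(names, 2):
        m1 = sum(rank_by_group[g1]) / len(rank_by_group[g1])
        m2 = sum(rank_by_group[g2]) / len(rank_by_group[g2])
        se = (var * (1 / len(groups[g1]) + 1 / len(groups[g2]))) ** 0.5
        out[(g1, g2)] = (m1 - m2) / se
    return out


class TestKruskalDunn:
    def test_identical_groups_nothing_significant(self):
        groups = {g: [1.0, 2.0, 3.0] for g in "abcd"}
        comp = kruskal_dunn(groups)
        assert (comp.pairwise["q"] >= 0.05).all()
        assert all(v == "" for v in comp.letters.values())

    def test_dunn_z_matches_bruteforce_oracle(self):
        groups = {
            "a": [1.2, 3.4, 2.2],
            "b": [5.1, 4.4, 6.0],
            "c": [2.2, 2.9, 8.8],  # includes a tie with group a
        }
        comp = kruskal_dunn(groups)
        oracle = _dunn_oracle(groups)
        for row in comp.pairwise.itertuples():
            assert row.z == pytest.approx(oracle[(row.group1, row.group2)], abs=1e-10)

    def test_dunn_z_antisymmetric(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}
        z_ab = kruskal_dunn(groups).pairwise.iloc[0]["z"]
        z_ba = kruskal_dunn(dict(reversed(groups.items()))).pairwise.iloc[0]["z"]
        assert z_ab == pytest.approx(-z_ba)

    def test_bh_adjustment_monotone_in_p(self):
        rng = np.random.default_rng(0)
        groups = {f"g{i}": rng.normal(i * 0.5, 1.0, 6) for i in range(5)}
        pw = kruskal_dunn(groups).pairwise.sort_values("p_raw")
        assert (np.diff(pw["q"]) >= -1e-12).all()
        assert (pw["q"] >= pw["p_raw"] - 1e-12).all()

    def test_multiplicity_control_under_the_null(self):
        # 7 groups of n=5 from one null distribution: raw p yields many
        # false-positive runs, BH q far fewer
        rng = np.random.default_rng(123)
        raw_hits = q_hits = 0
        n_rep = 500
        for _ in range(n_rep):
            groups = {f"g{i}": rng.normal(0.0, 1.0, 5) for i in range(7)}
            pw = kruskal_dunn(groups).pairwise
            raw_hits += (pw["p_raw"] < 0.05).any()
            q_hits += (pw["q"] < 0.05).any()
        assert raw_hits > 3 * max(q_hits, 1)

    def test_small_group_excluded_with_warning(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0], "c": [9.0]}
        with pytest.warns(UserWarning, match="excluding"):
            comp = kruskal_dunn(groups)
        pairs = set(zip(comp.pairwise["group1"], comp.pairwise["group2"]))
        assert pairs == {("a", "b")}


class TestLetters:
    def test_shared_letter_marks_significant_pair(self):
        letters = assign_letters([("a", "b"), ("a", "c")], ["a", "b", "c", "d"])
        assert letters_to_pairs(letters) == {("a", "b"), ("a", "c")}
        assert letters["d"] == ""

    def test_roundtrip_random_pair_sets(self):
        rng = np.random.default_rng(5)
        names = list("abcdefg")
        all_pairs = list(itertools.combinations(names, 2))
        for _ in range(20):
            k = rng.integers(0, len(all_pairs) + 1)
            chosen = {all_pairs[i] for i in rng.choice(len(all_pairs), k, replace=False)}
            letters = assign_letters(sorted(chosen), names)
            assert letters_to_pairs(letters) == chosen

    def test_symmetry(self):
        letters = assign_letters([("a", "b")], ["a", "b"])
        assert set(letters["a"]) & set(letters["b"])


# ---------------------------------------------------------------------------
# correlation


class TestCorrelate:
    def test_perfect_linear_relation(self):
        x = np.arange(1.0, 8.0)
        res = correlate(x, 2 * x + 1)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_antimonotone_rank_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = np.exp(-x)
        assert correlate(x, y).spearman_rho == pytest.approx(-1.0)

    def test_zero_variance_absent(self):
        res = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.pearson_r is None and res.spearman_rho is None

    def test_exact_permutation_p_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=7)
        y = 0.8 * x + rng.normal(scale=0.6, size=7)
        res = correlate(x, y)
        assert res.spearman_p_method == "exact-permutation"
        # independent Monte-Carlo permutation oracle
        obs = abs(sps.spearmanr(x, y).statistic)
        n_mc = 4000
        hits = 0
        for _ in range(n_mc):
            perm = rng.permutation(len(y))
            if abs(sps.spearmanr(x, y[perm]).statistic) >= obs - 1e-12:
                hits += 1
        mc_p = hits / n_mc
        se = (mc_p * (1 - mc_p) / n_mc) ** 0.5
        assert res.spearman_p == pytest.approx(mc_p, abs=max(4 * se, 0.01))
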