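import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phylogan.datamodel import AbundanceTable
from phylogan.io import lineage_to_tree
from phylogan.metrics import (clr, compare, filter_taxa, nmds, phi_matrix,
                              proportionality_phi, shannon, sparsity,
                              spearman_structure, top_abundant,
                              unifrac_matrix, unweighted_unifrac)

from tests.conftest import random_composition, random_tree


def _table(vals, taxa=None, normalized=False):
    vals = np.atleast_2d(np.asarray(vals, float))
    taxa = taxa or [f"k__K|p__P|s__sp{j}" for j in range(vals.shape[1])]
    return AbundanceTable([f"s{i}" for i in range(vals.shape[0])], taxa, vals,
                          normalized=normalized)


def brute_force_unifrac(pres_a, pres_b, tree):
    """Enumerate every branch and classify it by descendant presence.

    A sample with no present taxa makes the distance undefined (nan),
    matching the flagged-missing contract of the implementation.
    """
    if not pres_a or not pres_b:
        return float("nan")
    unique = observed = 0.0
    for node in tree.preorder():
        if node == tree.root:
            continue
        leaves = set(tree.descendant_leaves(node))
        in_a = bool(leaves & pres_a)
        in_b = bool(leaves & pres_b)
        length = tree.branch_length(node)
        if in_a or in_b:
            observed += length
            if in_a != in_b:
                unique += length
    return unique / observed if observed else float("nan")


class TestSparsity:
    @pytest.mark.parametrize("row,threshold,expected", [
        ([0.5, 0.5, 0, 0], 1e-4, 0.5),
        ([0.99995, 5e-5, 0], 1e-4, 2 / 3),
        ([0, 0, 0], 1e-4, 1.0),
    ])
    def test_fraction_of_thresholded_zeros(self, row, threshold, expected):
        assert sparsity(_table(row), threshold)[0] == pytest.approx(expected)

    def test_matches_naive_counting_on_random_tables(self, rng):
        vals = random_composition(rng, 10, 20)
        got = sparsity(_table(vals), 1e-4)
        naive = [sum(1 for v in row if v < 1e-4) / 20 for row in vals]
        assert np.allclose(got, naive)


class TestShannon:
    def test_uniform_composition_attains_log_p(self):
        assert shannon(_table([0.25] * 4))[0] == pytest.approx(np.log(4))

    def test_single_taxon_has_zero_entropy(self):
        assert shannon(_table([1.0, 0.0, 0.0]))[0] == 0.0

    def test_closed_form_mixed_composition(self):
        got = shannon(_table([0.5, 0.25, 0.25]))[0]
        assert got == pytest.approx(1.0397, abs=1e-4)

    def test_unnormalized_rows_renormalized_over_nonzero(self):
        assert shannon(_table([0.2, 0.2, 0.0]))[0] == pytest.approx(np.log(2))

    def test_all_zero_row_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert shannon(_table([0.0, 0.0]))[0] == 0.0

    def test_uniform_maximizes_among_same_support(self, rng):
        p = 6
        uniform = shannon(_table([1 / p] * p))[0]
        for _ in range(20):
            assert shannon(_table(rng.dirichlet(np.ones(p))))[0] <= uniform + 1e-12


class TestUnweightedUnifrac:
    @pytest.fixture
    def four_leaf(self, tmp_path):
        from phylogan.io import read_newick
        p = tmp_path / "t.nwk"
        p.write_text("((a:1,b:1):1,(c:1,d:1):1);\n")
        return read_newick(p)

    def test_identical_presence_sets_give_zero(self, four_leaf):
        a = np.array([0.5, 0.5, 0.0, 0.0])
        assert unweighted_unifrac(a, a, list("abcd"), four_leaf) == 0.0

    def test_disjoint_subtrees_give_one(self, four_leaf):
        a = np.array([0.5, 0.5, 0.0, 0.0])
        b = np.array([0.0, 0.0, 0.5, 0.5])
        assert unweighted_unifrac(a, b, list("abcd"), four_leaf) == 1.0

    def test_partial_overlap_matches_branch_classification(self, four_leaf):
        # A={a,b}, B={a,c}: unique branches b, c and the (c,d) stem;
        # observed adds a and the (a,b) stem -> 3/5
        a = np.array([0.5, 0.5, 0.0, 0.0])
        b = np.array([0.5, 0.0, 0.5, 0.0])
        got = unweighted_unifrac(a, b, list("abcd"), four_leaf)
        assert got == pytest.approx(
            brute_force_unifrac({"a", "b"}, {"a", "c"}, four_leaf))
        assert got == pytest.approx(0.6)

    def test_agrees_with_brute_force_on_random_trees(self, rng):
        for _ in range(50):
            tree = random_tree(rng, max_leaves=10)
            leaves = tree.leaves()
            a = rng.uniform(size=len(leaves)) * (rng.uniform(size=len(leaves)) > 0.4)
            b = rng.uniform(size=len(leaves)) * (rng.uniform(size=len(leaves)) > 0.4)
            got = unweighted_unifrac(a, b, leaves, tree)
            want = brute_force_unifrac(
                {l for l, v in zip(leaves, a) if v > 1e-4},
                {l for l, v in zip(leaves, b) if v > 1e-4}, tree)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_agrees_with_skbio(self, rng):
        import io as _io
        from skbio import TreeNode
        from skbio.diversity.beta import unweighted_unifrac as sk_unifrac
        from phylogan.fixtures import make_taxonomy

        lineages, tree = make_taxonomy(10, 2)

        def to_newick(node, is_root=False):
            ch = tree.children.get(node, [])
            bl = "0" if is_root else "1"
            if ch:
                inner = ",".join(to_newick(c) for c in ch)
                return f"({inner})'{node}':{bl}"
            return f"'{node}':{bl}"

        sk = TreeNode.read(_io.StringIO(to_newick(tree.root, True) + ";"))
        for _ in range(10):
            a = (rng.uniform(size=10) > 0.5) * rng.uniform(0.1, 1, 10)
            b = (rng.uniform(size=10) > 0.5) * rng.uniform(0.1, 1, 10)
            if not a.any() or not b.any():
                continue
            mine = unweighted_unifrac(a, b, lineages, tree)
            theirs = sk_unifrac((a > 1e-4).astype(int), (b > 1e-4).astype(int),
                                lineages, sk)
            assert mine == pytest.approx(float(theirs), abs=1e-12)

    def test_matrix_is_symmetric_zero_diagonal_in_unit_range(self, rng):
        tree = random_tree(rng, max_leaves=8)
        leaves = tree.leaves()
        vals = random_composition(rng, 12, len(leaves))
        D = unifrac_matrix(vals, leaves, tree)
        ok = ~np.isnan(D)
        assert np.allclose(D[ok], np.clip(D[ok], 0, 1))
        assert np.allclose(D, D.T, equal_nan=True)
        assert np.all((np.diag(D) == 0) | np.isnan(np.diag(D)))

    def test_sample_with_no_present_taxa_flagged_missing(self, four_leaf):
        a = np.zeros(4)
        b = np.array([0.5, 0.5, 0.0, 0.0])
        assert np.isnan(unweighted_unifrac(a, b, list("abcd"), four_leaf))


class TestNmds:
    def test_three_equidistant_points_embed_as_equilateral(self):
        D = np.ones((3, 3)) - np.eye(3)
        coords, _ = nmds(D, seed=0)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        off = d[np.triu_indices(3, 1)]
        assert np.max(off) - np.min(off) < 1e-3

    def test_planar_euclidean_distances_embed_with_near_zero_stress(self, rng):
        X = rng.standard_normal((15, 2))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        _, stress = nmds(D, seed=0)
        assert stress < 0.01

    def test_seeded_run_reproducible(self, rng):
        X = rng.standard_normal((10, 3))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        c1, s1 = nmds(D, seed=4)
        c2, s2 = nmds(D, seed=4)
        assert np.array_equal(c1, c2) and s1 == s2

    def test_non_symmetric_input_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            nmds(D)


class TestFiltering:
    def test_taxon_with_excess_zeros_dropped(self):
        vals = np.zeros((20, 2))
        vals[:, 0] = 0.5
        vals[0, 1] = 0.5  # zero in 95% of samples
        t = filter_taxa(_table(vals), max_zero_fraction=0.9)
        assert t.n_taxa == 1

    def test_fraction_one_keeps_everything(self, rng):
        t = _table(random_composition(rng, 5, 8))
        assert top_abundant(t, fraction=1.0).taxon_ids == t.taxon_ids

    def test_top_abundant_matches_brute_force_sort(self, rng):
        vals = random_composition(rng, 15, 20)
        t = _table(vals)
        kept = top_abundant(t, fraction=0.1).taxon_ids
        means = vals.mean(axis=0)
        want = {t.taxon_ids[j] for j in
                sorted(range(20), key=lambda j: (-means[j], t.taxon_ids[j]))[:2]}
        assert set(kept) == want
        assert kept == [tx for tx in t.taxon_ids if tx in want]

    def test_empty_result_rejected(self):
        vals = np.zeros((10, 2))
        with pytest.raises(ValueError, match="retained"):
            filter_taxa(_table(vals), max_zero_fraction=0.5)


class TestSpearmanStructure:
    def test_table_against_itself_is_perfect(self, rng):
        t = _table(random_composition(rng, 30, 6))
        out = spearman_structure(t, t)
        assert out["r2"] == pytest.approx(1.0)
        assert out["mse"] == pytest.approx(0.0, abs=1e-15)

    def test_shuffled_columns_degrade_agreement(self, rng):
        vals = random_composition(rng, 60, 6)
        shuffled = vals.copy()
        for j in range(6):
            rng.shuffle(shuffled[:, j])
        out = spearman_structure(_table(vals), _table(shuffled))
        assert out["r2"] < 1.0

    def test_pairs_match_naive_rank_correlation(self, rng):
        vals = random_composition(rng, 25, 5)
        sim = random_composition(rng, 25, 5)
        out = spearman_structure(_table(vals), _table(sim))
        naive = []
        for a in range(5):
            for b in range(a + 1, 5):
                ra = stats.rankdata(vals[:, a])
                rb = stats.rankdata(vals[:, b])
                naive.append(np.corrcoef(ra, rb)[0, 1])
        assert np.allclose(out["real_pairs"], naive, atol=1e-9)

    def test_constant_taxon_pairs_flagged_and_excluded(self, rng):
        vals = random_composition(rng, 20, 4)
        vals[:, 0] = 0.0
        out = spearman_structure(_table(vals), _table(vals))
        assert out["n_dropped_pairs"] == 3


class TestClr:
    def test_equal_composition_maps_to_zero_vector(self):
        assert np.allclose(clr(np.array([0.25, 0.25, 0.25, 0.25])), 0.0)

    def test_two_part_closed_form(self):
        got = clr(np.array([0.2, 0.8]))
        assert np.allclose(got, [-np.log(2), np.log(2)], atol=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0),
                    min_size=2, max_size=10))
    def test_components_sum_to_zero(self, row):
        assert abs(clr(np.array(row)).sum()) < 1e-9

    def test_zeros_replaced_by_half_minimum_positive(self):
        got = clr(np.array([0.0, 0.4, 0.6]))
        want = np.log([0.2, 0.4, 0.6])
        want = want - want.mean()
        assert np.allclose(got, want)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            clr(np.zeros(3))


class TestProportionality:
    def test_identical_taxa_give_zero(self, rng):
        x = rng.lognormal(size=50)
        v = clr(np.column_stack([x, x, rng.lognormal(size=50)]))
        assert proportionality_phi(v[:, 0], v[:, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_multiple_gives_zero_after_clr(self, rng):
        x = rng.lognormal(size=50)
        comp = np.column_stack([x, 2 * x, rng.lognormal(size=50)])
        v = clr(comp / comp.sum(axis=1, keepdims=True))
        assert proportionality_phi(v[:, 0], v[:, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_variance_ratio(self, rng):
        v = clr(rng.lognormal(size=(1000, 4)))
        got = proportionality_phi(v[:, 0], v[:, 1])
        want = np.var(v[:, 0] - v[:, 1], ddof=1) / np.var(v[:, 0], ddof=1)
        assert got == pytest.approx(want, abs=1e-9)

    def test_phi_matrix_consistent_with_pairwise(self, rng):
        v = clr(rng.lognormal(size=(30, 4)))
        M = phi_matrix(v)
        assert M[1, 2] == pytest.approx(proportionality_phi(v[:, 1], v[:, 2]))
        assert np.allclose(np.diag(M), 0.0, atol=1e-12)

    def test_constant_denominator_flagged(self):
        assert np.isnan(proportionality_phi(np.ones(10), np.arange(10.0)))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            proportionality_phi(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestCompare:
    def test_real_against_itself_has_ranksum_p_one(self, small_fixture):
        _, table, tree, _ = small_fixture
        report = compare(table, {"self": table}, tree)
        assert report.sections["shannon"]["self"]["ranksum_p"] == pytest.approx(1.0)

    def test_all_sections_present_for_each_simulator(self, small_fixture, rng):
        _, table, tree, _ = small_fixture
        sim = _table(random_composition(rng, 30, table.n_taxa),
                     taxa=table.taxon_ids)
        report = compare(table, {"a": sim, "b": sim}, tree)
        for section in ("sparsity", "shannon", "stratified_abundance",
                        "taxa_subset", "unifrac"):
            assert section in report.sections
        for name in ("a", "b"):
            assert name in report.sections["sparsity"]
            assert name in report.sections["shannon"]

    def test_missing_tree_skips_unifrac_with_notice(self, small_fixture):
        _, table, _, _ = small_fixture
        report = compare(table, {"self": table}, tree=None)
        assert "skipped" in report.sections["unifrac"]

    def test_report_json_is_deterministic_under_fixed_seed(self, small_fixture, rng):
        _, table, tree, _ = small_fixture
        sim = _table(random_composition(rng, 25, table.n_taxa),
                     taxa=table.taxon_ids)
        j1 = compare(table, {"sim": sim}, tree, nmds_seed=5).to_json()
        j2 = compare(table, {"sim": sim}, tree, nmds_seed=5).to_json()
        assert j1 == j2
        json.loads(j1)  # valid JSON
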