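import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import ventbiogeo as vb
from ventbiogeo.mrt import (
    ConstantResponseError,
    HellingerMatrix,
    TreeControl,
    cross_validate,
    grow_tree,
    prune,
)

from conftest import assert_tree_splits_optimal


def make_response(values, site_ids=None, species_ids=None):
    values = np.asarray(values, dtype=float)
    return HellingerMatrix(
        site_ids=site_ids or [f"s{i}" for i in range(values.shape[0])],
        species_ids=species_ids or [f"sp{j}" for j in range(values.shape[1])],
        values=values,
    )


def constraints_for(response, columns):
    return pd.DataFrame(columns, index=response.site_ids)


class TestHellinger:
    def test_binary_row(self):
        occ = np.zeros((1, 10))
        occ[0, :4] = 1
        m = vb.CommunityMatrix(["s1"], [f"sp{j}" for j in range(10)], occ)
        h = vb.hellinger(m)
        np.testing.assert_allclose(h.values[0, :4], 0.5)
        np.testing.assert_allclose(h.values[0, 4:], 0.0)

    def test_abundance_row(self):
        m = vb.CommunityMatrix(["s1"], ["a", "b", "c"], np.array([[1.0, 3.0, 0.0]]))
        h = vb.hellinger(m)
        np.testing.assert_allclose(h.values[0], [0.5, np.sqrt(0.75), 0.0])

    def test_zero_row_warns_and_stays_zero(self):
        with pytest.warns(UserWarning):
            m = vb.CommunityMatrix(["s1", "s2"], ["a"], np.array([[1.0], [0.0]]))
        with pytest.warns(UserWarning, match="s2"):
            h = vb.hellinger(m)
        assert h.values[1, 0] == 0.0
        assert h.zero_rows == ["s2"]

    def test_unit_row_norms(self, strong_meta):
        h = vb.hellinger(strong_meta.matrix)
        np.testing.assert_allclose((h.values**2).sum(axis=1), 1.0, atol=1e-12)
        assert (h.values >= 0).all() and (h.values <= 1).all()


class TestGrowTree:
    def test_constant_response_single_leaf(self):
        resp = make_response(np.ones((4, 3)))
        tree = grow_tree(resp, constraints_for(resp, {"x": [0.0, 1, 2, 3]}))
        assert tree.is_leaf
        assert tree.within_ss == 0.0

    def test_four_site_perfect_split(self):
        resp = make_response([[1, 0], [1, 0], [0, 1], [0, 1]])
        tree = grow_tree(resp, constraints_for(resp, {"x": [0.0, 1, 10, 11]}))
        assert tree.split_threshold == 5.5
        assert tree.left.within_ss == 0.0
        assert tree.right.within_ss == 0.0
        assert sorted(tree.left.members) == [0, 1]

    def test_first_split_matches_brute_force(self):
        rng = np.random.default_rng(42)
        for seed in range(5):
            resp = make_response(np.random.default_rng(seed).integers(0, 2, (6, 4)))
            X = constraints_for(resp, {"x": rng.normal(size=6), "y": rng.normal(size=6)})
            tree = grow_tree(resp, X, TreeControl(min_node_size=1))
            assert_tree_splits_optimal(tree, resp.values, X.to_numpy(), min_node_size=1)

    def test_misaligned_rows(self):
        resp = make_response([[1, 0], [0, 1]])
        bad = pd.DataFrame({"x": [0.0, 1]}, index=["other1", "other2"])
        with pytest.raises(ValueError, match="different sites"):
            grow_tree(resp, bad)

    def test_identical_constraints_single_leaf_with_warning(self):
        resp = make_response([[1, 0], [0, 1], [1, 0]])
        X = constraints_for(resp, {"x": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="identical"):
            tree = grow_tree(resp, X)
        assert tree.is_leaf

    def test_max_leaves_cap(self, strong_meta):
        resp = vb.hellinger(strong_meta.matrix)
        X = vb.build_constraints(strong_meta.sites)
        tree = grow_tree(resp, X, TreeControl(max_leaves=3))
        assert tree.n_leaves() == 3

    def test_min_node_size_respected(self, strong_meta):
        resp = vb.hellinger(strong_meta.matrix)
        X = vb.build_constraints(strong_meta.sites)
        tree = grow_tree(resp, X, TreeControl(min_node_size=4))
        assert min(len(leaf.members) for leaf in tree.leaves()) >= 4


class TestPrune:
    def test_single_leaf_sequence(self):
        resp = make_response(np.ones((3, 2)))
        tree = grow_tree(resp, constraints_for(resp, {"x": [0.0, 1, 2]}))
        seq = prune(tree)
        assert len(seq.entries) == 1
        assert seq.entries[0].rel_error == 1.0

    def test_four_site_sequence(self):
        resp = make_response([[1, 0], [1, 0], [0, 1], [0, 1]])
        tree = grow_tree(resp, constraints_for(resp, {"x": [0.0, 1, 10, 11]}))
        seq = prune(tree)
        assert [e.n_leaves for e in seq.entries] == [2, 1]
        assert seq.entries[0].rel_error == pytest.approx(0.0)
        assert seq.entries[-1].rel_error == pytest.approx(1.0)
        # alpha of the collapse equals the SS the split removed
        assert seq.entries[1].alpha == pytest.approx(tree.within_ss)

    def test_monotone_structure(self, strong_meta):
        resp = vb.hellinger(strong_meta.matrix)
        X = vb.build_constraints(strong_meta.sites)
        seq = prune(grow_tree(resp, X))
        leaves = [e.n_leaves for e in seq.entries]
        alphas = [e.alpha for e in seq.entries]
        errors = [e.rel_error for e in seq.entries]
        assert all(a < b for a, b in zip(leaves[1:], leaves[:-1]))
        assert all(a < b for a, b in zip(alphas[:-1], alphas[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(errors[:-1], errors[1:]))
        assert leaves[-1] == 1 and errors[-1] == pytest.approx(1.0)

    def test_variance_decomposition(self, strong_meta):
        resp = vb.hellinger(strong_meta.matrix)
        X = vb.build_constraints(strong_meta.sites)
        seq = prune(grow_tree(resp, X))
        Y = resp.values
        grand = Y.mean(axis=0)
        for entry in seq.entries:
            between = sum(
                len(leaf.members) * float(((leaf.centroid - grand) ** 2).sum())
                for leaf in entry.root.leaves()
            )
            within = entry.root.leaf_within_ss()
            assert between + within == pytest.approx(seq.root_ss, rel=1e-9)


class TestCrossValidate:
    def test_constant_response_guarded(self):
        resp = make_response(np.ones((6, 2)))
        X = constraints_for(resp, {"x": np.arange(6.0)})
        with pytest.raises(ConstantResponseError):
            cross_validate(resp, X, folds=3, seed=0)

    def test_too_many_folds(self, strong_meta):
        resp = vb.hellinger(strong_meta.matrix)
        X = vb.build_constraints(strong_meta.sites)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(resp, X, folds=100, seed=0)

    def test_strong_clusters_minimize_at_three(self, strong_meta):
        resp = vb.hellinger(strong_meta.matrix)
        X = vb.build_constraints(strong_meta.sites)
        res = cross_validate(resp, X, folds=10, seed=3)
        best = res.sizes[int(np.argmin(res.xerror))]
        assert best == 3
        assert (res.xerror >= 0).all() and (res.se >= 0).all()

    def test_determinism(self, strong_meta):
        resp = vb.hellinger(strong_meta.matrix)
        X = vb.build_constraints(strong_meta.sites)
        r1 = cross_validate(resp, X, folds=10, seed=5)
        r2 = cross_validate(resp, X, folds=10, seed=5)
        np.testing.assert_array_equal(r1.xerror, r2.xerror)
        np.testing.assert_array_equal(r1.se, r2.se)


class TestMultiCV:
    def test_single_replicate(self, strong_meta):
        resp = vb.hellinger(strong_meta.matrix)
        X = vb.build_constraints(strong_meta.sites)
        summary = vb.multi_cv(resp, X, replicates=1, folds=10, seed=0)
        assert sum(summary.frequencies.values()) == 1
        assert len(summary.optimal_sizes) == 1

    def test_frequencies_sum_to_replicates(self, strong_meta):
        resp = vb.hellinger(strong_meta.matrix)
        X = vb.build_constraints(strong_meta.sites)
        summary = vb.multi_cv(resp, X, replicates=12, folds=10, seed=0)
        assert sum(summary.frequencies.values()) == 12

    def test_modal_size_is_three(self, strong_meta):
        resp = vb.hellinger(strong_meta.matrix)
        X = vb.build_constraints(strong_meta.sites)
        summary = vb.multi_cv(resp, X, replicates=30, folds=10, seed=0)
        assert vb.select_size(summary, "most_frequent_min") == 3
        assert summary.frequencies.get(3, 0) >= 28

    def test_bit_identical_under_fixed_seed(self, strong_meta):
        resp = vb.hellinger(strong_meta.matrix)
        X = vb.build_constraints(strong_meta.sites)
        s1 = vb.multi_cv(resp, X, replicates=5, folds=10, seed=9)
        s2 = vb.multi_cv(resp, X, replicates=5, folds=10, seed=9)
        np.testing.assert_array_equal(s1.xerror_mean, s2.xerror_mean)
        np.testing.assert_array_equal(s1.xerror_se, s2.xerror_se)
        assert s1.optimal_sizes == s2.optimal_sizes


class TestSelectSize:
    def _summary(self, sizes, xerror, se, freqs):
        return vb.MultiCVSummary(
            replicates=sum(freqs.values()),
            sizes=sizes,
            xerror_mean=np.array(xerror),
            xerror_se=np.array(se),
            optimal_sizes=[s for s, c in freqs.items() for _ in range(c)],
            frequencies=freqs,
            seed=0,
        )

    def test_most_frequent_min(self):
        s = self._summary([5, 3, 1], [0.5, 0.4, 1.0], [0.1, 0.1, 0.1], {3: 60, 5: 40})
        assert vb.select_size(s, "most_frequent_min") == 3

    def test_most_frequent_tie_takes_smaller(self):
        s = self._summary([5, 3, 1], [0.5, 0.4, 1.0], [0.1, 0.1, 0.1], {3: 50, 5: 50})
        assert vb.select_size(s, "most_frequent_min") == 3

    def test_one_se_flat_curve_takes_smallest(self):
        s = self._summary(
            [7, 5, 3, 1], [0.50, 0.49, 0.52, 0.55], [0.1, 0.1, 0.1, 0.1], {7: 1}
        )
        assert vb.select_size(s, "one_se") == 1

    def test_unknown_rule(self):
        s = self._summary([1], [1.0], [0.0], {1: 1})
        with pytest.raises(ValueError):
            vb.select_size(s, "elbow")

    def test_rules_agree_on_strong_five_province_signal(self):
        meta = vb.generate_metacommunity(
            vb.MetacommunityParams(n_provinces=5, endemicity=0.95, detection_prob=0.95),
            seed=4,
        )
        resp = vb.hellinger(meta.matrix)
        X = vb.build_constraints(meta.sites)
        summary = vb.multi_cv(resp, X, replicates=20, folds=10, seed=1)
        assert vb.select_size(summary, "most_frequent_min") == 5
        assert vb.select_size(summary, "one_se") == 5


class TestAssignProvinces:
    def test_size_one(self, strong_meta):
        resp = vb.hellinger(strong_meta.matrix)
        X = vb.build_constraints(strong_meta.sites)
        seq = prune(grow_tree(resp, X))
        labels = vb.assign_provinces(seq, 1, resp.site_ids)
        assert set(labels.values()) == {1}
        assert len(labels) == resp.n_sites

    def test_four_site_pairs(self):
        resp = make_response([[1, 0], [1, 0], [0, 1], [0, 1]])
        seq = prune(grow_tree(resp, constraints_for(resp, {"x": [0.0, 1, 10, 11]})))
        labels = vb.assign_provinces(seq, 2, resp.site_ids)
        assert labels["s0"] == labels["s1"]
        assert labels["s2"] == labels["s3"]
        assert labels["s0"] != labels["s2"]

    def test_strong_signal_ari_one(self, strong_meta):
        resp = vb.hellinger(strong_meta.matrix)
        X = vb.build_constraints(strong_meta.sites)
        seq = prune(grow_tree(resp, X))
        labels = vb.assign_provinces(seq, 3, resp.site_ids)
        truth = [strong_meta.true_labels[s] for s in resp.site_ids]
        pred = [labels[s] for s in resp.site_ids]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_unachievable_size_reports_alternatives(self, strong_meta):
        resp = vb.hellinger(strong_meta.matrix)
        X = vb.build_constraints(strong_meta.sites)
        seq = prune(grow_tree(resp, X, TreeControl(max_leaves=4)))
        with pytest.raises(ValueError, match="achievable"):
            vb.assign_provinces(seq, 99, resp.site_ids)


class TestEncodingSensitivityScan:
    def test_single_scheme_matches_direct_run(self, strong_meta):
        res = vb.encoding_sensitivity_scan(
            strong_meta.matrix,
            strong_meta.sites,
            ["greenwich_pm180"],
            replicates=5,
            folds=10,
            seed=2,
        )
        resp = vb.hellinger(strong_meta.matrix)
        X = vb.build_constraints(strong_meta.sites, "greenwich_pm180")
        direct = vb.multi_cv(resp, X, replicates=5, folds=10, seed=2)
        np.testing.assert_array_equal(
            res["greenwich_pm180"].summary.xerror_mean, direct.xerror_mean
        )
        assert res["greenwich_pm180"].summary.frequencies == direct.frequencies

    def test_no_schemes_rejected(self, strong_meta):
        with pytest.raises(ValueError):
            vb.encoding_sensitivity_scan(strong_meta.matrix, strong_meta.sites, [])

    def test_far_from_cut_lines_schemes_agree(self):
        # all provinces well inside the eastern hemisphere: every scheme
        # should produce the same partition
        params = vb.MetacommunityParams(n_provinces=3, sites_per_province=6)
        meta = vb.generate_metacommunity(params, seed=8)
        sites = [
            vb.SiteRecord(
                s.site_id,
                s.latitude_deg,
                30.0 + (meta.true_labels[s.site_id] - 1) * 40.0 + (i % 7) - 3,
                s.region_label,
            )
            for i, s in enumerate(meta.sites)
        ]
        res = vb.encoding_sensitivity_scan(
            meta.matrix, sites, sorted(vb.encoding.SCHEMES), replicates=5, folds=6, seed=3
        )
        partitions = []
        for r in res.values():
            labels = [r.assignment[s] for s in meta.matrix.site_ids]
            partitions.append(labels)
        for other in partitions[1:]:
            assert adjusted_rand_score(partitions[0], other) == 1.0
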