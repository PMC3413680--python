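import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gbaselect import (
    GenePartition,
    RocCurve,
    SelectionParams,
    SyntheticSpec,
    auc_from_scores,
    average_roc,
    compare_histograms,
    cross_validate,
    default_experiment_design,
    gba_scores,
    generate_collection,
    generate_nested_chain,
    pair_scores,
    pearson,
    roc_from_scores,
    specificity_sweep,
)


def _auc_oracle(pos, neg):
    """Exhaustive pair enumeration: wins count 1, ties 1/2."""
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


scores = st.lists(st.integers(-5, 5), min_size=1, max_size=8)


class TestAuc:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ((3, 4), (1, 2), 1.0),
            ((1, 1, 1), (1, 1, 1), 0.5),
            ((1, 3), (2, 4), 0.25),  # frozen from the enumeration oracle
        ],
    )
    def test_examples(self, pos, neg, expected):
        assert _auc_oracle(pos, neg) == expected
        assert auc_from_scores(pos, neg) == pytest.approx(expected)

    @settings(deadline=None, max_examples=200)
    @given(pos=scores, neg=scores)
    def test_matches_exhaustive_oracle(self, pos, neg):
        assert auc_from_scores(pos, neg) == pytest.approx(_auc_oracle(pos, neg),
                                                          abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(pos=scores, neg=scores)
    def test_sign_reversal_complements(self, pos, neg):
        auc = auc_from_scores(pos, neg)
        flipped = auc_from_scores([-x for x in pos], [-x for x in neg])
        assert flipped == pytest.approx(1.0 - auc, abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(pos=scores, neg=scores)
    def test_roc_curve_consistency(self, pos, neg):
        curve = roc_from_scores(pos, neg)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert curve.fpr[0] == 0 and curve.fpr[-1] == 1
        trapezoid = float(np.trapezoid(curve.tpr, curve.fpr))
        assert curve.auc == pytest.approx(trapezoid, abs=1e-9)
        assert curve.auc == pytest.approx(auc_from_scores(pos, neg), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc_from_scores([], [1.0])


class TestAverageRoc:
    def test_identical_curves_unchanged(self):
        c = roc_from_scores([3, 4, 5], [1, 2, 3.5])
        avg = average_roc([c, c, c])
        np.testing.assert_allclose(np.interp(avg.fpr, c.fpr, c.tpr), avg.tpr,
                                   atol=1e-12)
        assert avg.auc == pytest.approx(c.auc, abs=1e-3)

    def test_midpoint_of_diagonal_and_perfect(self):
        diag = RocCurve(np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0.5)
        perfect = RocCurve(np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 1.0]), 1.0)
        avg = average_roc([diag, perfect])
        at_half = avg.tpr[np.searchsorted(avg.fpr, 0.5)]
        assert at_half == pytest.approx(0.75)

    def test_average_auc_within_inputs(self):
        rng = np.random.default_rng(8)
        curves = [roc_from_scores(rng.normal(0.5, 1, 20), rng.normal(0, 1, 30))
                  for _ in range(5)]
        avg = average_roc(curves)
        aucs = [c.auc for c in curves]
        assert min(aucs) - 1e-6 <= avg.auc <= max(aucs) + 1e-6


class TestPairScores:
    def test_counting_with_all_genes(self, planted):
        _, collection, truth = planted
        pos, neg = pair_scores(collection, truth.partition,
                               collection.experiment_ids,
                               collection.gene_ids, alpha=None)
        m, b = 40, 200
        assert len(pos) == m * (m - 1) // 2
        assert len(neg) == m * b

    def test_planted_auc_high_on_relevant(self, planted):
        _, collection, truth = planted
        pos, neg = pair_scores(collection, truth.partition,
                               truth.relevant_experiments, collection.gene_ids)
        assert auc_from_scores(pos, neg) > 0.9

    def test_background_only_eval_genes_rejected(self, planted):
        _, collection, truth = planted
        with pytest.raises(ValueError, match="positive"):
            pair_scores(collection, truth.partition, collection.experiment_ids,
                        truth.partition.background[:5])


class TestGbaScores:
    def test_score_is_sum_of_pair_correlations(self, tiny_collection):
        train = ("g0", "g1", "g2")
        cand = ("g3", "g4")
        got = gba_scores(tiny_collection, {"E1", "E2"}, train, cand, alpha=None)
        values = tiny_collection.matrix.values
        idx = {g: i for i, g in enumerate(tiny_collection.gene_ids)}
        for g in cand:
            expected = sum(pearson(values[idx[g]], values[idx[t]]) for t in train)
            assert got[g] == pytest.approx(expected, abs=1e-12)

    def test_identical_profile_contributes_one(self, tiny_collection):
        from gbaselect import ExpressionCollection, ExpressionMatrix

        values = tiny_collection.matrix.values.copy()
        values[3] = values[0]  # candidate g3 duplicates training gene g0
        collection = ExpressionCollection(
            ExpressionMatrix(values, tiny_collection.gene_ids,
                             tiny_collection.matrix.array_ids),
            tiny_collection.experiments,
        )
        got = gba_scores(collection, {"E1", "E2"}, ("g0",), ("g3",), alpha=None)
        assert got["g3"] == pytest.approx(1.0)

    def test_planted_separates_held_out_category(self, planted):
        _, collection, truth = planted
        cat, bg = truth.partition.category, truth.partition.background
        scores = gba_scores(collection, truth.relevant_experiments,
                            cat[:30], cat[30:] + bg[:50])
        held_out = np.mean([scores[g] for g in cat[30:]])
        background = np.mean([scores[g] for g in bg[:50]])
        assert held_out > background

    def test_validation(self, tiny_collection):
        with pytest.raises(ValueError, match="empty"):
            gba_scores(tiny_collection, {"E1"}, (), ("g3",))
        with pytest.raises(ValueError, match="disjoint"):
            gba_scores(tiny_collection, {"E1"}, ("g0",), ("g0", "g3"))


class TestCompareHistograms:
    def test_selected_equals_all_is_null(self, planted):
        _, collection, truth = planted
        cmp = compare_histograms(collection, truth.partition,
                                 collection.experiment_ids)
        np.testing.assert_array_equal(cmp.counts_selected, cmp.counts_all)
        assert cmp.log_p == pytest.approx(math.log(0.5))

    def test_planted_enrichment_in_high_correlations(self, planted):
        _, collection, truth = planted
        cmp = compare_histograms(collection, truth.partition,
                                 truth.relevant_experiments, bins=40)
        edges = cmp.bin_edges
        high = np.abs((edges[:-1] + edges[1:]) / 2) > 0.5
        frac_sel = cmp.counts_selected[high].sum() / cmp.counts_selected.sum()
        frac_all = cmp.counts_all[high].sum() / cmp.counts_all.sum()
        assert frac_sel > frac_all
        assert cmp.log_p < math.log(1e-6)

    def test_counts_conserve_retained_values(self, planted):
        _, collection, truth = planted
        cmp = compare_histograms(collection, truth.partition,
                                 truth.relevant_experiments, bins=40)
        assert cmp.counts_selected.sum() == cmp.n_selected
        assert cmp.counts_all.sum() == cmp.n_all


@pytest.fixture(scope="module")
def small_planted():
    """Small planted collection so cross-validation stays fast."""
    spec = SyntheticSpec(
        n_category_genes=20, n_background_genes=60, background_block_size=10,
        experiments=default_experiment_design(2, 8, 6), rng_seed=3,
    )
    return generate_collection(spec)


class TestCrossValidate:
    def test_planted_improvement_pair_mode(self, small_planted):
        collection, truth = small_planted
        params = SelectionParams(k_seeds=5, rng_seed=3)
        report = cross_validate(collection, truth.partition, "pair", params)
        assert report.mean_one_minus_auc_selected < report.mean_one_minus_auc_all
        assert report.fold_ttest_p < 0.05
        assert len(report.fold_auc_selected) == 10
        assert len(report.selections) == 10

    def test_selected_equals_all_gives_null_comparison(self, small_planted):
        collection, truth = small_planted
        # threshold rule with L = 1 accepts everything: selected == all
        params = SelectionParams(k_seeds=2, significance=1.0,
                                 acceptance_rule="threshold", rng_seed=1)
        report = cross_validate(collection, truth.partition, "pair", params,
                                folds=5)
        assert all(set(s.selected) == set(collection.experiment_ids)
                   for s in report.selections)
        np.testing.assert_allclose(report.fold_auc_selected, report.fold_auc_all)
        assert report.fold_ttest_p >= 0.5

    def test_bit_reproducible(self, small_planted):
        collection, truth = small_planted
        params = SelectionParams(k_seeds=3, rng_seed=11)
        r1 = cross_validate(collection, truth.partition, "gba", params, folds=5)
        r2 = cross_validate(collection, truth.partition, "gba", params, folds=5)
        assert r1.to_json() == r2.to_json()

    def test_leave_one_category_gene_out(self):
        spec = SyntheticSpec(
            n_category_genes=8, n_background_genes=24, background_block_size=8,
            experiments=default_experiment_design(1, 4, 5), rng_seed=6,
        )
        collection, truth = generate_collection(spec)
        params = SelectionParams(k_seeds=2, rng_seed=6)
        report = cross_validate(collection, truth.partition, "pair", params,
                                folds=len(truth.partition.category))
        assert len(report.fold_auc_selected) == 8

    def test_category_smaller_than_folds_rejected(self, small_planted):
        collection, truth = small_planted
        small = GenePartition(truth.partition.category[:5],
                              truth.partition.background)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(collection, small, "pair", SelectionParams(k_seeds=2))

    def test_label_shuffle_gives_null_auc(self, noise_collection):
        """Pair AUC on all experiments is ~0.5 once labels are shuffled."""
        collection, truth = noise_collection
        genes = list(truth.partition.category) + list(truth.partition.background)
        n_cat = len(truth.partition.category)
        rng = np.random.default_rng(17)
        aucs = []
        for _ in range(50):
            perm = rng.permutation(genes)
            part = GenePartition(tuple(perm[:n_cat]), tuple(perm[n_cat:]))
            pos, neg = pair_scores(collection, part, collection.experiment_ids,
                                   genes, alpha=None)
            aucs.append(auc_from_scores(pos, neg))
        assert abs(np.mean(aucs) - 0.5) <= 0.05


class TestSpecificitySweep:
    def test_single_level_equals_cross_validate(self, small_planted):
        collection, truth = small_planted
        params = SelectionParams(k_seeds=3, rng_seed=2)
        diffs, reports = specificity_sweep(collection, [truth.partition], params,
                                           folds=5)
        assert len(diffs) == 1
        assert diffs[0] == pytest.approx(
            reports[0].mean_one_minus_auc_all
            - reports[0].mean_one_minus_auc_selected)

    def test_non_nested_chain_rejected(self, small_planted):
        collection, truth = small_planted
        cat, bg = truth.partition.category, truth.partition.background
        p1 = GenePartition(cat, bg)
        p2 = GenePartition(cat[:10] + bg[:5], bg[5:])  # drops category genes
        with pytest.raises(ValueError, match="nested"):
            specificity_sweep(collection, [p1, p2], SelectionParams(k_seeds=2))

    def test_planted_chain_diffs_decrease(self, small_planted):
        collection, truth = small_planted
        spec = SyntheticSpec(
            n_category_genes=20, n_background_genes=60, background_block_size=10,
            experiments=default_experiment_design(2, 8, 6), rng_seed=3,
        )
        chain = generate_nested_chain(spec, 3)
        params = SelectionParams(k_seeds=3, rng_seed=4)
        diffs, _ = specificity_sweep(collection, chain, params, folds=5)
        assert diffs[0] > diffs[-1]
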