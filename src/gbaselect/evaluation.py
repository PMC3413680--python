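"""Correlation-based evaluation of an experiment subset.

Four instruments, all driven by Pearson correlations over a chosen
experiment subset:

* :func:`compare_histograms` — distribution of within-category correlations
  for a selected subset vs the whole collection, with a one-sided t-test on
  the absolute values;
* pair classification — can the correlation of a gene pair tell
  category-category pairs (positives) from category-background pairs
  (negatives)?  Scored by ROC/AUC;
* guilt-by-association (GBA) prediction — score a gene by the sum of its
  correlations to the training genes of the category, again ROC/AUC;
* :func:`cross_validate` — 10-fold cross-validation wrapping either task:
  experiments are selected on the training genes only, evaluation uses the
  held-out genes, and "selected" is compared against "all experiments" via
  the per-fold (1-AUC) values and a paired one-sided t-test.

:func:`specificity_sweep` repeats pair-mode cross-validation along a
user-supplied leaf-to-root chain of nested categories, reporting the
(1-AUC) improvement at each annotation level.

Correlations used as scores are, by default, zeroed when not significant at
``alpha = 0.05`` (two-sided t-transform), which controls the vector-length
bias between subsets of different sizes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .correlation import (
    _cross_correlations,
    build_correlation_sets,
    correlation_pvalue,
    filter_significant,
    log_t_sf,
)
from .io import ExpressionCollection, GenePartition
from .selection import SelectionParams, select_experiments

__all__ = [
    "RocCurve",
    "CvReport",
    "HistogramComparison",
    "compare_histograms",
    "auc_from_scores",
    "roc_from_scores",
    "average_roc",
    "pair_scores",
    "gba_scores",
    "cross_validate",
    "specificity_sweep",
]

DEFAULT_ALPHA = 0.05
ROC_GRID_POINTS = 101


@dataclass(frozen=True)
class RocCurve:
    """ROC curve points (FPR ascending) and its trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self):
        object.__setattr__(self, "fpr", np.asarray(self.fpr, dtype=float))
        object.__setattr__(self, "tpr", np.asarray(self.tpr, dtype=float))


def roc_from_scores(pos_scores, neg_scores) -> RocCurve:
    """ROC curve from raw scores; thresholds descend, tied scores grouped."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    # group ties: take cumulative counts at the last element of each tie block
    block_end = np.flatnonzero(np.diff(scores)) if scores.size > 1 else np.array([], int)
    idx = np.concatenate([block_end, [scores.size - 1]])
    tp = np.concatenate([[0.0], np.cumsum(labels)[idx]])
    fp = np.concatenate([[0.0], np.cumsum(1.0 - labels)[idx]])
    tpr = tp / pos.size
    fpr = fp / neg.size
    return RocCurve(fpr, tpr, float(np.trapezoid(tpr, fpr)))


def auc_from_scores(pos_scores, neg_scores) -> float:
    """P(random positive outscores random negative), ties counted 1/2.

    Rank (Mann-Whitney) formulation; identical to the trapezoidal area of
    the tie-grouped ROC curve.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def average_roc(curves) -> RocCurve:
    """Vertical (pointwise-in-FPR) average of ROC curves on a common grid."""
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one curve")
    grid = np.linspace(0.0, 1.0, ROC_GRID_POINTS)
    stackedtpr = np.vstack([np.interp(grid, c.fpr, c.tpr) for c in curves])
    tpr = stackedtpr.mean(axis=0)
    return RocCurve(grid, tpr, float(np.trapezoid(tpr, grid)))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _zero_insignificant(R: np.ndarray, n_arrays: int, alpha) -> np.ndarray:
    if alpha is None:
        return R
    p = correlation_pvalue(R, n_arrays)
    return np.where(np.asarray(p) < alpha, R, 0.0)


def _subset_correlations(collection: ExpressionCollection, experiments,
                         genes_a, genes_b):
    cols = collection.column_indices(experiments)
    m = collection.matrix
    X = m.values[np.ix_(m.gene_indices(genes_a), cols)]
    Y = m.values[np.ix_(m.gene_indices(genes_b), cols)]
    return _cross_correlations(X, Y), len(cols)


def pair_scores(collection: ExpressionCollection, partition: GenePartition,
                experiments, eval_genes, alpha=DEFAULT_ALPHA):
    """Correlation scores for the pair-classification task.

    Positives: category-category pairs; negatives: category-background
    pairs; in both cases only pairs with at least one endpoint in
    ``eval_genes``.  Scores are the pair correlations, zeroed when not
    significant at ``alpha`` (pass ``alpha=None`` for raw correlations).
    Undefined (dropped) pairs are omitted.
    """
    eval_set = set(eval_genes)
    unknown = eval_set - set(collection.gene_ids)
    if unknown:
        raise KeyError(f"unknown gene id {sorted(unknown)[0]!r}")
    cat = partition.category
    bg = partition.background
    Rcc, n_arrays = _subset_correlations(collection, experiments, cat, cat)
    Rcb, _ = _subset_correlations(collection, experiments, cat, bg)
    in_eval_cat = np.array([g in eval_set for g in cat])
    in_eval_bg = np.array([g in eval_set for g in bg])
    iu, ju = np.triu_indices(len(cat), k=1)
    keep_pos = in_eval_cat[iu] | in_eval_cat[ju]
    pos = Rcc[iu, ju][keep_pos]
    keep_neg = in_eval_cat[:, None] | in_eval_bg[None, :]
    neg = Rcb[keep_neg]
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    if pos.size == 0:
        raise ValueError("no positive (category-category) pairs touch the evaluation genes")
    if neg.size == 0:
        raise ValueError("no negative (category-background) pairs touch the evaluation genes")
    pos = _zero_insignificant(pos, n_arrays, alpha)
    neg = _zero_insignificant(neg, n_arrays, alpha)
    return pos, neg


def gba_scores(collection: ExpressionCollection, experiments, train_category,
               candidates, alpha=DEFAULT_ALPHA) -> dict:
    """Guilt-by-association score: sum of a gene's correlations to the
    training category genes over the experiment subset.

    Undefined correlations contribute 0; with ``alpha`` set, correlations
    not significant at that level also contribute 0.
    """
    train = tuple(train_category)
    cand = tuple(candidates)
    if not train:
        raise ValueError("train_category is empty")
    if set(train) & set(cand):
        raise ValueError("train_category and candidates must be disjoint")
    R, n_arrays = _subset_correlations(collection, experiments, cand, train)
    R = np.where(np.isfinite(R), R, 0.0)
    R = _zero_insignificant(R, n_arrays, alpha)
    totals = R.sum(axis=1)
    return {g: float(s) for g, s in zip(cand, totals)}


# ---------------------------------------------------------------------------
# histogram comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HistogramComparison:
    """Within-category correlation distributions, selected vs all experiments."""

    bin_edges: np.ndarray
    counts_selected: np.ndarray
    counts_all: np.ndarray
    log_p: float  # one-sided t-test on |r|, selected > all
    n_selected: int
    n_all: int
    n_arrays_selected: int
    n_arrays_all: int


def _abs_ttest_log_p(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided pooled t-test log p for mean(|a|) > mean(|b|)."""
    a = np.abs(np.asarray(a, dtype=float))
    b = np.abs(np.asarray(b, dtype=float))
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if se == 0.0:
        return math.log(0.5) if a.mean() == b.mean() else (
            -math.inf if a.mean() > b.mean() else 0.0)
    return log_t_sf((a.mean() - b.mean()) / se, na + nb - 2)


def compare_histograms(collection: ExpressionCollection, partition: GenePartition,
                       selected, alpha: float = DEFAULT_ALPHA,
                       bins: int = 40) -> HistogramComparison:
    """Compare within-category correlation distributions for a selected
    experiment subset against the full collection.

    Each distribution keeps only correlations significant at ``alpha`` for
    its own vector length (the length-bias control), then the absolute
    values are compared by a one-sided t-test (selected > all).
    """
    sel_sets = build_correlation_sets(collection, selected, partition)
    all_sets = build_correlation_sets(collection, collection.experiment_ids, partition)
    a_sel = filter_significant(sel_sets.a_values, sel_sets.n_arrays, alpha)
    a_all = filter_significant(all_sets.a_values, all_sets.n_arrays, alpha)
    if a_sel.size < 2 or a_all.size < 2:
        raise ValueError(
            "too few significant within-category correlations "
            f"(selected: {a_sel.size} of {sel_sets.a_values.size}, "
            f"all: {a_all.size} of {all_sets.a_values.size})"
        )
    edges = np.linspace(-1.0, 1.0, bins + 1)
    return HistogramComparison(
        bin_edges=edges,
        counts_selected=np.histogram(a_sel, bins=edges)[0],
        counts_all=np.histogram(a_all, bins=edges)[0],
        log_p=_abs_ttest_log_p(a_sel, a_all),
        n_selected=int(a_sel.size),
        n_all=int(a_all.size),
        n_arrays_selected=sel_sets.n_arrays,
        n_arrays_all=all_sets.n_arrays,
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CvReport:
    mode: str
    fold_auc_selected: tuple
    fold_auc_all: tuple
    avg_roc_selected: RocCurve
    avg_roc_all: RocCurve
    fold_ttest_p: float
    selections: tuple  # per-fold SelectionResult
    # convention flag: test pairs have >= 1 endpoint in the held-out fold
    eval_pair_convention: str = "at_least_one_test_endpoint"

    @property
    def mean_one_minus_auc_selected(self) -> float:
        return 1.0 - float(np.mean(self.fold_auc_selected))

    @property
    def mean_one_minus_auc_all(self) -> float:
        return 1.0 - float(np.mean(self.fold_auc_all))

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "fold_auc_selected": list(self.fold_auc_selected),
            "fold_auc_all": list(self.fold_auc_all),
            "mean_one_minus_auc_selected": self.mean_one_minus_auc_selected,
            "mean_one_minus_auc_all": self.mean_one_minus_auc_all,
            "fold_ttest_p": self.fold_ttest_p,
            "eval_pair_convention": self.eval_pair_convention,
            "avg_roc_selected": {
                "fpr": self.avg_roc_selected.fpr.tolist(),
                "tpr": self.avg_roc_selected.tpr.tolist(),
                "auc": self.avg_roc_selected.auc,
            },
            "avg_roc_all": {
                "fpr": self.avg_roc_all.fpr.tolist(),
                "tpr": self.avg_roc_all.tpr.tolist(),
                "auc": self.avg_roc_all.auc,
            },
            "selections": [s.to_dict() for s in self.selections],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _stratified_folds(genes, folds: int, rng: np.random.Generator):
    """Shuffle then split one gene list into ``folds`` near-equal parts."""
    genes = list(genes)
    order = rng.permutation(len(genes))
    shuffled = [genes[i] for i in order]
    return [shuffled[i::folds] for i in range(folds)]


def _paired_one_sided_p(worse, better) -> float:
    """Paired t-test p for mean(worse) > mean(better); 0.5 when identical."""
    d = np.asarray(worse, dtype=float) - np.asarray(better, dtype=float)
    if np.allclose(d, 0.0):
        return 0.5
    if d.std(ddof=1) == 0.0:
        return float(np.nextafter(0, 1)) if d.mean() > 0 else 1.0
    t, p = stats.ttest_rel(worse, better, alternative="greater")
    return float(max(p, np.nextafter(0, 1)))


def _fold_scores(collection, partition, experiments, mode, cat_train, test_genes,
                 alpha):
    if mode == "pair":
        return pair_scores(collection, partition, experiments, test_genes, alpha)
    scores = gba_scores(collection, experiments, cat_train, test_genes, alpha)
    cat_set = set(partition.category)
    pos = np.array([scores[g] for g in test_genes if g in cat_set])
    neg = np.array([scores[g] for g in test_genes if g not in cat_set])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("a fold lacks positive or negative evaluation genes")
    return pos, neg


def cross_validate(collection: ExpressionCollection, partition: GenePartition,
                   mode: str, params: SelectionParams, folds: int = 10,
                   alpha=DEFAULT_ALPHA) -> CvReport:
    """Stratified ``folds``-fold cross-validation of experiment selection.

    Per fold: experiments are selected with only the training genes, then the
    held-out genes are scored (pair or GBA mode) under both the selected
    subset and the full collection.  Stratification spreads category genes
    across folds so every fold retains positives; the paired one-sided t-test
    compares the ten (1-AUC) values fold by fold.
    """
    if mode not in ("pair", "gba"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(partition.category) < folds:
        raise ValueError(
            f"category has {len(partition.category)} genes; need >= folds ({folds})"
        )
    master = np.random.SeedSequence(int(params.rng_seed))
    ss_folds, ss_select = master.spawn(2)
    rng = np.random.default_rng(ss_folds)
    cat_folds = _stratified_folds(partition.category, folds, rng)
    bg_folds = _stratified_folds(partition.background, folds, rng)
    select_seeds = [int(s.generate_state(1, np.uint32)[0]) for s in ss_select.spawn(folds)]

    all_ids = collection.experiment_ids
    auc_sel, auc_all, rocs_sel, rocs_all, selections = [], [], [], [], []
    for f in range(folds):
        cat_test, bg_test = cat_folds[f], bg_folds[f]
        if not cat_test:
            raise ValueError(f"fold {f} holds no category genes")
        cat_train = tuple(g for g in partition.category if g not in set(cat_test))
        bg_train = tuple(g for g in partition.background if g not in set(bg_test))
        train_partition = GenePartition(cat_train, bg_train)
        fold_params = SelectionParams(**{**asdict(params), "rng_seed": select_seeds[f]})
        sel = select_experiments(collection, train_partition, fold_params)
        selections.append(sel)
        test_genes = tuple(cat_test) + tuple(bg_test)
        for experiments, aucs, rocs in (
            (sel.selected, auc_sel, rocs_sel),
            (all_ids, auc_all, rocs_all),
        ):
            pos, neg = _fold_scores(collection, partition, experiments, mode,
                                    cat_train, test_genes, alpha)
            aucs.append(auc_from_scores(pos, neg))
            rocs.append(roc_from_scores(pos, neg))
    one_minus_sel = [1.0 - a for a in auc_sel]
    one_minus_all = [1.0 - a for a in auc_all]
    return CvReport(
        mode=mode,
        fold_auc_selected=tuple(auc_sel),
        fold_auc_all=tuple(auc_all),
        avg_roc_selected=average_roc(rocs_sel),
        avg_roc_all=average_roc(rocs_all),
        fold_ttest_p=_paired_one_sided_p(one_minus_all, one_minus_sel),
        selections=tuple(selections),
    )


def specificity_sweep(collection: ExpressionCollection, nested_partitions,
                      params: SelectionParams, folds: int = 10,
                      mode: str = "pair", alpha=DEFAULT_ALPHA):
    """(1-AUC) improvement of selected over all experiments at each level of
    a leaf-to-root chain of nested categories.

    Returns ``(differences, reports)`` where ``differences[i] =
    mean(1-AUC)_all - mean(1-AUC)_selected`` at level ``i``.
    """
    nested_partitions = list(nested_partitions)
    if not nested_partitions:
        raise ValueError("need at least one partition")
    prev = None
    for p in nested_partitions:
        if prev is not None and not set(prev.category) <= set(p.category):
            raise ValueError("categories must be nested (non-decreasing leaf to root)")
        prev = p
    diffs, reports = [], []
    for p in nested_partitions:
        report = cross_validate(collection, p, mode, params, folds, alpha)
        reports.append(report)
        diffs.append(report.mean_one_minus_auc_all - report.mean_one_minus_auc_selected)
    return diffs, reports
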