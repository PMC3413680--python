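"""Greedy selection of the experiments relevant to a functional category.

The objective for a candidate experiment subset is the one-sided two-sample
t-test asking whether the mean within-category correlation (set A) exceeds
the mean category-vs-background correlation (set B), computed over the
subset's concatenated arrays.  The search:

1. scores every single experiment and keeps the ``k_seeds`` best as seeds;
2. grows one list per seed — candidates are visited in random order, each is
   tentatively appended and kept according to the acceptance rule;
3. returns the grown list with the best (lowest) final log p-value.

All p-values are natural-log values computed with :func:`~gbaselect.correlation.log_t_sf`
so they stay comparable far below double underflow.

Acceptance rules
----------------
``improve`` (default)
    keep a candidate iff the expanded list's p-value is below the
    significance level ``L`` *and* strictly better than the current list's.
    A pure significance threshold saturates whenever the category signal is
    strong — the A/B test over hundreds or thousands of correlation pairs
    stays significant even after heavy dilution, so every candidate would be
    accepted; requiring improvement keeps the grown lists small and relevant.
``threshold``
    the literal rule: keep iff the expanded list's p-value is below ``L``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .correlation import CorrelationSets, build_correlation_sets, log_t_sf
from .io import ExpressionCollection, GenePartition

__all__ = [
    "SelectionParams",
    "ListTrace",
    "SelectionResult",
    "discrimination_log_p",
    "rank_seed_experiments",
    "grow_list",
    "select_experiments",
]


@dataclass(frozen=True)
class SelectionParams:
    """Tunable parameters of the selection search.

    k_seeds
        number of seed experiments (K); clamped nowhere — must not exceed
        the number of experiments.
    significance
        the t-test significance level L for accepting a candidate.
    ttest_variant
        "pooled" (equal-variance) or "welch".
    acceptance_rule
        "improve" or "threshold"; see module docstring.
    use_fisher_transform
        apply atanh to all correlations before the t-test, making the
        values closer to Gaussian (off by default).
    objective_alpha
        if set, significance-filter the A/B correlations (two-sided
        t-transform p < alpha) before the objective t-test.  Off by
        default: within one selection run the vector-length bias the filter
        controls for matters only across subset sizes, and filtering
        changes sample sizes mid-search.
    background_sample
        if set, use only this many background genes (deterministic
        subsample per run) — a documented speed-up for very large
        backgrounds, with no tuned default.
    rng_seed
        master seed; each seed-list's candidate order comes from an
        independent substream so results are reproducible and K can grow
        without reshuffling earlier lists.
    """

    k_seeds: int = 25
    significance: float = 0.05
    ttest_variant: str = "pooled"
    acceptance_rule: str = "improve"
    use_fisher_transform: bool = False
    objective_alpha: float | None = None
    background_sample: int | None = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.k_seeds < 1:
            raise ValueError("k_seeds must be >= 1")
        if not 0.0 < self.significance <= 1.0:
            raise ValueError("significance must be in (0, 1]")
        if self.ttest_variant not in ("pooled", "welch"):
            raise ValueError(f"unknown ttest_variant {self.ttest_variant!r}")
        if self.acceptance_rule not in ("improve", "threshold"):
            raise ValueError(f"unknown acceptance_rule {self.acceptance_rule!r}")


@dataclass(frozen=True)
class ListTrace:
    """Record of one seed list's growth."""

    seed: str
    visit_order: tuple
    accepted: tuple  # includes the seed, in acceptance order
    log_p_after_each_accept: tuple
    final_log_p: float


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple
    final_log_p: float
    traces: tuple
    params: SelectionParams
    n_ttests: int

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "final_log_p": self.final_log_p,
            "params": asdict(self.params),
            "n_ttests": self.n_ttests,
            "traces": [
                {
                    "seed": t.seed,
                    "visit_order": list(t.visit_order),
                    "accepted": list(t.accepted),
                    "log_p_after_each_accept": list(t.log_p_after_each_accept),
                    "final_log_p": t.final_log_p,
                }
                for t in self.traces
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def discrimination_log_p(sets: CorrelationSets, variant: str = "pooled",
                         use_fisher_transform: bool = False) -> float:
    """One-sided (mean A > mean B) two-sample t-test, natural-log p-value."""
    a = np.asarray(sets.a_values, dtype=float)
    b = np.asarray(sets.b_values, dtype=float)
    if use_fisher_transform:
        a = np.arctanh(np.clip(a, -1 + 1e-15, 1 - 1e-15))
        b = np.arctanh(np.clip(b, -1 + 1e-15, 1 - 1e-15))
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError(f"need >= 2 values per sample, got |A|={na}, |B|={nb}")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    diff = a.mean() - b.mean()
    if variant == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    elif variant == "welch":
        se = math.sqrt(va / na + vb / nb)
        if se > 0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = na + nb - 2
    else:
        raise ValueError(f"unknown ttest_variant {variant!r}")
    if se == 0.0:
        if diff == 0.0:
            return math.log(0.5)
        return -math.inf if diff > 0 else 0.0
    return log_t_sf(diff / se, df)


def _objective(collection: ExpressionCollection, partition: GenePartition,
               subset, params: SelectionParams) -> float:
    sets = build_correlation_sets(collection, subset, partition)
    if params.objective_alpha is not None:
        from .correlation import filter_significant

        sets = CorrelationSets(
            filter_significant(sets.a_values, sets.n_arrays, params.objective_alpha),
            filter_significant(sets.b_values, sets.n_arrays, params.objective_alpha),
            sets.n_arrays,
            sets.dropped_pairs,
        )
    return discrimination_log_p(sets, params.ttest_variant, params.use_fisher_transform)


def _effective_partition(collection: ExpressionCollection, partition: GenePartition,
                         params: SelectionParams) -> GenePartition:
    if params.background_sample is None or params.background_sample >= len(partition.background):
        return partition
    rng = np.random.default_rng(np.random.SeedSequence([int(params.rng_seed), 0x6B67]))
    idx = rng.choice(len(partition.background), size=params.background_sample, replace=False)
    return GenePartition(partition.category,
                         tuple(partition.background[i] for i in sorted(idx)))


def rank_seed_experiments(collection: ExpressionCollection, partition: GenePartition,
                          params: SelectionParams):
    """Score every single experiment; return the best ``k_seeds`` as
    ``(experiment_id, log_p)`` pairs, ascending log p (ties: manifest order)."""
    experiments = collection.experiment_ids
    n = len(experiments)
    if params.k_seeds > n:
        raise ValueError(f"k_seeds={params.k_seeds} exceeds {n} experiments")
    partition = _effective_partition(collection, partition, params)
    scored = [(e, _objective(collection, partition, {e}, params)) for e in experiments]
    scored.sort(key=lambda t: t[1])  # stable: manifest order breaks ties
    return scored[: params.k_seeds]


def grow_list(collection: ExpressionCollection, partition: GenePartition,
              seed_experiment: str, params: SelectionParams, rng: np.random.Generator,
              seed_log_p: float | None = None) -> ListTrace:
    """Grow one list from a seed: a single randomized pass over all other
    experiments, each kept or discarded by the acceptance rule."""
    partition = _effective_partition(collection, partition, params)
    others = [e for e in collection.experiment_ids if e != seed_experiment]
    if len(others) + 1 != len(collection.experiment_ids):
        raise KeyError(f"unknown experiment id {seed_experiment!r}")
    visit = tuple(others[i] for i in rng.permutation(len(others)))
    if seed_log_p is None:
        seed_log_p = _objective(collection, partition, {seed_experiment}, params)
    accepted = [seed_experiment]
    log_l = math.log(params.significance)
    current_log_p = seed_log_p
    accept_log = []
    for candidate in visit:
        trial = set(accepted) | {candidate}
        lp = _objective(collection, partition, trial, params)
        if params.acceptance_rule == "threshold":
            keep = lp < log_l
        else:  # improve
            keep = lp < log_l and lp < current_log_p
        if keep:
            accepted.append(candidate)
            current_log_p = lp
            accept_log.append(lp)
    return ListTrace(
        seed=seed_experiment,
        visit_order=visit,
        accepted=tuple(accepted),
        log_p_after_each_accept=tuple(accept_log),
        final_log_p=current_log_p,
    )


def select_experiments(collection: ExpressionCollection, partition: GenePartition,
                       params: SelectionParams) -> SelectionResult:
    """Run the full seed-and-grow search and return the best list.

    Ties on the final log p are broken toward fewer experiments, then
    lexicographic experiment ids.  The number of t-tests performed is
    ``n + K*(n-1)`` (n seed scores plus one test per candidate per list).
    """
    n = len(collection.experiment_ids)
    if n < 2:
        raise ValueError("need at least 2 experiments")
    seeds = rank_seed_experiments(collection, partition, params)
    master = np.random.SeedSequence(int(params.rng_seed))
    streams = master.spawn(len(seeds))
    traces = []
    for i, (seed_exp, seed_lp) in enumerate(seeds):
        rng = np.random.default_rng(streams[i])
        traces.append(grow_list(collection, partition, seed_exp, params, rng,
                                seed_log_p=seed_lp))
    best = min(traces,
               key=lambda t: (t.final_log_p, len(t.accepted), tuple(sorted(t.accepted))))
    n_ttests = n + len(seeds) * (n - 1)
    return SelectionResult(
        selected=tuple(sorted(best.accepted)),
        final_log_p=best.final_log_p,
        traces=tuple(traces),
        params=params,
        n_ttests=n_ttests,
    )
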