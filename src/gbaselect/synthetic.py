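"""Synthetic expression collections with planted relevant experiments.

The generative model encodes the working hypothesis behind experiment
selection: when the biological process of a category is *active* in an
experiment, its genes co-vary through a shared latent signal; when it is
not, their measurements are independent noise.

* Category genes: in each *relevant* experiment, every array carries a
  latent value ``s ~ N(0, signal_sd^2)`` shared by all category genes, plus
  i.i.d. noise ``N(0, noise_sd^2)``; in irrelevant experiments they are
  noise only.
* Background genes are grouped into co-expression blocks (standing in for
  "other functional terms"); each block shares its own latent in *every*
  experiment, so background structure is present throughout.

Values are rescaled so that every gene has marginal variance ``noise_sd^2``
in every experiment — the generator emulates normalized expression data, in
which biological signal changes correlation structure, not the overall
variance scale.  Within-category correlation in a relevant experiment is
therefore ``signal_sd^2 / (signal_sd^2 + noise_sd^2)`` in expectation, and
concatenating irrelevant arrays dilutes it toward zero.

Everything is deterministic under ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlation import build_correlation_sets
from .io import ExperimentMap, ExpressionCollection, ExpressionMatrix, GenePartition

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "default_experiment_design",
    "generate_collection",
    "dilution_curve",
    "generate_nested_chain",
]


def default_experiment_design(n_relevant: int = 4, n_irrelevant: int = 16,
                              arrays_per_experiment: int = 6):
    """The planted study design: a few relevant experiments hidden in a
    mostly-irrelevant collection, each with a handful of arrays."""
    design = []
    for i in range(n_relevant):
        design.append((f"REL{i + 1:02d}", arrays_per_experiment, True))
    for i in range(n_irrelevant):
        design.append((f"IRR{i + 1:02d}", arrays_per_experiment, False))
    return tuple(design)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-signal generator.

    ``signal_sd / noise_sd`` is the single effect-size knob: within-category
    correlation in a relevant experiment is ``ratio^2 / (ratio^2 + 1)``
    (0.8 at the default ratio 2).  ``background_block_size`` groups the
    background genes into independent co-expressed blocks.
    """

    n_category_genes: int = 40
    n_background_genes: int = 200
    experiments: tuple = field(default_factory=default_experiment_design)
    signal_sd: float = 2.0
    noise_sd: float = 1.0
    background_block_size: int = 10
    shared_gene: bool = False  # plant one gene in two background blocks
    rng_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "experiments", tuple(tuple(e) for e in self.experiments))
        if self.n_category_genes < 3:
            raise ValueError("need >= 3 category genes")
        if self.n_background_genes < 1:
            raise ValueError("need >= 1 background gene")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.signal_sd < 0:
            raise ValueError("signal_sd must be >= 0")
        if self.background_block_size < 1:
            raise ValueError("background_block_size must be >= 1")
        if not self.experiments:
            raise ValueError("need at least one experiment")
        ids = [e[0] for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate experiment ids")
        for name, n_arrays, _rel in self.experiments:
            if n_arrays < 3:
                raise ValueError(f"experiment {name!r} has {n_arrays} arrays; >= 3 required")

    @property
    def relevant_ids(self) -> tuple:
        return tuple(name for name, _n, rel in self.experiments if rel)

    @property
    def category_gene_ids(self) -> tuple:
        return tuple(f"CAT{i + 1:04d}" for i in range(self.n_category_genes))

    @property
    def background_gene_ids(self) -> tuple:
        return tuple(f"BG{i + 1:04d}" for i in range(self.n_background_genes))

    def background_blocks(self):
        """Background gene ids grouped into co-expression blocks."""
        genes = self.background_gene_ids
        size = self.background_block_size
        return [genes[i:i + size] for i in range(0, len(genes), size)]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated collection."""

    relevant_experiments: tuple
    partition: GenePartition

    def to_dict(self) -> dict:
        return {
            "relevant_experiments": list(self.relevant_experiments),
            "category": list(self.partition.category),
            "background": list(self.partition.background),
        }


def generate_collection(spec: SyntheticSpec):
    """Generate ``(ExpressionCollection, SyntheticTruth)`` from a spec."""
    rng = np.random.default_rng(int(spec.rng_seed))
    cat = spec.category_gene_ids
    bg = spec.background_gene_ids
    gene_ids = cat + bg
    n_cat = len(cat)
    blocks = spec.background_blocks()
    # unit-variance rescale: latent + noise keeps marginal sd = noise_sd
    shrink = spec.noise_sd / float(np.hypot(spec.signal_sd, spec.noise_sd))

    columns = []
    array_ids = []
    experiment_of = {}
    for name, n_arrays, relevant in spec.experiments:
        block_vals = rng.normal(0.0, spec.noise_sd, (len(gene_ids), n_arrays))
        if relevant and spec.signal_sd > 0:
            s = rng.normal(0.0, spec.signal_sd, n_arrays)
            block_vals[:n_cat] = (block_vals[:n_cat] + s) * shrink
        if spec.signal_sd > 0:
            offset = n_cat
            for block in blocks:
                latent = rng.normal(0.0, spec.signal_sd, n_arrays)
                sl = slice(offset, offset + len(block))
                block_vals[sl] = (block_vals[sl] + latent) * shrink
                offset += len(block)
            if spec.shared_gene and len(blocks) >= 2:
                # one background gene straddles two blocks (pathway cross-talk
                # motif): its profile mixes both blocks' signals
                block_vals[n_cat] = 0.5 * (
                    block_vals[n_cat] + block_vals[n_cat + len(blocks[0])]
                )
        array_ids_exp = [f"{name}_a{i + 1}" for i in range(n_arrays)]
        array_ids.extend(array_ids_exp)
        for a in array_ids_exp:
            experiment_of[a] = name
        columns.append(block_vals)
    values = np.concatenate(columns, axis=1)
    matrix = ExpressionMatrix(values, gene_ids, array_ids)
    collection = ExpressionCollection(matrix, ExperimentMap(experiment_of))
    truth = SyntheticTruth(spec.relevant_ids, GenePartition(cat, bg))
    return collection, truth


def dilution_curve(collection: ExpressionCollection, truth: SyntheticTruth,
                   max_noise_experiments: int):
    """Mean |within-category r| as irrelevant experiments are appended.

    Element ``k`` is the mean absolute within-category correlation computed
    over the relevant experiments' arrays plus the first ``k`` irrelevant
    experiments (manifest order).  Quantifies how quickly uninformative
    arrays dilute a planted correlation signal.
    """
    relevant = [e for e in collection.experiment_ids if e in set(truth.relevant_experiments)]
    if not relevant:
        raise ValueError("truth has no relevant experiments")
    irrelevant = [e for e in collection.experiment_ids
                  if e not in set(truth.relevant_experiments)]
    if max_noise_experiments > len(irrelevant):
        raise ValueError(
            f"requested {max_noise_experiments} noise experiments, only "
            f"{len(irrelevant)} available"
        )
    curve = []
    for k in range(max_noise_experiments + 1):
        subset = set(relevant) | set(irrelevant[:k])
        sets = build_correlation_sets(collection, subset, truth.partition)
        curve.append(float(np.mean(np.abs(sets.a_values))))
    return curve


def generate_nested_chain(spec: SyntheticSpec, levels: int):
    """Leaf-to-root chain of nested partitions for the specificity sweep.

    Level 1 is the true category; each subsequent level absorbs one
    background block into the category, emulating progressively broader
    annotation terms that mix the process of interest with unrelated genes.
    Gene ids are determined by the spec, so the chain matches any collection
    generated from the same spec.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    blocks = spec.background_blocks()
    if levels - 1 > len(blocks):
        raise ValueError(
            f"{levels} levels need {levels - 1} background blocks, "
            f"only {len(blocks)} available"
        )
    if levels - 1 == len(blocks):
        raise ValueError("root level would leave the background empty")
    partitions = []
    category = list(spec.category_gene_ids)
    background = list(spec.background_gene_ids)
    partitions.append(GenePartition(tuple(category), tuple(background)))
    for level in range(1, levels):
        absorbed = blocks[level - 1]
        category.extend(absorbed)
        background = [g for g in background if g not in set(absorbed)]
        partitions.append(GenePartition(tuple(category), tuple(background)))
    return partitions
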