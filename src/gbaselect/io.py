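"""Reading, validation and writing of expression matrices, experiment
manifests and gene-set (GMT) files.

The on-disk formats are deliberately plain:

* expression matrix — TSV, header ``gene_id<TAB>arr1<TAB>arr2...``, one row
  per gene, missing values written as ``NA``;
* experiment manifest — two-column TSV ``array_id<TAB>experiment_id``;
* gene sets — standard GMT (set name, description, then gene ids).

All parsers raise :class:`ParseError` with the offending line number so that
malformed inputs are diagnosable.  Missing expression values are represented
as ``NaN`` in the value matrix; downstream correlation code treats them as
pairwise-complete missing data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParseError",
    "ExpressionMatrix",
    "ExperimentMap",
    "ExpressionCollection",
    "GenePartition",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_experiment_manifest",
    "write_experiment_manifest",
    "read_gene_sets",
    "write_gene_sets",
    "make_partition",
]

MISSING_TOKEN = "NA"


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ParseError(f"duplicate {what} {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x arrays matrix of normalized expression values.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` on
    ``array_ids[j]``; missing measurements are ``NaN``.
    """

    values: np.ndarray
    gene_ids: tuple
    array_ids: tuple

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "array_ids", tuple(self.array_ids))
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.array_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.array_ids)} arrays"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.array_ids, "array id")
        if self.values.size:
            dead = np.isnan(self.values).all(axis=0)
            if dead.any():
                bad = self.array_ids[int(np.flatnonzero(dead)[0])]
                raise ValueError(f"array column {bad!r} is entirely missing")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_arrays(self) -> int:
        return len(self.array_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def gene_indices(self, genes) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.fromiter((index[g] for g in genes), dtype=int, count=len(genes))
        except KeyError as exc:
            raise KeyError(f"unknown gene id {exc.args[0]!r}") from None


@dataclass(frozen=True)
class ExperimentMap:
    """Partition of array columns into experiments.

    ``experiment_of`` maps every array id to exactly one experiment id;
    experiment order is first-appearance order in the manifest, and each
    experiment must own at least two arrays (a single array supports no
    correlation downstream).
    """

    experiment_of: dict

    def __post_init__(self):
        object.__setattr__(self, "experiment_of", dict(self.experiment_of))
        counts: dict = {}
        for exp in self.experiment_of.values():
            counts[exp] = counts.get(exp, 0) + 1
        for exp, c in counts.items():
            if c < 2:
                raise ValueError(f"experiment {exp!r} owns only {c} array(s); >= 2 required")
        object.__setattr__(self, "_experiment_ids", tuple(counts))

    @property
    def experiment_ids(self) -> tuple:
        return self._experiment_ids

    @property
    def array_ids(self) -> tuple:
        return tuple(self.experiment_of)

    @property
    def n_experiments(self) -> int:
        return len(self._experiment_ids)

    def arrays_of(self, experiment_id) -> tuple:
        if experiment_id not in self._experiment_ids:
            raise KeyError(f"unknown experiment id {experiment_id!r}")
        return tuple(a for a, e in self.experiment_of.items() if e == experiment_id)


@dataclass(frozen=True)
class ExpressionCollection:
    """An expression matrix together with its experiment structure."""

    matrix: ExpressionMatrix
    experiments: ExperimentMap

    def __post_init__(self):
        if set(self.matrix.array_ids) != set(self.experiments.experiment_of):
            raise ValueError("matrix array ids and manifest array ids differ")

    @property
    def gene_ids(self) -> tuple:
        return self.matrix.gene_ids

    @property
    def experiment_ids(self) -> tuple:
        return self.experiments.experiment_ids

    def column_indices(self, experiment_subset) -> np.ndarray:
        """Column indices of the subset's arrays, in manifest order."""
        subset = set(experiment_subset)
        if not subset:
            raise ValueError("experiment subset must be non-empty")
        unknown = subset - set(self.experiment_ids)
        if unknown:
            raise KeyError(f"unknown experiment id {sorted(unknown)[0]!r}")
        col = {a: j for j, a in enumerate(self.matrix.array_ids)}
        return np.array(
            [col[a] for a, e in self.experiments.experiment_of.items() if e in subset],
            dtype=int,
        )


@dataclass(frozen=True)
class GenePartition:
    """The category-of-interest genes and the background genes.

    Background genes are genes annotated to functional terms other than the
    term of interest; the two sets are disjoint by construction.
    """

    category: tuple
    background: tuple

    def __post_init__(self):
        object.__setattr__(self, "category", tuple(dict.fromkeys(self.category)))
        object.__setattr__(self, "background", tuple(dict.fromkeys(self.background)))
        if set(self.category) & set(self.background):
            overlap = sorted(set(self.category) & set(self.background))[0]
            raise ValueError(f"gene {overlap!r} is in both category and background")
        if len(self.category) < 3:
            raise ValueError(f"category has {len(self.category)} genes; >= 3 required")
        if len(self.background) < 1:
            raise ValueError("background is empty")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = array ids, first column = gene ids)."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].strip():
        raise ParseError(f"{path}: line 1: empty or missing header")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: line 1: malformed header (need gene_id column plus >= 1 array)")
    array_ids = header[1:]
    _check_unique(array_ids, "array id")
    n_cols = len(header)
    gene_ids, rows = [], []
    seen = set()
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise ParseError(
                f"{path}: line {ln}: ragged row ({len(fields)} fields, expected {n_cols})"
            )
        gid = fields[0]
        if gid in seen:
            raise ParseError(f"{path}: line {ln}: duplicate gene id {gid!r}")
        seen.add(gid)
        row = np.empty(n_cols - 1)
        for j, cell in enumerate(fields[1:]):
            if cell == MISSING_TOKEN:
                row[j] = np.nan
            else:
                try:
                    row[j] = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: line {ln}: non-numeric cell {cell!r}"
                    ) from None
        gene_ids.append(gid)
        rows.append(row)
    values = np.array(rows) if rows else np.empty((0, n_cols - 1))
    return ExpressionMatrix(values, gene_ids, array_ids)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix so that ``read_expression_matrix`` round-trips it exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.array_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            cells = (MISSING_TOKEN if np.isnan(v) else repr(float(v)) for v in row)
            fh.write(gid + "\t" + "\t".join(cells) + "\n")


def read_experiment_manifest(path, header: bool = False) -> ExperimentMap:
    """Read a two-column TSV mapping array_id -> experiment_id."""
    mapping: dict = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or (header and ln == 1):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {ln}: expected 2 tab-separated fields, got {len(fields)}"
                )
            array_id, experiment_id = fields
            if array_id in mapping:
                raise ParseError(f"{path}: line {ln}: array {array_id!r} listed twice")
            mapping[array_id] = experiment_id
    try:
        return ExperimentMap(mapping)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_experiment_manifest(experiments: ExperimentMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for array_id, experiment_id in experiments.experiment_of.items():
            fh.write(f"{array_id}\t{experiment_id}\n")


def read_gene_sets(path) -> dict:
    """Read a GMT file into an ordered mapping ``name -> tuple of gene ids``.

    Duplicate genes within one set are dropped with a warning; the gene order
    of first appearance is preserved.
    """
    sets: dict = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {ln}: GMT line needs >= 3 fields "
                    f"(name, description, genes), got {len(fields)}"
                )
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            deduped = tuple(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                warnings.warn(
                    f"{path}: line {ln}: gene set {name!r} contains duplicate genes; deduplicated"
                )
            sets[name] = deduped
    return sets


def write_gene_sets(sets: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write(name + "\tna\t" + "\t".join(genes) + "\n")


def make_partition(sets: dict, term, collection: ExpressionCollection,
                   min_size: int = 25) -> GenePartition:
    """Build the category/background partition for one functional term.

    The category is the term's genes restricted to the collection; the
    background is the union of all *other* sets' genes (restricted to the
    collection) minus the category.  ``min_size`` defaults to 25, the usual
    floor for a category to support a stable t-test and cross-validation,
    but may be lowered for small synthetic studies.
    """
    if term not in sets:
        raise KeyError(f"unknown term {term!r}")
    present = set(collection.gene_ids)
    category = tuple(g for g in sets[term] if g in present)
    if len(category) < min_size:
        raise ValueError(
            f"category {term!r} has {len(category)} genes in the collection; "
            f"minimum is {min_size}"
        )
    cat = set(category)
    background = tuple(
        dict.fromkeys(
            g
            for name, genes in sets.items()
            if name != term
            for g in genes
            if g in present and g not in cat
        )
    )
    return GenePartition(category, background)
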