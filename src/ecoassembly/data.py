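"""Core data containers and I/O.

The pipeline's universal currency is an integer feature-by-sample count
table: features are "species" of the null model (ASVs, genera, or
functional genes) and each read is one individual.  Everything downstream
(rarefaction, diversity partitioning, the individual-shuffle null) relies
on counts staying non-negative integers, so this module validates that at
the boundary and the rest of the code can assume it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "StudyDesign",
    "PhyloDistances",
    "EnvironmentTable",
    "read_count_table",
    "write_count_table",
    "read_design",
    "read_environment_table",
    "read_tree_distances",
    "rarefy",
    "pool_group",
]

LEVEL_ORDER = {"A": 0, "L": 1, "H": 2}


@dataclass
class CountTable:
    """Integer feature-by-sample count matrix.

    Parameters
    ----------
    features : list of str
        Feature identifiers (taxon or gene labels), one per matrix row.
    samples : list of str
        Sample identifiers, one per matrix column.
    counts : ndarray of shape (n_features, n_samples)
        Non-negative integer read counts.
    feature_kind : {"ASV", "genus", "gene"}
        What the features represent; informational only.
    """

    features: list[str]
    samples: list[str]
    counts: np.ndarray
    feature_kind: str = "ASV"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate feature IDs")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")

    # -- convenience accessors -------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def column(self, sample: str) -> np.ndarray:
        return self.counts[:, self.samples.index(sample)]

    def select_samples(self, samples: list[str]) -> "CountTable":
        idx = [self.samples.index(s) for s in samples]
        return CountTable(
            list(self.features), list(samples), self.counts[:, idx], self.feature_kind
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.features, columns=self.samples)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, feature_kind: str = "ASV") -> "CountTable":
        return cls(
            [str(f) for f in df.index],
            [str(s) for s in df.columns],
            df.to_numpy(),
            feature_kind,
        )


@dataclass
class StudyDesign:
    """Sample -> (reactor, treatment level, day) mapping.

    Levels follow the study phases: A (acclimation), L (low organic
    loading), H (high organic loading); arbitrary labels are accepted and
    sorted after the known phases.
    """

    frame: pd.DataFrame  # columns: sample_id, reactor, level, day

    def __post_init__(self) -> None:
        required = {"sample_id", "reactor", "level", "day"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"design missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in design")
        self.frame = self.frame.copy()
        self.frame["day"] = self.frame["day"].astype(int)

    def groups(self) -> list[tuple[tuple[str, int], list[str]]]:
        """(level, day) groups with their sample IDs, sorted by phase then day."""
        out: dict[tuple[str, int], list[str]] = {}
        for row in self.frame.itertuples(index=False):
            out.setdefault((str(row.level), int(row.day)), []).append(row.sample_id)
        return sorted(
            out.items(), key=lambda kv: (LEVEL_ORDER.get(kv[0][0], 99), kv[0][0], kv[0][1])
        )

    def samples_in(self, level: str, day: int) -> list[str]:
        m = (self.frame["level"] == level) & (self.frame["day"] == int(day))
        return list(self.frame.loc[m, "sample_id"])


@dataclass
class PhyloDistances:
    """Tip-to-tip patristic distance matrix from a rooted tree."""

    tips: list[str]
    dist: np.ndarray

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float)
        n = len(self.tips)
        if self.dist.shape != (n, n):
            raise ValueError("distance matrix shape does not match tips")
        if len(set(self.tips)) != n:
            raise ValueError("duplicate tip labels")
        if not np.allclose(self.dist, self.dist.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.dist < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(self.dist), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        self._index = {t: i for i, t in enumerate(self.tips)}

    def indices_of(self, taxa: list[str]) -> np.ndarray:
        missing = [t for t in taxa if t not in self._index]
        if missing:
            raise KeyError(f"taxa absent from tree: {missing[:10]}")
        return np.array([self._index[t] for t in taxa], dtype=np.intp)


@dataclass
class EnvironmentTable:
    """Per-sample numeric environmental measurements (samples x variables)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("environment table must be numeric and finite")

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    @property
    def variables(self) -> list[str]:
        return [str(v) for v in self.frame.columns]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_count_table(
    path, orientation: str = "features", feature_kind: str = "ASV", sep: str = "\t"
) -> CountTable:
    """Read a delimited count table.

    ``orientation="features"`` means features are rows (the default layout);
    ``"samples"`` means samples are rows and the table is transposed on read.
    Non-integer or negative cells raise a ValueError naming the offending
    row and column.
    """
    if orientation not in ("features", "samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if orientation == "samples":
        df = df.T
    mat = np.empty(df.shape, dtype=np.int64)
    values = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = values[i, j]
            try:
                v = int(str(cell))
            except (TypeError, ValueError):
                raise ValueError(
                    f"cell ({df.index[i]!r}, {df.columns[j]!r}) is not an "
                    f"integer: {cell!r}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"cell ({df.index[i]!r}, {df.columns[j]!r}) is negative: {v}"
                )
            mat[i, j] = v
    return CountTable(
        [str(f) for f in df.index], [str(s) for s in df.columns], mat, feature_kind
    )


def write_count_table(table: CountTable, path, orientation: str = "features", sep: str = "\t") -> None:
    df = table.to_dataframe()
    if orientation == "samples":
        df = df.T
    elif orientation != "features":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=sep)


def read_design(path, sep: str = "\t") -> StudyDesign:
    return StudyDesign(pd.read_csv(path, sep=sep, dtype={"sample_id": str, "reactor": str, "level": str}))


def read_environment_table(path, sep: str = "\t") -> EnvironmentTable:
    return EnvironmentTable(pd.read_csv(path, sep=sep, index_col=0))


def read_tree_distances(path) -> PhyloDistances:
    """Patristic (path-length) tip-to-tip distances from a Newick tree."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return tree_distances(tree)


def tree_distances(tree: dendropy.Tree) -> PhyloDistances:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has edges without branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return PhyloDistances(labels, d)


def tree_distances_from_string(newick: str) -> PhyloDistances:
    return tree_distances(dendropy.Tree.get(data=newick, schema="newick"))


# ---------------------------------------------------------------------------
# Depth normalization
# ---------------------------------------------------------------------------


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to ``depth`` reads without replacement.

    A single multivariate-hypergeometric draw per sample (one random
    subsample, not an average over draws) so counts stay integers for the
    individual-shuffle null model downstream.  Deterministic given ``seed``.
    """
    depth = int(depth)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_totals()
    short = [s for s, t in zip(table.samples, totals) if t < depth]
    if short:
        raise ValueError(f"samples with fewer than {depth} reads: {short}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for j in range(len(table.samples)):
        col = table.counts[:, j]
        if totals[j] == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth, method="marginals")
    return CountTable(list(table.features), list(table.samples), out, table.feature_kind)


def pool_group(table: CountTable, design: StudyDesign, level: str, day: int) -> np.ndarray:
    """Element-wise sum of the (level, day) group's sample columns.

    The pooled vector is the gamma-scale community whose individuals the
    null model redistributes.
    """
    samples = design.samples_in(level, day)
    if not samples:
        raise ValueError(f"no samples in group ({level!r}, {day})")
    idx = [table.samples.index(s) for s in samples]
    return table.counts[:, idx].sum(axis=1)
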