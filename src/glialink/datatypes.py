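"""Core containers shared across the pipeline.

The pipeline moves a gene x sample count matrix (plus per-sample design
metadata) through normalization, differential-expression filtering, set
decomposition and ligand-receptor scoring.  The containers here are thin,
validated wrappers around :class:`pandas.DataFrame` so that every stage can
rely on the same invariants: unique gene and sample ids, metadata covering
every sample, and an explicit record of which transform produced an
expression matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The four pairwise comparisons of the OPC study design
#: (genotype: WT vs TNFR2-knockout; condition: non-stimulated vs cytokine
#: stimulated).
COMPARISONS: tuple[str, ...] = (
    "KO-NS vs WT-NS",
    "WT-St vs WT-NS",
    "KO-St vs KO-NS",
    "KO-St vs WT-St",
)

#: Recognised expression transforms; "linear" quantities may be
#: log2-transformed exactly once.
LINEAR_TRANSFORMS = ("CPM", "FPKM")
LOG_TRANSFORMS = ("log2CPM", "logFPKM")

METADATA_COLUMNS = ("cell_type", "genotype", "condition")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} ids: {dups[:5]}")


def _check_metadata(metadata: pd.DataFrame, samples: pd.Index) -> pd.DataFrame:
    missing_cols = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing_cols:
        raise ValueError(f"metadata lacks required columns: {missing_cols}")
    missing = samples.difference(metadata.index)
    if len(missing):
        raise ValueError(f"metadata does not cover samples: {missing.tolist()[:5]}")
    return metadata.loc[samples]


@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-sample design metadata.

    Parameters
    ----------
    values
        Non-negative integer counts, genes as rows, samples as columns.
    metadata
        One row per sample (indexed by sample id) with columns
        ``cell_type``, ``genotype``, ``condition``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.metadata = _check_metadata(self.metadata, self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.values[list(samples)], self.metadata)


@dataclass
class ExpressionMatrix:
    """Normalized expression values with the transform that produced them.

    ``transform`` is one of CPM, log2CPM, FPKM, logFPKM; ``pseudocount``
    records the offset used by the log transform (``None`` for linear
    quantities).
    """

    values: pd.DataFrame
    transform: str
    pseudocount: float | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.transform not in LINEAR_TRANSFORMS + LOG_TRANSFORMS:
            raise ValueError(f"unknown transform: {self.transform!r}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if self.is_log and not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("log-transformed values must be finite")
        if self.metadata is not None:
            self.metadata = _check_metadata(self.metadata, self.values.columns)

    @property
    def is_log(self) -> bool:
        return self.transform in LOG_TRANSFORMS

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class GeneAnnotation:
    """Per-gene transcript length in base pairs (the FPKM divisor)."""

    lengths: pd.Series  # index: gene id, values: length_bp

    def __post_init__(self) -> None:
        _check_unique(self.lengths.index, "gene")
        if (self.lengths < 1).any():
            raise ValueError("gene lengths must be >= 1 bp")
        self.lengths = self.lengths.astype(np.int64)
        self.lengths.name = "length_bp"

    def to_frame(self) -> pd.DataFrame:
        return self.lengths.rename_axis("gene").reset_index()


@dataclass
class LRPairTable:
    """Ordered (ligand gene, receptor gene) pairs defining the tested space."""

    pairs: pd.DataFrame  # columns: ligand, receptor[, name]

    def __post_init__(self) -> None:
        for col in ("ligand", "receptor"):
            if col not in self.pairs.columns:
                raise ValueError(f"pair table lacks column {col!r}")
            if (self.pairs[col].astype(str).str.len() == 0).any():
                raise ValueError(f"empty {col} id in pair table")
        if self.pairs.duplicated(subset=["ligand", "receptor"]).any():
            raise ValueError("duplicate (ligand, receptor) rows")
        if "name" not in self.pairs.columns:
            self.pairs = self.pairs.assign(
                name=self.pairs["ligand"] + "_" + self.pairs["receptor"]
            )

    def __len__(self) -> int:
        return len(self.pairs)

    def as_tuples(self) -> list[tuple[str, str]]:
        return list(zip(self.pairs["ligand"], self.pairs["receptor"]))


@dataclass
class GroundTruth:
    """Planted effects of a simulation run.

    ``de_genes`` has one row per (gene, comparison) with the planted
    direction and log2 fold change; ``active_pairs`` / ``null_pairs``
    partition the emitted ligand-receptor pair list.
    """

    de_genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene", "direction", "log2fc", "comparison"]
        )
    )
    active_pairs: list[tuple[str, str]] = field(default_factory=list)
    null_pairs: list[tuple[str, str]] = field(default_factory=list)

    def up_genes(self, comparison: str) -> set[str]:
        t = self.de_genes
        return set(t.loc[(t.direction == "up") & (t.comparison == comparison), "gene"])

    def down_genes(self, comparison: str) -> set[str]:
        t = self.de_genes
        return set(
            t.loc[(t.direction == "down") & (t.comparison == comparison), "gene"]
        )
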