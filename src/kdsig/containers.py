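"""In-memory containers for the pipeline's tabular data.

Counts, annotations and metadata travel together: a :class:`CountMatrix`
bundles the integer gene x sample matrix with a gene annotation table
(symbol, biotype) and a sample metadata table (cell line, condition,
shRNA, replicate), index-aligned by construction. The normalized
counterpart, :class:`ExpressionMatrix`, carries log2(CPM + 1) values on
whatever gene subset is current (typically protein-coding only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError

GENE_ANNOTATION_COLUMNS = ("symbol", "biotype")
SAMPLE_METADATA_COLUMNS = ("cell_line", "condition", "shRNA", "replicate")


def _check_aligned(values: pd.DataFrame, genes: pd.DataFrame, samples: pd.DataFrame) -> None:
    problems = []
    if not values.index.equals(genes.index):
        problems.append("gene annotation index does not match matrix rows")
    if not values.columns.equals(samples.index):
        missing = sorted(set(values.columns) ^ set(samples.index))
        problems.append(
            "sample metadata does not match matrix columns; offenders: " + ", ".join(map(str, missing))
        )
    for col in GENE_ANNOTATION_COLUMNS:
        if col not in genes.columns:
            problems.append(f"gene annotation missing column {col!r}")
    for col in SAMPLE_METADATA_COLUMNS:
        if col not in samples.columns:
            problems.append(f"sample metadata missing column {col!r}")
    if problems:
        raise FormatError("; ".join(problems))


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus gene and sample annotations."""

    counts: pd.DataFrame
    genes: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        _check_aligned(self.counts, self.genes, self.samples)
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("counts matrix contains non-integer values")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("counts matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        """Per-sample total counts over all features."""
        return self.counts.sum(axis=0)


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample matrix in log2(CPM + 1) units."""

    values: pd.DataFrame
    genes: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        _check_aligned(self.values, self.genes, self.samples)
        if (self.values.to_numpy() < 0).any():
            raise FormatError("log2(CPM + 1) values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = pd.Index(gene_ids)
        missing = idx.difference(self.values.index)
        if len(missing):
            raise KeyError(f"genes absent from matrix: {', '.join(map(str, missing[:10]))}")
        return ExpressionMatrix(self.values.loc[idx], self.genes.loc[idx], self.samples)

    def cpm(self) -> pd.DataFrame:
        """Recover the CPM scale exactly: 2**value - 1."""
        return np.exp2(self.values) - 1.0
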