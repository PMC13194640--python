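"""Normalization and principal component analysis.

Counts are normalized per sample to counts per million (CPM) over ALL
features, shifted by a pseudocount of one and log2-transformed; only
then is the matrix restricted to protein-coding genes. PCA treats
samples as observations and genes as variables: values are mean-centered
per gene across all samples and decomposed by SVD, with no variance
scaling. The cell-line-adjusted variant first removes each gene's
within-line mean, so baseline differences between lines cannot dominate
the leading components and condition structure becomes visible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix
from .errors import ConfigError

log = logging.getLogger(__name__)


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million: each column scaled to sum to 1e6.

    Library size is the column total over all features, taken before any
    biotype restriction.
    """
    lib = counts.library_sizes()
    zero = lib.index[lib == 0]
    if len(zero):
        raise ConfigError("zero library size for sample(s): " + ", ".join(zero))
    return counts.counts.div(lib, axis=1) * 1e6


def log2_cpm(cpm_matrix: pd.DataFrame, genes: pd.DataFrame, samples: pd.DataFrame) -> ExpressionMatrix:
    """Elementwise log2(CPM + 1)."""
    return ExpressionMatrix(np.log2(cpm_matrix + 1.0), genes, samples)


def normalize(counts: CountMatrix) -> ExpressionMatrix:
    """CPM then log2(CPM + 1), over all features."""
    return log2_cpm(cpm(counts), counts.genes, counts.samples)


def filter_protein_coding(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Restrict to rows annotated protein_coding, preserving order."""
    keep = expr.genes["biotype"] == "protein_coding"
    n_kept = int(keep.sum())
    log.info("protein-coding filter: retained %d of %d genes", n_kept, len(keep))
    if n_kept == 0:
        warnings.warn("no protein_coding genes retained", stacklevel=2)
    return ExpressionMatrix(expr.values.loc[keep], expr.genes.loc[keep], expr.samples)


@dataclass
class PcaResult:
    """SVD-based principal components of a gene x sample matrix.

    ``scores`` are sample x component projections of the (per-gene
    centered) matrix; ``loadings`` gene x component directions;
    fractions of explained variance are non-increasing and sum to <= 1.
    The sign of each component is fixed so its largest-magnitude loading
    is positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray


def pca(expr) -> PcaResult:
    """Mean-center each gene across samples and decompose by SVD.

    Accepts an :class:`ExpressionMatrix` or a bare gene x sample
    DataFrame (the latter is used for pre-adjusted matrices that are no
    longer on the log2(CPM + 1) scale).
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    X = values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ConfigError("PCA needs at least 2 samples")
    if np.isnan(X).any():
        raise ConfigError("PCA input contains missing values")
    centered = X - X.mean(axis=1, keepdims=True)
    # observations = samples: decompose centered.T (samples x genes)
    U, s, Vt = np.linalg.svd(centered.T, full_matrices=False)
    # deterministic orientation: largest-|loading| entry positive per component
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip
    Vt = Vt * flip[:, None]
    scores = U * s
    total = (s ** 2).sum()
    frac = (s ** 2) / total if total > 0 else np.zeros_like(s)
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=values.columns, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=values.index, columns=comp),
        explained_variance_fraction=frac,
    )


def center_within_lines(expr: ExpressionMatrix) -> pd.DataFrame:
    """Subtract each gene's mean within each cell line.

    Every gene's within-line mean is exactly zero afterwards, making the
    result invariant to any per-line per-gene additive shift. Returns a
    bare DataFrame because the result is no longer on the CPM scale.
    """
    labels = expr.samples["cell_line"]
    sizes = labels.value_counts()
    lonely = sizes.index[sizes < 2]
    if len(lonely):
        raise ConfigError(
            "cell line(s) with a single sample (adjusted values would be "
            "identically zero): " + ", ".join(map(str, lonely))
        )
    adjusted = expr.values.copy()
    for line in sizes.index:
        cols = labels.index[labels == line]
        block = adjusted[cols]
        adjusted[cols] = block.sub(block.mean(axis=1), axis=0)
    return adjusted


def cell_line_adjusted_pca(expr: ExpressionMatrix) -> PcaResult:
    """PCA on the within-line mean-centered matrix."""
    return pca(center_within_lines(expr))
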