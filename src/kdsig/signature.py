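"""Cross-model core signature and heatmap matrices.

The core signature keeps protein-coding genes whose knockdown response
is concordant across both cell-line models: |log2FC| >= threshold
(inclusive) in each line and the same direction of change, irrespective
of any FDR cut. Heatmap matrices are gene-wise z-scores (sample SD,
n - 1 denominator), with rows ordered by the leaf order of an
average-linkage (UPGMA) dendrogram over Euclidean distances. Focused
modules are curated symbol lists; their display matrix is the z-scored
per-condition mean of log2-CPM values in a fixed column order
(line 1 NT, KD1, KD2, then line 2 NT, KD1, KD2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .containers import ExpressionMatrix
from .errors import ConfigError
from .io import GeneSetCollection

log = logging.getLogger(__name__)

# Curated seven-gene modules pairing Hallmark membership with core-signature
# genes, one per biological axis of the knockdown response.
DEFAULT_MODULES = {
    "G2M_DNA_REPAIR": ("AURKB", "SLC7A5", "TP53", "MLH1", "NEK6", "CKS1B", "RPS3A"),
    "TNFA_NFKB": ("NFKB1", "SDC4", "CXCL2", "PLK2", "BIRC3", "CD83", "TNFAIP3"),
    "IL6_INFLAMMATORY": ("HMOX1", "IL6", "EREG", "SERPINE1", "IL6R", "CCL17", "PANX1"),
    "EMT_ADHESION": ("SERPINE1", "FERMT2", "ARPC3", "SDC4", "TGFBR3", "AKT3", "EGFR"),
}


@dataclass
class CoreSignature:
    """Concordantly regulated genes with per-line fold changes.

    ``table`` is indexed by gene id with columns symbol, direction
    (up/down), and one log2fc column per line.
    """

    table: pd.DataFrame
    lfc_threshold: float

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())

    @property
    def gene_ids(self) -> list:
        return self.table.index.tolist()

    @property
    def symbols(self) -> list:
        return self.table["symbol"].tolist()


def core_signature(de1: pd.DataFrame, de2: pd.DataFrame,
                   lfc_threshold: float = 1.0) -> CoreSignature:
    """Select genes concordantly changed in both DE tables.

    Membership: |log2fc| >= lfc_threshold in BOTH tables (inclusive
    boundary) and identical sign. Tables are intersected on gene id;
    symmetric in its two arguments.
    """
    if lfc_threshold <= 0:
        raise ConfigError("lfc_threshold must be positive")
    common = de1.index.intersection(de2.index)
    if len(common) == 0:
        raise ConfigError("DE tables share no gene ids")
    l1 = de1.loc[common, "log2fc"].to_numpy()
    l2 = de2.loc[common, "log2fc"].to_numpy()
    keep = (np.abs(l1) >= lfc_threshold) & (np.abs(l2) >= lfc_threshold) \
        & (np.sign(l1) == np.sign(l2))
    line1 = str(de1["cell_line"].iloc[0]) if "cell_line" in de1 else "line1"
    line2 = str(de2["cell_line"].iloc[0]) if "cell_line" in de2 else "line2"
    table = pd.DataFrame(
        {
            "symbol": de1.loc[common, "symbol"].to_numpy(),
            "direction": np.where(l1 > 0, "up", "down"),
            f"log2fc_{line1}": l1,
            f"log2fc_{line2}": l2,
        },
        index=common,
    )[keep]
    sig = CoreSignature(table, lfc_threshold)
    log.info("core signature: %d genes (%d up, %d down) at |log2FC| >= %g",
             len(sig), sig.n_up, sig.n_down, lfc_threshold)
    return sig


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Gene-wise z-scores: subtract the row mean, divide by row SD (n-1).

    Constant rows become all zeros with a warning rather than NaN.
    """
    if values.shape[1] < 2:
        raise ConfigError("z-scoring needs at least 2 columns")
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant row(s) z-scored to zeros",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[constant, :] = 0.0
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def cluster_gene_order(z: pd.DataFrame) -> list:
    """Leaf order of an average-linkage dendrogram over Euclidean rows.

    Uses the standard recursive left-to-right ordering of the linkage
    tree; no optimal-leaf reordering, so the order is deterministic.
    """
    if z.shape[0] < 2:
        raise ConfigError("clustering needs at least 2 rows")
    Z = linkage(pdist(z.to_numpy(dtype=float), metric="euclidean"), method="average")
    return z.index[leaves_list(Z)].tolist()


def signature_heatmap(expr: ExpressionMatrix, signature: CoreSignature) -> pd.DataFrame:
    """Z-scored log2-CPM of signature genes, rows in dendrogram order."""
    sub = expr.subset_genes(signature.gene_ids)
    z = zscore_rows(sub.values)
    return z.loc[cluster_gene_order(z)]


def condition_order(samples: pd.DataFrame, lines=None, conditions=None) -> list:
    """Fixed display order: line 1 conditions then line 2 conditions."""
    if lines is None:
        lines = list(dict.fromkeys(samples["cell_line"]))
    if conditions is None:
        conditions = list(dict.fromkeys(samples["condition"]))
    return [f"{ln}_{cond}" for ln in lines for cond in conditions]


def module_condition_means(expr: ExpressionMatrix, module_genes,
                           lines=None, conditions=None,
                           by_symbol: bool = True) -> pd.DataFrame:
    """Gene x condition matrix of z-scored condition-mean log2-CPM.

    Replicate values are averaged within each (line, condition) cell and
    the resulting means z-scored per gene across the fixed column order.
    ``module_genes`` are symbols by default (curated lists are symbol
    based); missing genes are an error.
    """
    if by_symbol:
        lut = pd.Series(expr.genes.index, index=expr.genes["symbol"])
        missing = [g for g in module_genes if g not in lut.index]
        if missing:
            raise KeyError("module genes absent from matrix: " + ", ".join(missing))
        gene_ids = lut[list(module_genes)].tolist()
        labels = list(module_genes)
    else:
        gene_ids = list(module_genes)
        labels = gene_ids
    sub = expr.subset_genes(gene_ids)
    meta = sub.samples
    cols = condition_order(meta, lines, conditions)
    means = {}
    for col in cols:
        line, cond = col.rsplit("_", 1)
        sel = meta.index[(meta["cell_line"] == line) & (meta["condition"] == cond)]
        if len(sel) == 0:
            raise ConfigError(f"no samples for condition column {col!r}")
        means[col] = sub.values[sel].mean(axis=1)
    mat = pd.DataFrame(means)[cols]
    mat.index = labels
    return zscore_rows(mat)


def intersect_with_sets(signature: CoreSignature, sets: GeneSetCollection) -> dict:
    """Per gene set: the signature members it contains, with directions."""
    by_symbol = signature.table.set_index("symbol")["direction"]
    out = {}
    for name in sets.names():
        members = sets.members(name)
        hits = [s for s in by_symbol.index if s in members]
        out[name] = [(s, by_symbol[s]) for s in hits]
    return out
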