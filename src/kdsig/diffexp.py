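"""Per-cell-line differential expression of combined knockdown vs control.

For each protein-coding gene the contrast pools both knockdown shRNAs
(KD1 + KD2) against the nontargeting control within one cell line. The
fold change is computed on the CPM scale from arithmetic group means
with a 0.5-count offset, log2((mean_KD + 0.5) / (mean_NT + 0.5)), which
keeps it finite for any observed means; significance comes from a
two-sided Welch t test on the log2(CPM + 1) values; and the preranked
GSEA input statistic is the signed -log10 p, signed by the fold change.

p-values that underflow to zero (extreme t) are floored at the smallest
positive double so the signed -log10 p stays finite; genes where both
group variances vanish but the means differ get that same floor and are
flagged in the ``degenerate`` column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .errors import ConfigError

P_FLOOR = float(np.finfo(float).tiny)


def log2_fold_change(mean_nt, mean_kd, offset: float = 0.5):
    """log2((mean_kd + offset) / (mean_nt + offset)) on CPM-scale means."""
    mean_nt = np.asarray(mean_nt, dtype=float)
    mean_kd = np.asarray(mean_kd, dtype=float)
    if (mean_nt < 0).any() or (mean_kd < 0).any():
        raise ValueError("CPM means must be nonnegative")
    return np.log2((mean_kd + offset) / (mean_nt + offset))


def _welch_arrays(a: np.ndarray, b: np.ndarray):
    """Vectorized Welch t over rows of a (genes x n_a) and b (genes x n_b).

    Returns (t, df, p, degenerate). Zero-variance-in-both-groups rows:
    equal means give t=0, p=1; unequal means give p floored at the
    machine minimum with t = +/-inf, flagged degenerate.
    """
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ConfigError("Welch t test needs >=2 observations per group")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sa, sb = va / na, vb / nb
    denom = np.sqrt(sa + sb)
    diff = ma - mb
    both_zero = (va == 0) & (vb == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        df = (sa + sb) ** 2 / (sa ** 2 / (na - 1) + sb ** 2 / (nb - 1))
    degenerate = both_zero & (diff != 0)
    with np.errstate(invalid="ignore"):
        t = np.where(both_zero, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    df = np.where(both_zero, na + nb - 2.0, df)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(both_zero & (diff == 0), 1.0, p)
    p = np.clip(p, P_FLOOR, 1.0)
    return t, df, p, degenerate


def welch_t_test(a, b):
    """Two-sided Welch t test for two samples; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)[None, :]
    b = np.asarray(b, dtype=float)[None, :]
    t, df, p, _ = _welch_arrays(a, b)
    return float(t[0]), float(df[0]), float(p[0])


def rank_scores(log2fc: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Signed -log10 p; zero when p == 1 regardless of fold-change sign."""
    return np.sign(log2fc) * (-np.log10(np.clip(p, P_FLOOR, 1.0)))


def de_table(expr: ExpressionMatrix, cell_line: str, nt_label: str = "NT",
             offset: float = 0.5) -> pd.DataFrame:
    """Knockdown-vs-control differential expression for one cell line.

    One row per gene of ``expr`` (pass the protein-coding subset):
    CPM-scale group means, offset log2 fold change, Welch t/df/p on the
    log2-CPM values, and the signed -log10 p rank score.
    """
    meta = expr.samples
    in_line = meta["cell_line"] == cell_line
    if not in_line.any():
        raise ConfigError(f"no samples for cell line {cell_line!r}")
    nt_cols = meta.index[in_line & (meta["condition"] == nt_label)]
    kd_cols = meta.index[in_line & (meta["condition"] != nt_label)]
    if len(nt_cols) < 2 or len(kd_cols) < 2:
        raise ConfigError(
            f"cell line {cell_line!r}: need >=2 {nt_label} and >=2 knockdown samples "
            f"(got {len(nt_cols)} and {len(kd_cols)})"
        )
    logv = expr.values
    cpm_vals = expr.cpm()
    mean_nt = cpm_vals[nt_cols].mean(axis=1).to_numpy()
    mean_kd = cpm_vals[kd_cols].mean(axis=1).to_numpy()
    lfc = log2_fold_change(mean_nt, mean_kd, offset=offset)
    t, df, p, degenerate = _welch_arrays(
        logv[kd_cols].to_numpy(float), logv[nt_cols].to_numpy(float)
    )
    return pd.DataFrame(
        {
            "symbol": expr.genes["symbol"].to_numpy(),
            "mean_cpm_nt": mean_nt,
            "mean_cpm_kd": mean_kd,
            "log2fc": lfc,
            "t": t,
            "df": df,
            "p": p,
            "rank_score": rank_scores(lfc, p),
            "degenerate": degenerate,
            "cell_line": cell_line,
        },
        index=expr.values.index,
    )


def volcano_table(de: pd.DataFrame, p_threshold: float = 0.01) -> pd.DataFrame:
    """Annotate a DE table with -log10 p and a strict p < threshold flag.

    No multiplicity adjustment: the flag reflects the raw p-value.
    """
    if p_threshold <= 0:
        raise ConfigError("p_threshold must be positive")
    out = de.copy()
    out["neg_log10_p"] = -np.log10(np.clip(out["p"].to_numpy(), P_FLOOR, 1.0))
    out["significant"] = out["p"].to_numpy() < p_threshold
    return out
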