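"""Synthetic data with the statistical structure the pipeline assumes.

Two generators:

* :func:`simulate_counts` draws negative-binomial RNA-seq counts for a
  multi-cell-line knockdown experiment: per-gene baseline expression,
  per-gene per-line baseline shifts (the "cell line effect" that the
  adjusted PCA removes), variable library sizes, and a planted knockdown
  program of genes whose mean is shifted multiplicatively (2**log2fc) in
  the knockdown conditions. Nulls, line-private and concordant planted
  genes let every downstream stage be tested for recovery.

* :func:`simulate_survival` draws cohorts whose hazard depends
  log-linearly on one gene's expression, h(t | x) = h0 * exp(beta * x),
  with independent exponential censoring — the generating model under
  which hazard-ratio recovery and log-rank null calibration are checked.

Both are deterministic given their config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .errors import ConfigError

DEFAULT_CONDITIONS = ("NT", "KD1", "KD2")


@dataclass(frozen=True)
class PlantedGene:
    """A gene with a prescribed knockdown effect per cell line.

    ``effect_log2fc_per_line`` holds one log2 fold change per line, in
    line order; 0 means the gene is null in that line. A gene is
    "planted concordant" iff |effect| >= 1 in every line with identical
    sign.
    """

    gene_id: str
    effect_log2fc_per_line: tuple
    biotype: str = "protein_coding"
    symbol: str | None = None

    def is_concordant(self, threshold: float = 1.0) -> bool:
        e = np.asarray(self.effect_log2fc_per_line, dtype=float)
        return bool((np.abs(e) >= threshold).all() and (len(set(np.sign(e))) == 1))


@dataclass(frozen=True)
class SimCountConfig:
    """Parameters of the count simulator.

    ``baseline_log_mean_range`` is the uniform range of per-gene log2
    relative expression; ``dispersion`` is the NB size parameter k
    (variance = m + m**2 / k); ``line_effect_sd`` the SD of the
    per-gene per-line additive shift on the log2 scale.
    """

    n_genes: int
    n_lines: int = 2
    conditions: tuple = DEFAULT_CONDITIONS
    n_reps: int = 2
    baseline_log_mean_range: tuple = (0.0, 9.0)
    line_effect_sd: float = 0.5
    dispersion: float = 10.0
    library_size_range: tuple = (800_000, 1_200_000)
    program: tuple = ()
    noncoding_fraction: float = 0.15
    line_labels: tuple | None = None
    seed: int = 0

    def validate(self) -> None:
        v = []
        if self.n_genes <= 0:
            v.append("n_genes must be positive")
        if self.n_lines <= 0:
            v.append("n_lines must be positive")
        if self.n_reps <= 0:
            v.append("n_reps must be positive")
        if len(self.conditions) < 2:
            v.append("need at least two conditions")
        if len(set(self.conditions)) != len(self.conditions):
            v.append("condition labels must be unique")
        if self.dispersion <= 0:
            v.append("dispersion must be positive")
        if self.line_effect_sd < 0:
            v.append("line_effect_sd must be nonnegative")
        lo, hi = self.baseline_log_mean_range
        if hi < lo:
            v.append("baseline_log_mean_range must be a nonempty interval")
        llo, lhi = self.library_size_range
        if llo <= 0 or lhi < llo:
            v.append("library_size_range must be a positive interval")
        if not 0 <= self.noncoding_fraction < 1:
            v.append("noncoding_fraction must be in [0, 1)")
        if self.line_labels is not None and len(self.line_labels) != self.n_lines:
            v.append("line_labels length must equal n_lines")
        if len(self.program) > self.n_genes:
            v.append("program larger than n_genes")
        for g in self.program:
            if len(g.effect_log2fc_per_line) != self.n_lines:
                v.append(f"planted gene {g.gene_id}: needs one effect per line")
        ids = [g.gene_id for g in self.program]
        if len(set(ids)) != len(ids):
            v.append("duplicate gene ids in program")
        if v:
            raise ConfigError(v)

    @property
    def n_samples(self) -> int:
        return self.n_lines * len(self.conditions) * self.n_reps

    @property
    def lines(self) -> tuple:
        if self.line_labels is not None:
            return tuple(self.line_labels)
        return tuple(f"L{i + 1}" for i in range(self.n_lines))


def simulate_counts(config: SimCountConfig) -> CountMatrix:
    """Draw a seeded NB count matrix with the configured planted program.

    Counts for gene g in sample j are NB with mean lib_j * p_gj, where
    p_gj is gene g's share of sample j's relative expression; knockdown
    effects multiply the relative expression by 2**effect in the KD
    conditions, so planted log2 fold changes survive CPM normalization.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_genes
    n_planted = len(config.program)
    gene_ids = [g.gene_id for g in config.program]
    gene_ids += [f"SIMG{i:06d}" for i in range(n - n_planted)]
    symbols = [g.symbol if g.symbol is not None else f"SYM_{g.gene_id}"
               for g in config.program]
    symbols += [f"SYM_{gid}" for gid in gene_ids[n_planted:]]

    biotypes = np.array(["protein_coding"] * n, dtype=object)
    for i, g in enumerate(config.program):
        biotypes[i] = g.biotype
    n_noncoding = int(round((n - n_planted) * config.noncoding_fraction))
    if n_noncoding:
        biotypes[n - n_noncoding:] = "lncRNA"

    base = rng.uniform(*config.baseline_log_mean_range, size=n)
    line_shift = rng.normal(0.0, config.line_effect_sd, size=(n, config.n_lines))

    effects = np.zeros((n, config.n_lines))
    for i, g in enumerate(config.program):
        effects[i] = np.asarray(g.effect_log2fc_per_line, dtype=float)

    lines = config.lines
    sample_rows = []
    for li, line in enumerate(lines):
        for cond in config.conditions:
            for rep in range(1, config.n_reps + 1):
                sample_rows.append((f"{line}_{cond}_R{rep}", line, cond,
                                    "shNT" if cond == "NT" else f"sh{cond}", rep, li))
    sample_ids = [r[0] for r in sample_rows]
    samples = pd.DataFrame(
        [r[1:5] for r in sample_rows], index=pd.Index(sample_ids, name="sample"),
        columns=["cell_line", "condition", "shRNA", "replicate"],
    )

    lib_sizes = rng.integers(config.library_size_range[0],
                             config.library_size_range[1] + 1,
                             size=len(sample_ids))

    counts = np.zeros((n, len(sample_ids)), dtype=np.int64)
    k = float(config.dispersion)
    for j, row in enumerate(sample_rows):
        _, _, cond, _, _, li = row
        log_rel = base + line_shift[:, li]
        if cond != "NT":
            log_rel = log_rel + effects[:, li]
        rel = np.exp2(log_rel)
        mean = lib_sizes[j] * rel / rel.sum()
        # NB(mean m, size k): p = k / (k + m); m == 0 gives a point mass at 0
        with np.errstate(divide="ignore"):
            p = k / (k + mean)
        counts[:, j] = np.where(mean > 0, rng.negative_binomial(k, np.clip(p, 1e-12, 1.0)), 0)

    genes = pd.DataFrame(
        {"symbol": symbols, "biotype": biotypes},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    mat = pd.DataFrame(counts, index=genes.index, columns=samples.index)
    return CountMatrix(mat, genes, samples)


@dataclass(frozen=True)
class SimSurvivalConfig:
    """Parameters of the exponential proportional-hazards cohort simulator."""

    n_subjects: int
    baseline_hazard: float = 0.02
    log_hr_per_unit: float = 0.0
    censor_rate: float = 0.01
    expression_dist: tuple = (0.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        v = []
        if self.n_subjects <= 0:
            v.append("n_subjects must be positive")
        if self.baseline_hazard <= 0:
            v.append("baseline_hazard must be positive")
        if self.censor_rate <= 0:
            v.append("censor_rate must be positive")
        if self.expression_dist[1] < 0:
            v.append("expression SD must be nonnegative")
        if v:
            raise ConfigError(v)


def simulate_survival(config: SimSurvivalConfig, gene: str = "GENE") -> pd.DataFrame:
    """Draw a cohort of (time, event, expression) rows.

    Event times are exponential with rate h0 * exp(beta * x); censoring
    is an independent exponential clock; the observed time is the
    minimum of the two and the event flag marks which fired first.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mu, sd = config.expression_dist
    x = rng.normal(mu, sd, size=config.n_subjects)
    rate = config.baseline_hazard * np.exp(config.log_hr_per_unit * x)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.exponential(1.0 / config.censor_rate, size=config.n_subjects)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(config.n_subjects)],
        "time": time,
        "event": event,
        gene: x,
    })
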