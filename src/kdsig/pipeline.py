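"""End-to-end orchestration: simulate/ingest -> normalize -> PCA -> DE ->
core signature -> GSEA -> module matrices, with a fixed output layout
and a run manifest.

A run is driven by a :class:`PipelineConfig` (buildable from a YAML
file). Outputs land in one directory per run with a subdirectory per
stage, and ``manifest.json`` records the config echo, library versions,
derived stage seeds, timings, and the gene counts at every filter so
the run can be audited against its own intermediate files. A single
global seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence`` so each stage is reproducible in
isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexp import de_table, volcano_table
from .errors import ConfigError, KdsigError
from .expression import cell_line_adjusted_pca, filter_protein_coding, normalize, pca
from .gsea import GseaParams, build_rank_file, gsea_preranked
from .io import (GeneSetCollection, read_counts, read_gmt, write_counts,
                 write_rnk)
from .signature import (DEFAULT_MODULES, core_signature, module_condition_means,
                        signature_heatmap)
from .simulate import PlantedGene, SimCountConfig, simulate_counts

log = logging.getLogger(__name__)


class PipelineStageError(KdsigError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    simulate: SimCountConfig | None = None
    counts_path: str | None = None
    annotation_path: str | None = None
    metadata_path: str | None = None
    nt_label: str = "NT"
    lfc_threshold: float = 1.0
    volcano_p: float = 0.01
    gsea: GseaParams = field(default_factory=GseaParams)
    gmt_paths: tuple = ()
    modules: dict = field(default_factory=lambda: dict(DEFAULT_MODULES))

    def validate(self) -> None:
        v = []
        if self.simulate is None:
            for name in ("counts_path", "annotation_path", "metadata_path"):
                p = getattr(self, name)
                if p is None:
                    v.append(f"either a simulate config or {name} is required")
                elif not Path(p).exists():
                    v.append(f"{name}: no such file: {p}")
        else:
            try:
                self.simulate.validate()
            except ConfigError as e:
                v.extend(f"simulate.{msg}" for msg in e.violations)
        if self.lfc_threshold <= 0:
            v.append("lfc_threshold must be positive")
        if self.volcano_p <= 0:
            v.append("volcano_p must be positive")
        try:
            self.gsea.validate()
        except ConfigError as e:
            v.extend(f"gsea.{msg}" for msg in e.violations)
        for p in self.gmt_paths:
            if not Path(p).exists():
                v.append(f"gmt path: no such file: {p}")
        if v:
            raise ConfigError(v)


def validate_config(path) -> PipelineConfig:
    """Load a YAML pipeline config, reporting ALL violations at once."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "out_dir" not in raw:
        raise ConfigError(["out_dir is required"])
    sim = None
    if "simulate" in raw:
        sim_raw = dict(raw["simulate"])
        program = tuple(
            PlantedGene(g["gene_id"], tuple(g["effect_log2fc_per_line"]),
                        g.get("biotype", "protein_coding"), g.get("symbol"))
            for g in sim_raw.pop("program", [])
        )
        for key in ("conditions", "baseline_log_mean_range", "library_size_range",
                    "line_labels"):
            if key in sim_raw and sim_raw[key] is not None:
                sim_raw[key] = tuple(sim_raw[key])
        sim = SimCountConfig(program=program, **sim_raw)
    gsea_params = GseaParams(**raw.get("gsea", {}))
    modules = {k: tuple(v) for k, v in raw["modules"].items()} \
        if "modules" in raw else dict(DEFAULT_MODULES)
    cfg = PipelineConfig(
        out_dir=raw["out_dir"],
        seed=int(raw.get("seed", 0)),
        simulate=sim,
        counts_path=raw.get("counts_path"),
        annotation_path=raw.get("annotation_path"),
        metadata_path=raw.get("metadata_path"),
        nt_label=raw.get("nt_label", "NT"),
        lfc_threshold=float(raw.get("lfc_threshold", 1.0)),
        volcano_p=float(raw.get("volcano_p", 0.01)),
        gsea=gsea_params,
        gmt_paths=tuple(raw.get("gmt_paths", ())),
        modules=modules,
    )
    cfg.validate()
    return cfg


def stage_seeds(seed: int, n: int = 4) -> list:
    """Fan one global seed out to fixed per-stage child seeds (< 2**31)."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def default_knockdown_program(n_up: int = 40, n_down: int = 40,
                              n_private: int = 10, effect: float = 2.0) -> tuple:
    """A planted program mirroring the structure of a real knockdown.

    The curated module genes are planted with the directions their
    pathways move after knockdown (cell-cycle/DNA-repair down,
    TNFa/IL6/EMT up), on top of generic concordant up/down genes and
    line-private responders.
    """
    down_syms = DEFAULT_MODULES["G2M_DNA_REPAIR"]
    up_syms = sorted(set(DEFAULT_MODULES["TNFA_NFKB"])
                     | set(DEFAULT_MODULES["IL6_INFLAMMATORY"])
                     | set(DEFAULT_MODULES["EMT_ADHESION"]))
    program = [PlantedGene(f"GENE_{s}", (-effect, -effect), symbol=s) for s in down_syms]
    program += [PlantedGene(f"GENE_{s}", (effect, effect), symbol=s) for s in up_syms]
    program += [PlantedGene(f"UP{i:03d}", (effect, effect)) for i in range(n_up)]
    program += [PlantedGene(f"DOWN{i:03d}", (-effect, -effect)) for i in range(n_down)]
    program += [PlantedGene(f"PRIV{i:03d}", (effect, 0.0)) for i in range(n_private)]
    return tuple(program)


def default_sim_config(seed: int = 0, n_genes: int = 2000) -> SimCountConfig:
    """Study-shaped defaults: two lines, NT/KD1/KD2, two replicates."""
    return SimCountConfig(n_genes=n_genes, program=default_knockdown_program(),
                          seed=seed)


def program_gene_sets(program, n_null_sets: int = 3, null_size: int = 30,
                      universe=None, seed: int = 0) -> GeneSetCollection:
    """Gene sets derived from a planted program, for simulation-mode GSEA.

    One set of planted-up symbols, one of planted-down, plus random null
    sets drawn from the supplied universe.
    """
    up, down = [], []
    for g in program:
        e = np.asarray(g.effect_log2fc_per_line, float)
        sym = g.symbol if g.symbol is not None else f"SYM_{g.gene_id}"
        if (e > 0).all():
            up.append(sym)
        elif (e < 0).all():
            down.append(sym)
    sets = {}
    if up:
        sets["PLANTED_UP"] = ("planted concordant up-regulated genes", frozenset(up))
    if down:
        sets["PLANTED_DOWN"] = ("planted concordant down-regulated genes", frozenset(down))
    if universe is not None and n_null_sets:
        rng = np.random.default_rng(seed)
        universe = list(universe)
        for i in range(n_null_sets):
            pick = rng.choice(len(universe), size=min(null_size, len(universe)),
                              replace=False)
            sets[f"NULL_SET_{i + 1}"] = ("random null set",
                                         frozenset(universe[j] for j in pick))
    return GeneSetCollection(sets)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    Deterministic given ``config.seed``. Any stage failure aborts with
    the stage name and cause; a ``_STALE`` marker flags partial output.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stale = out / "_STALE"
    stale.write_text("run in progress or aborted; outputs may be partial\n")

    sim_seed, gsea_seed, _, _ = stage_seeds(config.seed)
    manifest: dict = {
        "package": "kdsig",
        "version": __version__,
        "versions": {m.__name__: m.__version__ for m in (np, pd)},
        "seed": config.seed,
        "stage_seeds": {"simulate": sim_seed, "gsea": gsea_seed},
        "stages": {},
        "counts": {},
    }

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineStageError(name, exc) from exc
                manifest["stages"][name] = round(time.perf_counter() - self_inner.t0, 4)
        return _Timer()

    # --- counts -----------------------------------------------------------
    with stage("counts"):
        cdir = out / "counts"
        cdir.mkdir(exist_ok=True)
        if config.simulate is not None:
            sim_cfg = replace(config.simulate, seed=sim_seed)
            cm = simulate_counts(sim_cfg)
        else:
            cm = read_counts(config.counts_path, config.annotation_path,
                             config.metadata_path)
        write_counts(cm, cdir / "counts.tsv", cdir / "annotation.tsv",
                     cdir / "metadata.tsv")
        manifest["counts"]["n_features"] = cm.n_genes
        manifest["counts"]["n_samples"] = cm.n_samples

    # --- normalize --------------------------------------------------------
    with stage("normalize"):
        ndir = out / "normalize"
        ndir.mkdir(exist_ok=True)
        expr_all = normalize(cm)
        expr = filter_protein_coding(expr_all)
        expr.values.to_csv(ndir / "log2cpm_protein_coding.tsv", sep="\t",
                           index_label="gene_id")
        manifest["counts"]["n_protein_coding"] = expr.n_genes

    # --- pca --------------------------------------------------------------
    with stage("pca"):
        pdir = out / "pca"
        pdir.mkdir(exist_ok=True)
        for tag, res in (("global", pca(expr)),
                         ("cell_line_adjusted", cell_line_adjusted_pca(expr))):
            res.scores.to_csv(pdir / f"scores_{tag}.csv", index_label="sample")
            pd.Series(res.explained_variance_fraction,
                      index=res.scores.columns, name="fraction").to_csv(
                pdir / f"variance_{tag}.csv", index_label="component")

    # --- diffexp ----------------------------------------------------------
    with stage("diffexp"):
        ddir = out / "diffexp"
        ddir.mkdir(exist_ok=True)
        lines = list(dict.fromkeys(expr.samples["cell_line"]))
        de_tables = {}
        ranked = {}
        for line in lines:
            de = de_table(expr, line, nt_label=config.nt_label)
            de_tables[line] = de
            volcano_table(de, config.volcano_p).to_csv(
                ddir / f"de_{line}.csv", index_label="gene_id")
            rk = build_rank_file(de)
            ranked[line] = rk
            write_rnk(rk, ddir / f"{line}.rnk")
        manifest["counts"]["cell_lines"] = lines

    # --- signature --------------------------------------------------------
    with stage("signature"):
        sdir = out / "signature"
        sdir.mkdir(exist_ok=True)
        if len(lines) < 2:
            raise ConfigError("core signature needs two cell lines")
        sig = core_signature(de_tables[lines[0]], de_tables[lines[1]],
                             config.lfc_threshold)
        sig.table.to_csv(sdir / "core_signature.csv", index_label="gene_id")
        if len(sig) >= 2:
            heat = signature_heatmap(expr, sig)
            heat.to_csv(sdir / "heatmap_zscores.tsv", sep="\t", index_label="gene_id")
        manifest["counts"]["signature_total"] = len(sig)
        manifest["counts"]["signature_up"] = sig.n_up
        manifest["counts"]["signature_down"] = sig.n_down

    # --- gsea -------------------------------------------------------------
    with stage("gsea"):
        gdir = out / "gsea"
        gdir.mkdir(exist_ok=True)
        if config.gmt_paths:
            collection = read_gmt(config.gmt_paths[0])
            for extra in config.gmt_paths[1:]:
                collection = collection.merge(read_gmt(extra))
        elif config.simulate is not None:
            collection = program_gene_sets(
                config.simulate.program,
                universe=expr.genes["symbol"].tolist(), seed=gsea_seed)
        else:
            collection = None
        manifest["counts"]["gsea_sets_tested"] = {}
        if collection is not None and len(collection):
            params = replace(config.gsea, seed=gsea_seed)
            for line in lines:
                res = gsea_preranked(ranked[line], collection, params)
                exported = res.copy()
                exported["leading_edge"] = exported["leading_edge"].map(";".join)
                exported.to_csv(gdir / f"gsea_{line}.csv", index_label="set")
                manifest["counts"]["gsea_sets_tested"][line] = int(len(res))

    # --- modules ----------------------------------------------------------
    with stage("modules"):
        mdir = out / "modules"
        mdir.mkdir(exist_ok=True)
        available = set(expr.genes["symbol"])
        manifest["counts"]["modules"] = {}
        for name, genes_list in config.modules.items():
            present = [g for g in genes_list if g in available]
            if len(present) < 2:
                log.info("module %s skipped: %d gene(s) present", name, len(present))
                manifest["counts"]["modules"][name] = 0
                continue
            mat = module_condition_means(expr, present)
            mat.to_csv(mdir / f"module_{name}.tsv", sep="\t", index_label="symbol")
            manifest["counts"]["modules"][name] = len(present)

    manifest["config"] = _config_echo(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    stale.unlink()
    return manifest


def _config_echo(config: PipelineConfig) -> dict:
    echo = asdict(config)
    if config.simulate is not None:
        echo["simulate"]["program"] = [asdict(g) for g in config.simulate.program]
    return echo
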