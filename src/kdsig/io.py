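"""Readers and writers for the standard formats the pipeline touches.

Counts travel as a trio of UTF-8 tab-separated tables (counts,
annotation, metadata), gene sets as Broad-dialect GMT, ranked lists as
two-column RNK. Every reader/writer pair round-trips losslessly on
valid files; the only documented silent drop is RNK rows with a missing
gene symbol, which is logged with a count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .containers import CountMatrix, SAMPLE_METADATA_COLUMNS
from .errors import FormatError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# counts / annotation / metadata trio

def write_counts(cm: CountMatrix, counts_path, annotation_path, metadata_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.genes.to_csv(annotation_path, sep="\t", index_label="gene_id")
    cm.samples.to_csv(metadata_path, sep="\t", index_label="sample")


def read_counts(counts_path, annotation_path, metadata_path) -> CountMatrix:
    """Load and align the counts trio; mismatched sample sets are an error."""
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    counts.columns.name = "sample"
    genes = pd.read_csv(annotation_path, sep="\t", index_col="gene_id")
    samples = pd.read_csv(metadata_path, sep="\t", index_col="sample")

    extra = counts.columns.difference(samples.index)
    missing = samples.index.difference(counts.columns)
    if len(extra) or len(missing):
        parts = []
        if len(extra):
            parts.append("samples in counts but not metadata: " + ", ".join(extra))
        if len(missing):
            parts.append("samples in metadata but not counts: " + ", ".join(missing))
        raise FormatError("; ".join(parts))
    bad = counts.columns[counts.dtypes.apply(lambda d: d.kind not in "iu")]
    if len(bad):
        raise FormatError("non-integer counts in columns: " + ", ".join(bad))
    if not counts.index.equals(genes.index):
        raise FormatError("annotation gene ids do not match counts rows")
    samples = samples.loc[counts.columns]
    for col in SAMPLE_METADATA_COLUMNS:
        if col not in samples.columns:
            raise FormatError(f"metadata missing column {col!r}")
    return CountMatrix(counts, genes, samples)


# ---------------------------------------------------------------------------
# GMT gene sets

@dataclass
class GeneSetCollection:
    """Named gene sets: set name -> (description, member symbols)."""

    sets: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name) -> bool:
        return name in self.sets

    def members(self, name) -> frozenset:
        return self.sets[name][1]

    def names(self):
        return list(self.sets)

    def merge(self, other: "GeneSetCollection") -> "GeneSetCollection":
        """Union of two collections; identical set names collide loudly."""
        clash = set(self.sets) & set(other.sets)
        if clash:
            raise FormatError("gene set name collision: " + ", ".join(sorted(clash)))
        merged = dict(self.sets)
        merged.update(other.sets)
        return GeneSetCollection(merged)


def read_gmt(path) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file: name, description, members...

    Duplicate members within a line are stored once; empty member lists
    and duplicate set names are format errors.
    """
    sets: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            name, desc = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# RNK ranked lists

@dataclass
class RankedList:
    """Gene symbols with rank scores, held in descending score order.

    Ties keep their input order (stable sort), so enrichment scores are
    deterministic for a given file.
    """

    entries: pd.DataFrame  # columns: symbol, score

    def __post_init__(self) -> None:
        if list(self.entries.columns) != ["symbol", "score"]:
            raise FormatError("ranked list needs columns ['symbol', 'score']")
        if self.entries["symbol"].duplicated().any():
            dups = self.entries["symbol"][self.entries["symbol"].duplicated()].unique()
            raise FormatError("duplicate symbols in ranked list: " + ", ".join(map(str, dups[:10])))
        self.entries = (
            self.entries.sort_values("score", ascending=False, kind="stable")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def symbols(self) -> list:
        return self.entries["symbol"].tolist()

    @property
    def scores(self):
        return self.entries["score"].to_numpy()


def read_rnk(path) -> RankedList:
    """Read a two-column (symbol, score) TSV; no header.

    Rows with a missing symbol are dropped and counted in the log.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["symbol", "score"],
                     dtype={"symbol": str}, na_values=[""], keep_default_na=True,
                     float_precision="round_trip")
    if df["score"].isna().any():
        raise FormatError(f"{path}: non-numeric or missing rank scores")
    n_missing = int(df["symbol"].isna().sum())
    if n_missing:
        log.info("read_rnk: dropped %d rows with missing symbols from %s", n_missing, path)
        df = df.dropna(subset=["symbol"])
    return RankedList(df.reset_index(drop=True))


def write_rnk(ranked: RankedList, path) -> None:
    ranked.entries.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# survival cohorts

def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV: subject_id, time, event, then one column per gene."""
    df = pd.read_csv(path)
    required = {"subject_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError("cohort missing columns: " + ", ".join(sorted(missing)))
    if (df["time"] <= 0).any():
        raise FormatError("cohort contains nonpositive times")
    if not df["event"].isin([0, 1]).all():
        raise FormatError("event indicator must be 0/1")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)
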