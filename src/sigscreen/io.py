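"""Domain types and plain-text I/O for signature-based connectivity analysis.

The package works on three kinds of objects: per-gene differential-expression
results (the *query* side of every analysis), ranked gene signatures derived
from them, and libraries of perturbation signatures (per-gene z-scores for a
compound/dose/time/cell combination, emulating LINCS L1000 level 5 data).

All on-disk formats are plain text: tab-separated DE tables, GCT 1.2 matrices,
and GMT gene-set collections.  Writers emit deterministic column order with
6-decimal fixed point for scores and 6-significant-digit scientific notation
for probabilities.  Gene identifiers are matched case-sensitively and exactly;
no symbol/Ensembl mapping layer is provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sigscreen")

SCORE_FMT = "{:.6f}"
PVAL_FMT = "{:.6e}"


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class UnsupportedFormatError(FormatError):
    """A file is in a recognizable but unsupported dialect (e.g. GCT 1.3)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DifferentialExpressionRecord:
    """One gene's differential-expression result (DESeq2-style).

    ``stat`` is the test statistic (Wald statistic in DESeq2 output); it is
    optional because not every DE table carries it.
    """

    gene: str
    log2fc: float
    pvalue: float
    padj: float
    stat: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene identifier must be non-empty")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"pvalue must be in (0, 1], got {self.pvalue!r} for {self.gene}")
        if not (0.0 < self.padj <= 1.0):
            raise ValueError(f"padj must be in (0, 1], got {self.padj!r} for {self.gene}")


@dataclass(frozen=True)
class RankedSignature:
    """Genes ordered by a ranking metric, best (largest) first.

    The metric sequence must be non-increasing and genes unique; this is the
    input to all enrichment scoring.
    """

    entries: tuple
    metric_name: str = "log2fc"

    def __post_init__(self) -> None:
        entries = tuple((str(g), float(v)) for g, v in self.entries)
        object.__setattr__(self, "entries", entries)
        if len(entries) < 1:
            raise ValueError("ranked signature must have at least one entry")
        genes = [g for g, _ in entries]
        if len(set(genes)) != len(genes):
            raise ValueError("ranked signature contains duplicate gene identifiers")
        vals = [v for _, v in entries]
        for a, b in zip(vals, vals[1:]):
            if a < b:
                raise ValueError("ranking metric must be non-increasing")

    @property
    def genes(self) -> tuple:
        return tuple(g for g, _ in self.entries)

    @property
    def metrics(self) -> np.ndarray:
        return np.array([v for _, v in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(str(g) for g in self.members))
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} must have at least one member")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PerturbationSignature:
    """One compound/dose/time/cell perturbation signature of per-gene z-scores."""

    compound: str
    dose: str
    treat_time: str
    cell: str
    batch: str
    zscores: Mapping[str, float]

    def __post_init__(self) -> None:
        z = dict(self.zscores)
        object.__setattr__(self, "zscores", z)
        if not z:
            raise ValueError(f"signature {self.compound!r} has no z-scores")
        bad = [g for g, v in z.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"signature {self.compound!r} has non-finite z-scores for {bad[:3]}")

    @property
    def uid(self) -> str:
        """Stable signature identifier used in outputs and set ids."""
        return "|".join([self.batch, self.compound, self.dose, self.treat_time, self.cell])


@dataclass(frozen=True)
class CountTable:
    genes: tuple
    samples: tuple
    counts: np.ndarray  # genes x samples, non-negative

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("count matrix shape does not match gene/sample ids")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")


# ---------------------------------------------------------------------------
# DE table I/O
# ---------------------------------------------------------------------------

DEFAULT_DE_COLUMNS = {
    "gene": "gene",
    "log2fc": "log2FoldChange",
    "pvalue": "pvalue",
    "padj": "padj",
    "stat": "stat",
}


def read_de_table(path, column_map: Optional[Mapping[str, str]] = None):
    """Read a tab-separated differential-expression table.

    ``column_map`` maps the roles gene/log2fc/pvalue/padj/stat to column names
    (defaults follow DESeq2's result headers).  Rows with missing log2fc,
    pvalue or padj are dropped with a logged count, mirroring common DESeq2
    output where independent filtering leaves NA adjusted p-values.
    """
    cmap = dict(DEFAULT_DE_COLUMNS)
    cmap.update(column_map or {})
    df = pd.read_csv(path, sep="\t")
    for role in ("gene", "log2fc", "pvalue", "padj"):
        if cmap[role] not in df.columns:
            raise FormatError(f"missing required column {cmap[role]!r} (role {role!r}) in {path}")
    has_stat = cmap["stat"] in df.columns

    n0 = len(df)
    keep = (
        df[cmap["log2fc"]].notna()
        & df[cmap["pvalue"]].notna()
        & df[cmap["padj"]].notna()
    )
    dropped = int(n0 - keep.sum())
    if dropped:
        logger.warning("DROP: %d rows with NA log2fc/pvalue/padj in %s", dropped, path)
    df = df.loc[keep]

    genes = df[cmap["gene"]].astype(str)
    dup = genes[genes.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate gene id {dup.iloc[0]!r} in {path}")

    records = []
    for _, row in df.iterrows():
        stat = None
        if has_stat and pd.notna(row[cmap["stat"]]):
            stat = float(row[cmap["stat"]])
        records.append(
            DifferentialExpressionRecord(
                gene=str(row[cmap["gene"]]),
                log2fc=float(row[cmap["log2fc"]]),
                pvalue=float(row[cmap["pvalue"]]),
                padj=float(row[cmap["padj"]]),
                stat=stat,
            )
        )
    return records


def write_de_table(records: Sequence[DifferentialExpressionRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tlog2FoldChange\tpvalue\tpadj\tstat\n")
        for r in records:
            stat = SCORE_FMT.format(r.stat) if r.stat is not None else "NA"
            fh.write(
                f"{r.gene}\t{SCORE_FMT.format(r.log2fc)}\t{PVAL_FMT.format(r.pvalue)}"
                f"\t{PVAL_FMT.format(r.padj)}\t{stat}\n"
            )


# ---------------------------------------------------------------------------
# GCT 1.2 (the LINCS level-5 text dialect)
# ---------------------------------------------------------------------------

def read_gct(path):
    """Read a GCT 1.2 matrix; returns (matrix, row gene ids, column ids)."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if not lines or lines[0].strip() != "#1.2":
        found = lines[0].strip() if lines else "<empty file>"
        raise UnsupportedFormatError(f"expected GCT version line '#1.2', found {found!r}")
    try:
        nrow, ncol = (int(x) for x in lines[1].split("\t")[:2])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"malformed GCT dimension line: {lines[1]!r}") from exc
    header = lines[2].split("\t")
    if len(header) != 2 + ncol:
        raise FormatError(f"GCT header declares {len(header) - 2} columns, expected {ncol}")
    col_ids = header[2:]
    body = lines[3:]
    if len(body) != nrow:
        raise FormatError(f"GCT declares {nrow} rows but body has {len(body)}")
    genes = []
    matrix = np.empty((nrow, ncol), dtype=float)
    for i, ln in enumerate(body):
        fields = ln.split("\t")
        if len(fields) != 2 + ncol:
            raise FormatError(f"GCT row {i + 1} has {len(fields) - 2} values, expected {ncol}")
        genes.append(fields[0])
        matrix[i] = [float(x) for x in fields[2:]]
    if len(set(genes)) != len(genes):
        raise FormatError("GCT contains duplicate row gene ids")
    return matrix, genes, col_ids


def write_gct(matrix, genes: Sequence[str], col_ids: Sequence[str], path,
              descriptions: Optional[Sequence[str]] = None) -> None:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(genes), len(col_ids)):
        raise ValueError("matrix shape does not match row/column ids")
    if descriptions is None:
        descriptions = ["na"] * len(genes)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{len(genes)}\t{len(col_ids)}\n")
        fh.write("Name\tDescription\t" + "\t".join(col_ids) + "\n")
        for g, d, row in zip(genes, descriptions, matrix):
            fh.write(g + "\t" + d + "\t" + "\t".join(SCORE_FMT.format(v) for v in row) + "\n")


def write_library_gct(signatures: Sequence[PerturbationSignature], path) -> None:
    """Write a signature library as GCT 1.2 over the union of gene universes.

    Column ids are the signatures' ``uid`` (batch|compound|dose|time|cell).
    All signatures must share one gene universe (the usual case for level-5
    style matrices); a gene missing from any signature is an error.
    """
    if not signatures:
        raise ValueError("empty signature library")
    genes = sorted(signatures[0].zscores)
    for sig in signatures:
        if sorted(sig.zscores) != genes:
            raise ValueError(f"signature {sig.uid} gene universe differs from the library's")
    matrix = np.array([[sig.zscores[g] for sig in signatures] for g in genes])
    write_gct(matrix, genes, [sig.uid for sig in signatures], path)


def read_library_gct(path):
    """Read a GCT 1.2 library back into PerturbationSignature objects.

    Column ids of the form batch|compound|dose|time|cell are split into
    metadata; any other id is kept whole as the compound name.
    """
    matrix, genes, col_ids = read_gct(path)
    sigs = []
    for j, cid in enumerate(col_ids):
        parts = cid.split("|")
        if len(parts) == 5:
            batch, compound, dose, time, cell = parts
        else:
            batch, compound, dose, time, cell = "", cid, "", "", ""
        sigs.append(
            PerturbationSignature(
                compound=compound, dose=dose, treat_time=time, cell=cell, batch=batch,
                zscores={g: float(matrix[i, j]) for i, g in enumerate(genes)},
            )
        )
    return sigs


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path):
    sets = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: expected at least 3 tab-separated fields")
            members = fields[2:]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning("DEDUP: GMT line %d (%s): duplicate members removed", lineno, fields[0])
            sets.append(GeneSet(set_id=fields[0], description=fields[1], members=frozenset(unique)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write(gs.set_id + "\t" + gs.description + "\t" + "\t".join(sorted(gs.members)) + "\n")


# ---------------------------------------------------------------------------
# Filtering, DEG selection, ranking, extreme sets
# ---------------------------------------------------------------------------

def filter_genes(counts: CountTable, min_avg: float = 5.0,
                 keep_ids: Optional[Iterable[str]] = None) -> CountTable:
    """Keep genes whose mean count across samples is strictly above ``min_avg``.

    An optional allow-list (e.g. protein-coding gene ids) further restricts
    the result.  An empty result is a warning, not an error.
    """
    if min_avg < 0:
        raise ValueError("min_avg must be >= 0")
    means = counts.counts.mean(axis=1)
    mask = means > min_avg
    if keep_ids is not None:
        allowed = set(keep_ids)
        mask &= np.array([g in allowed for g in counts.genes])
    kept = [i for i, m in enumerate(mask) if m]
    if not kept:
        logger.warning("FILTER: no genes pass min_avg=%s", min_avg)
        return CountTable(genes=(), samples=counts.samples, counts=np.empty((0, len(counts.samples))))
    return CountTable(
        genes=tuple(counts.genes[i] for i in kept),
        samples=counts.samples,
        counts=counts.counts[kept],
    )


def select_degs(records: Sequence[DifferentialExpressionRecord], alpha: float = 0.05):
    """Split records into up/down DEG sets: padj < alpha and log2fc > 0 (resp. < 0).

    Both thresholds are strict; genes with log2fc == 0 fall in neither set.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    up = frozenset(r.gene for r in records if r.padj < alpha and r.log2fc > 0)
    down = frozenset(r.gene for r in records if r.padj < alpha and r.log2fc < 0)
    return up, down


def rank_genes(records: Sequence[DifferentialExpressionRecord],
               metric: str = "log2fc") -> RankedSignature:
    """Rank genes by the chosen metric in descending order, ties by gene id."""
    if metric not in ("log2fc", "stat"):
        raise ValueError(f"unknown ranking metric {metric!r}; use 'log2fc' or 'stat'")
    genes = [r.gene for r in records]
    if len(set(genes)) != len(genes):
        seen = set()
        dup = next(g for g in genes if g in seen or seen.add(g))
        raise ValueError(f"duplicate gene id {dup!r} in records")
    vals = []
    for r in records:
        v = r.log2fc if metric == "log2fc" else r.stat
        if v is None:
            raise ValueError(f"metric {metric!r} missing for gene {r.gene!r}")
        vals.append(float(v))
    order = sorted(zip(genes, vals), key=lambda gv: (-gv[1], gv[0]))
    return RankedSignature(entries=tuple(order), metric_name=metric)


def extreme_sets(sig: PerturbationSignature, n: int, require_sign: bool = False):
    """Top-n and bottom-n genes of a perturbation signature by z-score.

    The up set is the n largest z-scores and the down set the n smallest,
    regardless of sign (ties at either cutoff broken by gene id ascending;
    the down set is drawn from genes not already taken by the up set, which
    guarantees disjointness even when one z value spans both cutoffs).  With
    ``require_sign`` the up set is clamped to strictly positive z and the
    down set to strictly negative z, with a logged warning when clamped.
    """
    items = list(sig.zscores.items())
    if 2 * n > len(items):
        raise ValueError(f"need 2n <= gene count, got n={n} for {len(items)} genes")
    desc = sorted(items, key=lambda kv: (-kv[1], kv[0]))
    up_items = desc[:n]
    rest = desc[n:]
    asc = sorted(rest, key=lambda kv: (kv[1], kv[0]))
    down_items = asc[:n]
    if require_sign:
        up_kept = [(g, z) for g, z in up_items if z > 0]
        down_kept = [(g, z) for g, z in down_items if z < 0]
        if len(up_kept) < len(up_items) or len(down_kept) < len(down_items):
            logger.warning(
                "CLAMP: sign-restricted extreme sets for %s: up %d->%d, down %d->%d",
                sig.uid, len(up_items), len(up_kept), len(down_items), len(down_kept),
            )
        up_items, down_items = up_kept, down_kept
        if not up_items or not down_items:
            raise ValueError(f"sign restriction emptied an extreme set for {sig.uid}")
    up = GeneSet(set_id=sig.uid + "|up", description=f"top {len(up_items)} by z",
                 members=frozenset(g for g, _ in up_items))
    down = GeneSet(set_id=sig.uid + "|down", description=f"bottom {len(down_items)} by z",
                   members=frozenset(g for g, _ in down_items))
    return up, down
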