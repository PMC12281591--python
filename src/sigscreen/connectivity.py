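"""Compound-similarity recognition against a query expression signature.

Every perturbation signature in a library (e.g. LINCS L1000 level-5 z-score
columns) is reduced to its extreme gene sets — the top-n and bottom-n genes by
z-score (n = 500 for genome-scale libraries).  Each set is scored by preranked
GSEA against the query ranking (all query genes sorted by log2 fold change,
descending), yielding a signed NES per direction.  The *summarized NES* of a
signature is NES(up set) − NES(down set): a transcriptional mimic of the query
enriches its up set at the top of the ranking (positive NES) and its down set
at the bottom (negative NES), so mimics score high and inverters score low.
Signatures are ranked by summarized NES descending; per-direction permutation
p-values are BH-corrected within the screened library, separately for the up
and down families.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

from .enrichment import (
    EmptyEffectiveSetError,
    EnrichmentParams,
    bh_adjust,
    enrichment_score,
    normalize_es,
    permutation_null,
)
from .io import (
    PVAL_FMT,
    SCORE_FMT,
    DifferentialExpressionRecord,
    PerturbationSignature,
    RankedSignature,
    extreme_sets,
    rank_genes,
)

logger = logging.getLogger("sigscreen")

SCREEN_COLUMNS = [
    "rank", "batch", "compound", "dose", "treat_time", "cell",
    "nes_up", "p_up", "padj_up", "nes_down", "p_down", "padj_down", "total_nes",
]


@dataclass(frozen=True)
class ConnectivityResult:
    """One screened signature: per-direction NES/p and the summarized score."""

    compound: str
    dose: str
    treat_time: str
    cell: str
    batch: str
    nes_up: float
    p_up: float
    nes_down: float
    p_down: float
    total_nes: float
    padj_up: Optional[float] = None
    padj_down: Optional[float] = None
    rank: Optional[int] = None


def summarized_nes(nes_up: float, nes_down: float) -> float:
    """Summarized connectivity score: NES of the up set minus NES of the down set."""
    if not (math.isfinite(nes_up) and math.isfinite(nes_down)):
        raise ValueError(f"NES values must be finite, got ({nes_up!r}, {nes_down!r})")
    return nes_up - nes_down


def score_signature(query: RankedSignature, sig: PerturbationSignature, n: int,
                    params: EnrichmentParams,
                    _null_cache: Optional[dict] = None) -> Optional[ConnectivityResult]:
    """Score one signature against the query ranking; None if it must be skipped.

    The signature's extreme sets are intersected with the query universe before
    scoring; permutation nulls are seeded by (params.seed, effective size), so
    a shared per-size null cache gives results identical to standalone calls.
    ``n`` is clamped to half the signature's gene count with a warning.
    """
    n_genes = len(sig.zscores)
    n_eff = min(n, n_genes // 2)
    if n_eff < 1:
        logger.warning("SKIP: signature %s has too few genes (%d)", sig.uid, n_genes)
        return None
    if n_eff < n:
        logger.warning("CLAMP: extreme-set size %d -> %d for %s (library universe of %d)",
                       n, n_eff, sig.uid, n_genes)
    up, down = extreme_sets(sig, n_eff)
    universe = set(query.genes)
    sizes = {"up": len(up.members & universe), "down": len(down.members & universe)}
    if sizes["up"] == 0 or sizes["down"] == 0:
        logger.warning("SKIP: signature %s shares no extreme-set genes with the query", sig.uid)
        return None
    cache = _null_cache if _null_cache is not None else {}
    scores = {}
    for direction, gene_set in (("up", up), ("down", down)):
        try:
            es, _, _ = enrichment_score(query, gene_set, params.exponent)
        except EmptyEffectiveSetError:
            logger.warning("SKIP: signature %s %s set empty after intersection", sig.uid, direction)
            return None
        size = sizes[direction]
        if size not in cache:
            cache[size] = permutation_null(query, size, params)
        scores[direction] = normalize_es(es, cache[size])
    nes_up, p_up = scores["up"]
    nes_down, p_down = scores["down"]
    return ConnectivityResult(
        compound=sig.compound, dose=sig.dose, treat_time=sig.treat_time,
        cell=sig.cell, batch=sig.batch,
        nes_up=nes_up, p_up=p_up, nes_down=nes_down, p_down=p_down,
        total_nes=summarized_nes(nes_up, nes_down),
    )


def connectivity_screen(query_records: Sequence[DifferentialExpressionRecord],
                        library: Sequence[PerturbationSignature], n: int = 500,
                        params: Optional[EnrichmentParams] = None,
                        degs_only: bool = False, alpha: float = 0.05):
    """Screen a signature library against a query DE table.

    The query ranking uses all genes in the DE table sorted by log2FC
    (``degs_only`` restricts it to genes with padj < alpha first).  Returns
    ConnectivityResults sorted by summarized NES descending (ties by
    p_up + p_down ascending, then compound name), with 1-based ranks and
    per-direction BH adjustment across the screened library.
    """
    if not library:
        raise ValueError("signature library is empty")
    params = params or EnrichmentParams()
    records = list(query_records)
    if degs_only:
        records = [r for r in records if r.padj < alpha]
        if not records:
            raise ValueError("no significant query genes under --degs-only")
    query = rank_genes(records, metric="log2fc")
    null_cache: dict = {}
    scored = []
    for sig in library:
        res = score_signature(query, sig, n, params, _null_cache=null_cache)
        if res is not None:
            scored.append(res)
    if not scored:
        raise ValueError("all signatures were skipped; no overlap with the query universe")
    padj_up = bh_adjust([r.p_up for r in scored])
    padj_down = bh_adjust([r.p_down for r in scored])
    scored = [replace(r, padj_up=float(qu), padj_down=float(qd))
              for r, qu, qd in zip(scored, padj_up, padj_down)]
    scored.sort(key=lambda r: (-r.total_nes, r.p_up + r.p_down, r.compound,
                               r.batch, r.dose, r.treat_time))
    return [replace(r, rank=i + 1) for i, r in enumerate(scored)]


@dataclass(frozen=True)
class TopTable:
    """Top-k screen rows plus compound-level occurrence structure."""

    table: pd.DataFrame
    n_compounds: int
    compound_counts: dict


def top_table(results: Sequence[ConnectivityResult], k: int) -> TopTable:
    """First k ranked rows plus distinct-compound count and per-compound counts."""
    if k < 1:
        raise ValueError("k must be >= 1")
    results = sorted(results, key=lambda r: (r.rank if r.rank is not None else 0))
    if k > len(results):
        logger.warning("CLAMP: requested top %d of %d results; returning all", k, len(results))
        k = len(results)
    rows = results[:k]
    table = pd.DataFrame(
        [{
            "rank": r.rank, "batch": r.batch, "compound": r.compound, "dose": r.dose,
            "treat_time": r.treat_time, "cell": r.cell,
            "nes_up": r.nes_up, "p_up": r.p_up, "padj_up": r.padj_up,
            "nes_down": r.nes_down, "p_down": r.p_down, "padj_down": r.padj_down,
            "total_nes": r.total_nes,
        } for r in rows],
        columns=SCREEN_COLUMNS,
    )
    counts = Counter(r.compound for r in rows)
    return TopTable(table=table, n_compounds=len(counts),
                    compound_counts=dict(sorted(counts.items())))


def write_screen_tsv(results: Sequence[ConnectivityResult], path, n: int,
                     params: EnrichmentParams) -> None:
    """Write ranked screen results with a parameter-recording comment header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# n={n} n_perm={params.n_perm} exponent={SCORE_FMT.format(params.exponent)}"
                 f" seed={params.seed} bh_family_size={len(results)}\n")
        fh.write("\t".join(SCREEN_COLUMNS) + "\n")
        for r in results:
            qu = PVAL_FMT.format(r.padj_up) if r.padj_up is not None else "NA"
            qd = PVAL_FMT.format(r.padj_down) if r.padj_down is not None else "NA"
            fh.write(
                f"{r.rank}\t{r.batch}\t{r.compound}\t{r.dose}\t{r.treat_time}\t{r.cell}"
                f"\t{SCORE_FMT.format(r.nes_up)}\t{PVAL_FMT.format(r.p_up)}\t{qu}"
                f"\t{SCORE_FMT.format(r.nes_down)}\t{PVAL_FMT.format(r.p_down)}\t{qd}"
                f"\t{SCORE_FMT.format(r.total_nes)}\n"
            )


def read_screen_tsv(path) -> list:
    """Read a screen result table written by :func:`write_screen_tsv` (or the
    bundled worked example, which lacks padj columns)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    results = []
    for _, row in df.iterrows():
        results.append(ConnectivityResult(
            compound=str(row["compound"]), dose=str(row["dose"]),
            treat_time=str(row["treat_time"]), cell=str(row["cell"]),
            batch=str(row["batch"]),
            nes_up=float(row["nes_up"]), p_up=float(row["p_up"]),
            nes_down=float(row["nes_down"]), p_down=float(row["p_down"]),
            total_nes=float(row["total_nes"]),
            padj_up=float(row["padj_up"]) if "padj_up" in df.columns and pd.notna(row.get("padj_up")) else None,
            padj_down=float(row["padj_down"]) if "padj_down" in df.columns and pd.notna(row.get("padj_down")) else None,
            rank=int(row["rank"]),
        ))
    return results


def load_example_screen() -> list:
    """The bundled worked example: top-10 LINCS L1000 compound signatures from a
    published A549 connectivity screen of an herbal-extract query, ranked by
    summarized NES."""
    ref = resources.files("sigscreen").joinpath("data/lincs_a549_top10.tsv")
    with resources.as_file(ref) as path:
        return read_screen_tsv(path)
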