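"""Preranked gene-set enrichment and over-representation statistics.

The enrichment score (ES) is the classic weighted Kolmogorov–Smirnov
running-sum statistic: walking a ranked gene list, a gene-set hit at rank i
adds |metric_i|^exponent / N_R (N_R normalizes hit increments to total 1)
and a miss adds -1/(N - N_H); the ES is the running-sum value of maximal
absolute deviation from zero, signed.  Significance comes from a gene-set
(label) permutation null: n_perm uniformly drawn subsets of the same size.
The normalized enrichment score (NES) divides the observed ES by the mean
magnitude of same-sign null values, and the permutation p-value is the
+1-corrected same-sign tail.

Also here: Benjamini–Hochberg FDR adjustment, one-sided hypergeometric
over-representation (Fisher's exact test for 2x2 tables with fixed margins),
and mean-rank aggregation across ranking libraries, the statistic used to
summarize transcription-factor enrichment over multiple target-gene
libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSet, RankedSignature

logger = logging.getLogger("sigscreen")


class EmptyEffectiveSetError(ValueError):
    """The gene set shares no genes with the ranked universe."""


class UndefinedMissError(ValueError):
    """The gene set covers the whole ranked universe; the miss increment is undefined."""


class DegenerateScoreError(ValueError):
    """All hit metrics are zero with a positive exponent; hit increments are undefined."""


@dataclass(frozen=True)
class EnrichmentParams:
    """Tuning knobs of the permutation GSEA machinery.

    exponent=1.0 is the classic "weighted" statistic; exponent=0 reduces the
    ES to the unweighted Kolmogorov–Smirnov form.  min_size/max_size bound the
    effective set size after intersection with the ranked universe.
    """

    exponent: float = 1.0
    n_perm: int = 1000
    min_size: int = 3
    max_size: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exponent < 0:
            raise ValueError("exponent must be >= 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (1 <= self.min_size <= self.max_size):
            raise ValueError("need 1 <= min_size <= max_size")


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    es: float
    nes: float
    pvalue: float
    padj: float
    size: int
    leading_edge: tuple


@dataclass(frozen=True)
class OraResult:
    set_id: str
    overlap: int
    set_size: int
    interest_size: int
    background_size: int
    gene_ratio: float
    pvalue: float
    padj: float


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def enrichment_score(ranked: RankedSignature, gene_set: GeneSet, exponent: float = 1.0):
    """Weighted running-sum enrichment score of ``gene_set`` on ``ranked``.

    Returns ``(es, running_sum, leading_edge)`` where the leading edge is the
    hit genes at or before the extremum (at or after it, for negative ES), in
    rank order.
    """
    genes = ranked.genes
    metrics = ranked.metrics
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}
    hits = sorted(index[g] for g in gene_set.members if g in index)
    n_hit = len(hits)
    if n_hit == 0:
        raise EmptyEffectiveSetError(f"set {gene_set.set_id!r} shares no genes with the ranking")
    if n_hit == n:
        raise UndefinedMissError(f"set {gene_set.set_id!r} covers the whole ranked universe")
    w = np.abs(metrics) ** exponent
    hit_w = w[hits]
    n_r = hit_w.sum()
    if exponent > 0 and n_r == 0:
        raise DegenerateScoreError(f"all hit metrics are zero for set {gene_set.set_id!r}")
    if n_r == 0:  # exponent == 0 gives w == 1 so this cannot happen; guard anyway
        n_r = float(n_hit)
    increments = np.full(n, -1.0 / (n - n_hit))
    increments[hits] = hit_w / n_r
    running = np.cumsum(increments)
    j = int(np.argmax(np.abs(running)))
    es = float(running[j])
    if es >= 0:
        leading = tuple(genes[i] for i in hits if i <= j)
    else:
        leading = tuple(genes[i] for i in hits if i >= j)
    return es, running, leading


def _batch_es(metrics: np.ndarray, hit_idx: np.ndarray, exponent: float) -> np.ndarray:
    """Vectorized ES for many equally sized gene subsets (rows of hit_idx)."""
    n_perm, k = hit_idx.shape
    n = metrics.size
    w = np.abs(metrics) ** exponent
    miss = -1.0 / (n - k)
    inc = np.full((n_perm, n), miss)
    hit_w = w[hit_idx]
    n_r = hit_w.sum(axis=1, keepdims=True)
    degenerate = n_r[:, 0] == 0
    if np.any(degenerate):  # all-zero hit metrics: fall back to unweighted increments
        hit_w[degenerate] = 1.0
        n_r[degenerate] = k
    rows = np.arange(n_perm)[:, None]
    inc[rows, hit_idx] = hit_w / n_r
    running = np.cumsum(inc, axis=1)
    j = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), j]


def permutation_null(ranked: RankedSignature, set_size: int, params: EnrichmentParams) -> np.ndarray:
    """Null ES values from uniformly drawn gene subsets of ``set_size``.

    The generator is seeded from (params.seed, set_size), so nulls depend only
    on the ranking, the size and the seed — one null per distinct effective
    size can be shared across gene sets and signatures with no change in
    results, and screens are independent of input order.
    """
    n = len(ranked)
    if set_size >= n:
        raise ValueError("set_size must be smaller than the ranked universe")
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    rng = np.random.default_rng((params.seed, set_size))
    u = rng.random((params.n_perm, n))
    hit_idx = np.argpartition(u, set_size - 1, axis=1)[:, :set_size]
    return _batch_es(ranked.metrics, hit_idx, params.exponent)


def normalize_es(es: float, null: Sequence[float]):
    """Sign-stratified NES and +1-corrected permutation p-value.

    NES = es / mean(|null values with the same sign as es|); the p-value is
    computed within the same-sign stratum.  If the stratum is empty the whole
    null is used for normalization and the p-value floors at 1/(len+1), with a
    warning.  es == 0 yields (0, 1) with a warning.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    if es == 0:
        logger.warning("NES: es == 0; returning nes=0, pvalue=1")
        return 0.0, 1.0
    same = null[np.sign(null) == np.sign(es)]
    if same.size == 0:
        logger.warning("NES: no same-sign null values; normalizing by mean |null|")
        denom = float(np.abs(null).mean())
        nes = es / denom if denom > 0 else 0.0
        return nes, 1.0 / (null.size + 1)
    nes = es / float(np.abs(same).mean())
    pvalue = (int((np.abs(same) >= abs(es)).sum()) + 1) / (same.size + 1)
    return float(nes), float(pvalue)


def gsea_preranked(ranked: RankedSignature, collection: Sequence[GeneSet],
                   params: EnrichmentParams):
    """Preranked GSEA over a gene-set collection with BH correction.

    Sets whose effective size (after intersection with the ranked universe)
    falls outside [min_size, max_size] are skipped with a log entry.  Results
    are sorted by NES descending (ties by set id).
    """
    if not collection:
        raise ValueError("gene-set collection is empty")
    universe = set(ranked.genes)
    null_cache: dict = {}
    tested = []
    for gs in collection:
        eff = len(gs.members & universe)
        if eff < len(gs.members):
            logger.info("INTERSECT: set %s reduced %d -> %d against ranked universe",
                        gs.set_id, len(gs.members), eff)
        if eff < params.min_size or eff > params.max_size or eff == 0 or eff >= len(ranked):
            logger.warning("SKIP: set %s effective size %d outside [%d, %d]",
                           gs.set_id, eff, params.min_size, params.max_size)
            continue
        es, _, leading = enrichment_score(ranked, gs, params.exponent)
        if eff not in null_cache:
            null_cache[eff] = permutation_null(ranked, eff, params)
        nes, pvalue = normalize_es(es, null_cache[eff])
        tested.append((gs.set_id, es, nes, pvalue, eff, leading))
    if not tested:
        logger.warning("SKIP: no testable gene set in collection")
        return []
    padj = bh_adjust([t[3] for t in tested])
    results = [
        EnrichmentResult(set_id=sid, es=es, nes=nes, pvalue=p, padj=float(q),
                         size=size, leading_edge=leading)
        for (sid, es, nes, p, size, leading), q in zip(tested, padj)
    ]
    results.sort(key=lambda r: (-r.nes, r.set_id))
    return results


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path) -> None:
    from .io import PVAL_FMT, SCORE_FMT
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("set_id\tsize\tes\tnes\tpvalue\tpadj\tleading_edge\n")
        for r in results:
            fh.write(
                f"{r.set_id}\t{r.size}\t{SCORE_FMT.format(r.es)}\t{SCORE_FMT.format(r.nes)}"
                f"\t{PVAL_FMT.format(r.pvalue)}\t{PVAL_FMT.format(r.padj)}"
                f"\t{','.join(r.leading_edge)}\n"
            )


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Over-representation (one-sided hypergeometric / Fisher exact)
# ---------------------------------------------------------------------------

def ora_fisher(interest, background, collection: Sequence[GeneSet]):
    """One-sided over-representation of ``interest`` in each gene set.

    For each set, overlap is computed against set ∩ background and the
    p-value is the hypergeometric upper tail P(X >= overlap) with population
    = background, successes = set ∩ background, draws = interest; BH across
    sets.  Results sorted by p-value ascending (ties by set id).
    """
    interest = set(interest)
    background = set(background)
    if len(background) < 2:
        raise ValueError("background must contain at least 2 genes")
    if not interest:
        raise ValueError("interest gene list is empty")
    offenders = sorted(interest - background)
    if offenders:
        raise ValueError(f"interest genes absent from background: {offenders}")
    rows = []
    for gs in collection:
        in_bg = gs.members & background
        overlap = len(in_bg & interest)
        pvalue = float(stats.hypergeom.sf(overlap - 1, len(background), len(in_bg), len(interest)))
        rows.append((gs.set_id, overlap, len(in_bg), pvalue))
    padj = bh_adjust([r[3] for r in rows]) if rows else np.empty(0)
    results = [
        OraResult(set_id=sid, overlap=ov, set_size=size, interest_size=len(interest),
                  background_size=len(background), gene_ratio=ov / len(interest),
                  pvalue=p, padj=float(q))
        for (sid, ov, size, p), q in zip(rows, padj)
    ]
    results.sort(key=lambda r: (r.pvalue, r.set_id))
    return results


def write_ora_tsv(results: Sequence[OraResult], path) -> None:
    from .io import PVAL_FMT, SCORE_FMT
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("set_id\toverlap\tset_size\tinterest_size\tbackground_size"
                 "\tgene_ratio\tpvalue\tpadj\n")
        for r in results:
            fh.write(
                f"{r.set_id}\t{r.overlap}\t{r.set_size}\t{r.interest_size}"
                f"\t{r.background_size}\t{SCORE_FMT.format(r.gene_ratio)}"
                f"\t{PVAL_FMT.format(r.pvalue)}\t{PVAL_FMT.format(r.padj)}\n"
            )


# ---------------------------------------------------------------------------
# Mean-rank aggregation across ranking libraries
# ---------------------------------------------------------------------------

def mean_rank_aggregate(rankings: Mapping[str, Mapping[str, int]]):
    """Aggregate several 1-based rank lists by mean rank per item.

    Items missing from a library receive that library's (length + 1) as a
    penalty rank (logged).  Returns (item, mean rank) pairs sorted ascending,
    ties broken by item id.
    """
    if not rankings:
        raise ValueError("no rankings supplied")
    items = sorted({it for rk in rankings.values() for it in rk})
    if not items:
        raise ValueError("rankings contain no items")
    means = {}
    for item in items:
        total = 0.0
        for name, rk in rankings.items():
            if item in rk:
                total += rk[item]
            else:
                total += len(rk) + 1
        means[item] = total / len(rankings)
    n_missing = sum(1 for item in items for rk in rankings.values() if item not in rk)
    if n_missing:
        logger.warning("PENALTY: %d (item, library) pairs missing; assigned length+1 ranks",
                       n_missing)
    return sorted(means.items(), key=lambda kv: (kv[1], kv[0]))
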