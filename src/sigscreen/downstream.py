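"""Downstream signature statistics: Jaccard similarity of DEG sets,
footprint-based pathway activities, and reporter-metabolite aggregation.

Pathway activities follow the footprint paradigm: each pathway is a weight
vector over its most responsive downstream target genes (top-100 footprint
genes in the published weight matrices), the raw activity is the weighted sum
of per-gene test statistics, and significance comes from permuting the
statistic values over gene labels.

Reporter metabolites aggregate transcriptional significance over each
metabolite's network-adjacent genes: per-gene Z = Phi^-1(1 - p), per-metabolite
Z_agg = sum(Z) / sqrt(k), corrected against the empirical mean and SD of Z_agg
over random size-k gene samples.  Directional variants (e.g. reporters of
downregulation) are obtained by pre-filtering the gene list to one DE
direction before calling the aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("sigscreen")

_P_CLAMP = 1e-15


# ---------------------------------------------------------------------------
# Jaccard similarity
# ---------------------------------------------------------------------------

def jaccard(a, b) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b| of two gene-id collections."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(a | b)


def jaccard_matrix(named_sets: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Symmetric matrix of pairwise Jaccard similarities with unit diagonal."""
    if len(named_sets) < 2:
        raise ValueError("need at least 2 named sets")
    sets = {}
    for name, genes in named_sets.items():
        s = set(genes)
        if not s:
            raise ValueError(f"set {name!r} is empty")
        sets[name] = s
    names = list(sets)
    mat = np.ones((len(names), len(names)))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            mat[i, j] = mat[j, i] = jaccard(sets[a], sets[names[j]])
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# Footprint pathway activities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayModel:
    """Signed footprint weights over a pathway's most responsive target genes."""

    pathway: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        w = {str(g): float(v) for g, v in dict(self.weights).items()}
        object.__setattr__(self, "weights", w)
        if not w:
            raise ValueError(f"pathway {self.pathway!r} has no weights")
        if not all(np.isfinite(list(w.values()))):
            raise ValueError(f"pathway {self.pathway!r} has non-finite weights")


@dataclass(frozen=True)
class PathwayActivity:
    pathway: str
    raw_score: float
    zscore: float
    pvalue: float


def top_k_models(weight_table: pd.DataFrame, k: int = 100):
    """Build PathwayModels from a full genes x pathways weight table, keeping
    each pathway's k largest-|weight| footprint genes (ties by gene id)."""
    models = []
    for pw in weight_table.columns:
        col = weight_table[pw].dropna()
        col = col[col != 0]
        order = sorted(col.items(), key=lambda gv: (-abs(gv[1]), gv[0]))[:k]
        models.append(PathwayModel(pathway=str(pw), weights=dict(order)))
    return models


def progeny_scores(gene_stats: Mapping[str, float], models: Sequence[PathwayModel],
                   n_perm: int = 1000, seed: int = 0):
    """Permutation-normalized pathway activities from per-gene test statistics.

    raw_score = sum over model genes present in gene_stats of weight * stat.
    The null permutes the statistic values over gene labels (n_perm uniform
    permutations, shared across pathways); zscore = (raw - null mean) / null
    SD and the p-value is the centered two-sided +1-corrected permutation
    tail.  A zero null SD yields zscore 0 with a warning.
    """
    if not models:
        raise ValueError("no pathway models supplied")
    if not gene_stats:
        raise ValueError("gene_stats is empty")
    genes = list(gene_stats)
    s = np.array([gene_stats[g] for g in genes], dtype=float)
    rng = np.random.default_rng((seed, 0))
    # First-k columns of uniform permutations = uniform ordered samples
    # without replacement; shared across pathways of any size.
    perm = np.argsort(rng.random((n_perm, s.size)), axis=1)
    results = []
    for model in models:
        present = sorted(g for g in model.weights if g in gene_stats)
        if not present:
            logger.warning("SKIP: pathway %s shares no genes with gene_stats", model.pathway)
            continue
        w = np.array([model.weights[g] for g in present])
        raw = float(np.dot(w, [gene_stats[g] for g in present]))
        null = s[perm[:, : w.size]] @ w
        mu = float(null.mean())
        sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
        # constant nulls can carry ~1e-16 summation noise; treat them as degenerate
        if sd <= 1e-12 * max(1.0, abs(mu)):
            logger.warning("DEGENERATE: pathway %s null SD is 0; zscore set to 0", model.pathway)
            z, p = 0.0, 1.0
        else:
            z = (raw - mu) / sd
            p = (int((np.abs(null - mu) >= abs(raw - mu)).sum()) + 1) / (null.size + 1)
        results.append(PathwayActivity(pathway=model.pathway, raw_score=raw,
                                       zscore=z, pvalue=float(p)))
    return results


def read_pathway_models(path, k: int = 100):
    """Read a full weight table (TSV, genes in rows, pathways in columns) and
    keep the top-k footprint genes per pathway."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return top_k_models(df, k=k)


def write_pathway_models(models: Sequence[PathwayModel], path) -> None:
    from .io import SCORE_FMT
    genes = sorted({g for m in models for g in m.weights})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(m.pathway for m in models) + "\n")
        for g in genes:
            vals = [SCORE_FMT.format(m.weights[g]) if g in m.weights else "0.000000"
                    for m in models]
            fh.write(g + "\t" + "\t".join(vals) + "\n")


def write_activities_tsv(activities: Sequence[PathwayActivity], path) -> None:
    from .io import PVAL_FMT, SCORE_FMT
    rows = sorted(activities, key=lambda a: (-a.zscore, a.pathway))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pathway\traw_score\tzscore\tpvalue\n")
        for a in rows:
            fh.write(f"{a.pathway}\t{SCORE_FMT.format(a.raw_score)}"
                     f"\t{SCORE_FMT.format(a.zscore)}\t{PVAL_FMT.format(a.pvalue)}\n")


# ---------------------------------------------------------------------------
# Reporter metabolites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReporterScore:
    metabolite: str
    k: int
    z_agg: float
    z_corrected: float
    pvalue: float


def reporter_metabolites(gene_pvalues: Mapping[str, float],
                         network: Mapping[str, Sequence[str]],
                         n_samples: int = 10000, seed: int = 0):
    """Reporter-metabolite scores from per-gene p-values and a bipartite network.

    Per-gene Z = Phi^-1(1 - p) with p clamped to [1e-15, 1 - 1e-15]; per
    metabolite with k neighbors, Z_agg = sum(Z) / sqrt(k), background-corrected
    to z_corrected = (Z_agg - mu_k) / sigma_k using n_samples random size-k
    draws (without replacement) from the full gene list, one null per distinct
    k.  pvalue = 1 - Phi(z_corrected).  Results sorted by z_corrected
    descending.
    """
    if not network:
        raise ValueError("metabolite network is empty")
    genes = list(gene_pvalues)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for met, neigh in network.items():
        if not neigh:
            raise ValueError(f"metabolite {met!r} has no neighboring genes")
        for g in neigh:
            if g not in gene_pos:
                raise ValueError(f"network gene {g!r} (metabolite {met!r}) missing from gene_pvalues")
    p = np.clip(np.array([gene_pvalues[g] for g in genes], dtype=float),
                _P_CLAMP, 1.0 - _P_CLAMP)
    z = stats.norm.isf(p)

    null_by_k: dict = {}

    def null_moments(k: int):
        if k not in null_by_k:
            rng = np.random.default_rng((seed, k))
            agg = np.empty(n_samples)
            pos = 0
            chunk = max(1, min(n_samples, int(2**22 // max(len(genes), 1)) or 1))
            while pos < n_samples:
                m = min(chunk, n_samples - pos)
                u = rng.random((m, len(genes)))
                idx = np.argpartition(u, k - 1, axis=1)[:, :k]
                agg[pos:pos + m] = z[idx].sum(axis=1) / np.sqrt(k)
                pos += m
            null_by_k[k] = (float(agg.mean()), float(agg.std(ddof=1)))
        return null_by_k[k]

    results = []
    for met in network:
        neigh = network[met]
        k = len(neigh)
        z_agg = float(z[[gene_pos[g] for g in neigh]].sum() / np.sqrt(k))
        mu, sd = null_moments(k)
        if sd <= 1e-12 * max(1.0, abs(mu)):  # constant null up to summation noise
            logger.warning("DEGENERATE: background SD is 0 for k=%d; z_corrected set to 0", k)
            zc = 0.0
        else:
            zc = (z_agg - mu) / sd
        results.append(ReporterScore(metabolite=met, k=k, z_agg=z_agg, z_corrected=zc,
                                     pvalue=float(stats.norm.sf(zc))))
    results.sort(key=lambda r: (-r.z_corrected, r.metabolite))
    return results


def read_network_tsv(path):
    """Two-column TSV of metabolite<TAB>gene edges -> metabolite adjacency."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValueError("network TSV must have two columns: metabolite, gene")
    network: dict = {}
    for met, gene in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        network.setdefault(met, [])
        if gene not in network[met]:
            network[met].append(gene)
    return network


def write_network_tsv(network: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("metabolite\tgene\n")
        for met in network:
            for g in network[met]:
                fh.write(f"{met}\t{g}\n")


def write_reporters_tsv(results: Sequence[ReporterScore], path) -> None:
    from .io import PVAL_FMT, SCORE_FMT
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("metabolite\tk\tz_agg\tz_corrected\tpvalue\n")
        for r in results:
            fh.write(f"{r.metabolite}\t{r.k}\t{SCORE_FMT.format(r.z_agg)}"
                     f"\t{SCORE_FMT.format(r.z_corrected)}\t{PVAL_FMT.format(r.pvalue)}\n")


def write_jaccard_tsv(matrix: pd.DataFrame, path) -> None:
    from .io import SCORE_FMT
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("set\t" + "\t".join(matrix.columns) + "\n")
        for name, row in matrix.iterrows():
            fh.write(str(name) + "\t" + "\t".join(SCORE_FMT.format(v) for v in row) + "\n")
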