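"""Synthetic data with planted structure for every pipeline stage.

The generators emulate the statistical shape of the real inputs without any
download: a differential-expression table that mixes null genes with signed
effect genes, a perturbation-signature library containing *mimics* (z-scores
correlated with the query log2FC), *inverters* (anti-correlated) and random
*decoys*, gene-set collections with an optional planted enriched set, random
pathway weight models, and toy bipartite gene–metabolite networks.

Every generator is a pure function of its configuration including the seed.
The DE model is deliberately simple — observed log2FC = true log2FC plus
Gaussian noise, with exact normal p-values — because the pipeline consumes DE
tables, not read counts; a small Poisson count generator is provided only to
exercise count filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .enrichment import bh_adjust
from .io import CountTable, DifferentialExpressionRecord, GeneSet, PerturbationSignature


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class LibraryConfig:
    """Composition of the synthetic perturbation library.

    ``mimic_weight`` is the slope applied to the standardized query log2FC
    (so a weight of a means a mimic's z is a z-scale units per query SD);
    ``noise_sd`` is the SD of additive Gaussian noise on mimic/inverter
    signatures.  Decoys are i.i.d. standard normal.
    """

    n_mimics: int = 1
    n_inverters: int = 1
    n_decoys: int = 20
    mimic_weight: float = 2.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if min(self.n_mimics, self.n_inverters, self.n_decoys) < 0:
            raise ConfigError("library counts must be >= 0")
        if self.mimic_weight < 0:
            raise ConfigError("mimic_weight must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic query and library.

    Defaults are the planted-structure conditions used throughout the test
    suite: 2000 genes, 20% true DE, unit effect SD, observation noise SD 0.3,
    and a library of 1 mimic + 1 inverter + 20 decoys at mimic_weight 2,
    signature noise SD 0.5.
    """

    n_genes: int = 2000
    frac_de: float = 0.2
    effect_sd: float = 1.0
    null_noise_sd: float = 0.3
    seed: int = 0
    library: LibraryConfig = field(default_factory=LibraryConfig)

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ConfigError("n_genes must be >= 10")
        if not (0.0 <= self.frac_de <= 1.0):
            raise ConfigError("frac_de must be in [0, 1]")
        if self.effect_sd < 0 or self.null_noise_sd < 0:
            raise ConfigError("standard deviations must be >= 0")


def simulate_de_table(config: SimulationConfig):
    """Simulate a DE table and return (records, truth mapping gene -> true log2FC).

    round(n_genes * frac_de) genes carry a true log2FC with magnitude
    |Normal(0, effect_sd^2)|; signs are forced half positive, half negative so
    both ranking tails are populated.  Observed log2FC adds Normal(0,
    null_noise_sd^2) noise; the test statistic is observed / null_noise_sd,
    the p-value its exact two-sided normal tail, and padj the BH adjustment
    over all genes.
    """
    if config.null_noise_sd <= 0:
        raise ConfigError("null_noise_sd must be > 0 to define test statistics")
    rng = np.random.default_rng((config.seed, 0))
    n = config.n_genes
    genes = [f"G{i:05d}" for i in range(n)]
    n_de = int(round(n * config.frac_de))
    truth = np.zeros(n)
    if n_de:
        de_idx = np.sort(rng.choice(n, size=n_de, replace=False))
        mags = np.abs(rng.normal(0.0, config.effect_sd, size=n_de))
        signs = np.ones(n_de)
        signs[(n_de + 1) // 2:] = -1.0
        truth[de_idx] = mags * signs
    observed = truth + rng.normal(0.0, config.null_noise_sd, size=n)
    stat = observed / config.null_noise_sd
    pvalue = np.clip(2.0 * stats.norm.sf(np.abs(stat)), 1e-300, 1.0)
    padj = np.clip(bh_adjust(pvalue), 1e-300, 1.0)
    records = [
        DifferentialExpressionRecord(gene=g, log2fc=float(observed[i]),
                                     pvalue=float(pvalue[i]), padj=float(padj[i]),
                                     stat=float(stat[i]))
        for i, g in enumerate(genes)
    ]
    return records, {g: float(truth[i]) for i, g in enumerate(genes)}


def simulate_library(query_truth: Mapping[str, float], config: SimulationConfig):
    """Simulate a perturbation library with planted connectivity structure.

    Mimics: z = mimic_weight * standardized(query log2FC) + Normal(0,
    noise_sd^2); inverters are the sign-flipped analogue; decoys are i.i.d.
    standard normal.  Compound names carry the role (mimic_1, inverter_1,
    decoy_1, ...).
    """
    if not query_truth:
        raise ValueError("query truth mapping is empty")
    genes = list(query_truth)
    x = np.array([query_truth[g] for g in genes], dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("query log2FC is constant; cannot standardize")
    std = (x - x.mean()) / sd
    lib = config.library
    rng = np.random.default_rng((config.seed, 1))
    sigs = []

    def make(name: str, z: np.ndarray) -> PerturbationSignature:
        return PerturbationSignature(
            compound=name, dose="10 uM", treat_time="24 h", cell="SIM", batch="sim0",
            zscores={g: float(z[i]) for i, g in enumerate(genes)},
        )

    for i in range(lib.n_mimics):
        z = lib.mimic_weight * std + rng.normal(0.0, lib.noise_sd, size=len(genes))
        sigs.append(make(f"mimic_{i + 1}", z))
    for i in range(lib.n_inverters):
        z = -lib.mimic_weight * std + rng.normal(0.0, lib.noise_sd, size=len(genes))
        sigs.append(make(f"inverter_{i + 1}", z))
    for i in range(lib.n_decoys):
        sigs.append(make(f"decoy_{i + 1}", rng.normal(0.0, 1.0, size=len(genes))))
    return sigs


def simulate_gene_sets(n_sets: int, size_range, universe: Sequence[str],
                       frac_enriched: float, target_genes: Sequence[str],
                       seed: int, n_enriched: int = 1):
    """Simulate a gene-set collection with optionally planted enrichment.

    The first ``n_enriched`` sets draw round(frac_enriched * size) members
    from ``target_genes`` (the rest uniformly from the remaining universe);
    all other sets are uniform draws from the universe.
    """
    lo, hi = size_range
    universe = list(universe)
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError(f"invalid size_range {size_range!r} for universe of {len(universe)}")
    if not (0.0 <= frac_enriched <= 1.0):
        raise ValueError("frac_enriched must be in [0, 1]")
    target = list(target_genes)
    rng = np.random.default_rng((seed, 2))
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        planted = frac_enriched > 0 and i < n_enriched and target
        if planted:
            n_t = min(int(round(frac_enriched * size)), len(target))
            picked = list(rng.choice(target, size=n_t, replace=False))
            pool = [g for g in universe if g not in set(picked)]
            rest = list(rng.choice(pool, size=size - n_t, replace=False))
            members = picked + rest
            desc = "planted"
        else:
            members = list(rng.choice(universe, size=size, replace=False))
            desc = "random"
        sets.append(GeneSet(set_id=f"SET_{i + 1}", description=desc, members=frozenset(members)))
    return sets


def simulate_metabolite_network(n_metabolites: int, degree_range, universe: Sequence[str],
                                seed: int):
    """Toy bipartite metabolite -> gene neighborhoods (stand-in for a genome-scale
    metabolic model's gene–metabolite adjacency)."""
    lo, hi = degree_range
    universe = list(universe)
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError(f"invalid degree_range {degree_range!r} for universe of {len(universe)}")
    rng = np.random.default_rng((seed, 3))
    network = {}
    for i in range(n_metabolites):
        k = int(rng.integers(lo, hi + 1))
        network[f"M{i + 1:04d}"] = sorted(rng.choice(universe, size=k, replace=False))
    return network


def simulate_pathway_models(n_pathways: int, n_targets: int, universe: Sequence[str],
                            seed: int):
    """Random footprint pathway models: Normal(0,1) weights on random gene subsets."""
    from .downstream import PathwayModel

    universe = list(universe)
    if not (1 <= n_targets <= len(universe)):
        raise ValueError("n_targets must be in [1, len(universe)]")
    rng = np.random.default_rng((seed, 4))
    models = []
    for i in range(n_pathways):
        genes = rng.choice(universe, size=n_targets, replace=False)
        weights = rng.normal(0.0, 1.0, size=n_targets)
        models.append(PathwayModel(pathway=f"PW_{i + 1}",
                                   weights={g: float(w) for g, w in zip(genes, weights)}))
    return models


def simulate_counts(n_genes: int = 50, n_samples: int = 4, mean_high: float = 50.0,
                    seed: int = 0) -> CountTable:
    """Small Poisson count table, provided only to exercise count filtering."""
    rng = np.random.default_rng((seed, 5))
    means = rng.uniform(0.0, mean_high, size=n_genes)
    counts = rng.poisson(means[:, None], size=(n_genes, n_samples)).astype(float)
    return CountTable(
        genes=tuple(f"G{i:05d}" for i in range(n_genes)),
        samples=tuple(f"S{j + 1}" for j in range(n_samples)),
        counts=counts,
    )
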