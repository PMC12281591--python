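import numpy as np
import pytest

import sigscreen as ss


@pytest.fixture
def ranked4():
    """4-gene ranking with metrics (3, 2, 1, 0.5)."""
    return ss.RankedSignature(entries=(("gA", 3.0), ("gB", 2.0), ("gC", 1.0), ("gD", 0.5)))


@pytest.fixture
def ranked10():
    """Symmetric 10-gene ranking with metrics 5..1, -1..-5."""
    metrics = [5.0, 4.0, 3.0, 2.0, 1.0, -1.0, -2.0, -3.0, -4.0, -5.0]
    genes = [f"g{i}" for i in range(10)]
    return ss.RankedSignature(entries=tuple(zip(genes, metrics)))


@pytest.fixture
def de_table_path(tmp_path):
    path = tmp_path / "de.tsv"
    path.write_text(
        "gene\tlog2FoldChange\tpvalue\tpadj\tstat\n"
        "gA\t1.500000\t1.000000e-03\t3.000000e-03\t3.290000\n"
        "gB\t-0.700000\t2.000000e-02\t4.000000e-02\t-2.330000\n"
        "gC\t0.100000\t5.000000e-01\t6.000000e-01\t0.670000\n"
    )
    return path


def brute_force_es(genes, metrics, members, exponent=1.0):
    """Independent cumulative-sum ES oracle (plain python loop)."""
    n = len(genes)
    hits = [g in members for g in genes]
    n_hit = sum(hits)
    n_r = sum(abs(m) ** exponent for g, m, h in zip(genes, metrics, hits) if h)
    run, best = 0.0, 0.0
    for m, h in zip(metrics, hits):
        run += (abs(m) ** exponent / n_r) if h else -1.0 / (n - n_hit)
        if abs(run) > abs(best):
            best = run
    return best


def naive_bh(pvalues):
    """O(m^2) direct-minimum Benjamini-Hochberg oracle."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for pos, i in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * m / j for j in range(pos, m + 1)]
        adj[i] = min(1.0, min(candidates))
    return adj
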