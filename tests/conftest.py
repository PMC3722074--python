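"""Shared fixtures: a small synthetic study world reused across unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from capbias.pipeline import ExperimentConfig, prepare_genomes_and_targets


SMALL_CFG = dict(
    n_chrom=2,
    chrom_length=60_000,
    n_targets=60,
    n_reads=30_000,
    wgs_reads=30_000,
)


@pytest.fixture(scope="session")
def small_world():
    """Genome pair + truth + orthologous annotated targets + k-mer indexes."""
    cfg = ExperimentConfig(**SMALL_CFG)
    return prepare_genomes_and_targets(cfg)


@pytest.fixture(scope="session")
def small_null_rep(small_world):
    """One unbiased 30k-read replicate, dual-mapped."""
    from capbias.pipeline import simulate_and_map
    from capbias.read_simulator import BiasModel

    return simulate_and_map(small_world, BiasModel(), seed=101)


def semiglobal_levenshtein(query: str, window: str) -> int:
    """Independent full-DP edit distance of query vs the best substring of window.

    Row-vectorized Wagner-Fischer with free gaps at both window ends; the
    in-row insertion dependency is resolved with a running-minimum transform.
    """
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    w = np.frombuffer(window.encode(), dtype=np.uint8)
    m, n = len(q), len(w)
    ar = np.arange(n + 1)
    prev = np.zeros(n + 1, dtype=int)  # free leading gaps in the window
    for i in range(m):
        cur = np.empty(n + 1, dtype=int)
        cur[0] = i + 1
        cur[1:] = np.minimum(prev[:-1] + (w != q[i]), prev[1:] + 1)
        cur = np.minimum.accumulate(cur - ar) + ar  # cur[j] = min(cur[j], cur[j-1]+1)
        prev = cur
    return int(prev.min())  # free trailing gaps
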