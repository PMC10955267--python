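"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths: naive
text scanning for FM-index checks and a plain-Python affine-gap DP for
Smith-Waterman checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from trialign import indexer as ix
from trialign import synthetic as syn
from trialign.io_formats import QueryRecord


# ---------------------------------------------------------------------------
# Oracles


def naive_occurrences(text: np.ndarray, pattern: np.ndarray) -> list[int]:
    """All start positions of ``pattern`` in ``text`` by direct scanning."""
    m = len(pattern)
    if m == 0:
        return list(range(len(text)))
    return [
        i
        for i in range(len(text) - m + 1)
        if (text[i : i + m] == pattern).all()
    ]


def naive_half_exact(text, seed, delta, restrict=True):
    """Occurrences of ``seed`` with <= delta mismatches restricted to the
    second half (brute-force restricted-Hamming scan)."""
    L = len(seed)
    half = (L + 1) // 2 if restrict else 0
    out = []
    for i in range(len(text) - L + 1):
        sub = text[i : i + L]
        mism = np.flatnonzero(sub != seed)
        if len(mism) <= delta and all(p >= half for p in mism):
            out.append(i)
    return out


def affine_dp_score(q, s, matrix, gap_extend, gap_open_extra) -> int:
    """Brute-force affine-gap local DP (scores only); a gap run of length g
    costs gap_open_extra + g * gap_extend."""
    m, n = len(q), len(s)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    go = gap_open_extra + gap_extend
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i - 1][j] + go, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + go, F[i][j - 1] + gap_extend)
            H[i][j] = max(
                0, H[i - 1][j - 1] + int(matrix[s[j - 1], q[i - 1]]), E[i][j], F[i][j]
            )
            best = max(best, H[i][j])
    return best


def path_lca(tree, taxids):
    """Root-path-intersection LCA oracle."""
    paths = [set(tree.path_to_root(t)) for t in taxids]
    common = set.intersection(*paths)
    # deepest = the common node with the longest path to root
    return max(common, key=lambda t: len(tree.path_to_root(t)))


def records_of(pairs) -> list[QueryRecord]:
    return [
        QueryRecord(rid, "", seq, None, i) for i, (rid, seq) in enumerate(pairs)
    ]


# ---------------------------------------------------------------------------
# Toy archives (session-scoped: index builds are the slow part)


@pytest.fixture(scope="session")
def toy_genome():
    cfg = syn.SimConfig(seed=42, genome_length=60_000, n_sequences=3)
    return syn.random_genome(cfg)


@pytest.fixture(scope="session")
def nt_archive(toy_genome):
    return ix.build_index([(g[0], "", g[1]) for g in toy_genome], "nucleotide")


@pytest.fixture(scope="session")
def bs_archive(toy_genome):
    return ix.build_index([(g[0], "", g[1]) for g in toy_genome], "bisulfite")


@pytest.fixture(scope="session")
def toy_proteome():
    cfg = syn.SimConfig(seed=43, genome_length=30_000, n_sequences=10)
    return syn.random_proteome(cfg)


@pytest.fixture(scope="session")
def prot_archive(toy_proteome):
    return ix.build_index([(p[0], "", p[1]) for p in toy_proteome], "protein")
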