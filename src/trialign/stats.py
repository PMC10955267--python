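"""Karlin-Altschul significance statistics.

Raw local-alignment scores S are normalized to bit-scores
``S' = (lambda*S - ln K) / ln 2`` using per-scoring-scheme constants, and
e-values follow as ``E = m * n * 2**(-S')`` where m is the query length and
n the total residue count of the database.  The inverse gives the widely
used pre-computed threshold ``floor(log2(m*n/E))`` for a chosen e-value
cut-off.  Edge-effect (effective length) corrections and composition-based
statistics are deliberately not applied.

The constants shipped for the bisulfite presets are the plain nucleotide
ones: asymmetric conversion-aware matrices have no published constants, so
bisulfite e-values are approximate and the search interface requires either
an explicit bit-score threshold or an acknowledgment flag.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

__all__ = [
    "KarlinParams",
    "ThresholdSpec",
    "get_karlin_params",
    "bitscore_from_raw",
    "evalue_from_bitscore",
    "bitscore_threshold_from_evalue",
    "raw_from_bitscore",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class KarlinParams:
    """Gapped Karlin-Altschul constants for one scoring preset."""

    preset: str
    lam: float  # nats per raw-score unit
    K: float

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass(frozen=True)
class ThresholdSpec:
    """Active report thresholds plus the (m, n) search-space dimensions."""

    max_evalue: float | None
    min_bitscore: float | None
    min_pct_identity: float | None
    query_length: int
    db_size: int

    def __post_init__(self) -> None:
        if self.max_evalue is not None and self.max_evalue <= 0:
            raise ValueError("e-value cut-off must be positive")
        if self.query_length < 1 or self.db_size < 1:
            raise ValueError("m and n must be >= 1")


def _load_params() -> dict[str, KarlinParams]:
    text = (
        importlib.resources.files("trialign.data")
        .joinpath("karlin_params.tsv")
        .read_text()
    )
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        preset, lam, k = line.split("\t")
        out[preset] = KarlinParams(preset, float(lam), float(k))
    return out


_PARAMS: dict[str, KarlinParams] = {}


def get_karlin_params(preset: str) -> KarlinParams:
    if not _PARAMS:
        _PARAMS.update(_load_params())
    try:
        return _PARAMS[preset]
    except KeyError:
        raise KeyError(f"no Karlin-Altschul constants for preset {preset!r}") from None


def bitscore_from_raw(raw: float, kp: KarlinParams) -> float:
    """(lambda*S - ln K) / ln 2 — strictly increasing in S."""
    return (kp.lam * raw - math.log(kp.K)) / _LN2


def raw_from_bitscore(bits: float, kp: KarlinParams) -> float:
    """Inverse of :func:`bitscore_from_raw` (raw-score equivalent)."""
    return (bits * _LN2 + math.log(kp.K)) / kp.lam


def evalue_from_bitscore(m: int, n: int, bitscore: float) -> float:
    """E = m * n * 2**(-bitscore)."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    return m * n * math.pow(2.0, -bitscore)


def bitscore_threshold_from_evalue(m: int, n: int, evalue: float) -> int:
    """floor(log2(m*n/E)): the integer bit-score equivalent of an e-value
    cut-off for query length m and database size n."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    if evalue <= 0:
        raise ValueError("e-value cut-off must be positive")
    return math.floor(math.log2(m * n / evalue))
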