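"""Sequence alphabets, encodings and the reductions used by the three search domains.

The engine works on rank-encoded sequences (``numpy.uint8`` arrays).  Three
original alphabets exist: ``dna5`` (A, C, G, T, N) for nucleotide data,
``aa27`` (26 letters + stop) for protein data, and the artificial six-letter
bisulfite alphabet ``bs6``.  Searching happens in *reduced* spaces:

* protein: aa27 -> li10 (default) or mu10, ten functional groups each;
* nucleotide: dna5 -> dna4, with N replaced by a seeded random base;
* bisulfite: dna5 -> bs6, where the first three ranks encode the C=T
  collapse (reads from the original strands) and the last three the G=A
  collapse (reads from reverse complements of the original strands).  The
  two images are disjoint, so a single index serves both strand families.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "Alphabet",
    "ReductionMap",
    "FrameTag",
    "QueryFrame",
    "DNA5",
    "DNA4",
    "AA27",
    "BS6",
    "encode",
    "decode",
    "reverse_complement",
    "translate_frame",
    "reduce",
    "reduce_bisulfite",
    "query_frames",
    "get_reduction",
]


@dataclass(frozen=True)
class Alphabet:
    """A rank codec: bijection between ``symbols`` and ranks ``0..size-1``.

    Unknown input characters map to the wildcard rank (N for nucleotides,
    X for aa27); encoding is total and never raises.
    """

    name: str
    symbols: str
    wildcard: str | None = None
    _lut: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        wc_rank = self.symbols.index(self.wildcard) if self.wildcard else 0
        lut = np.full(256, wc_rank, dtype=np.uint8)
        for rank, ch in enumerate(self.symbols):
            lut[ord(ch)] = rank
            lut[ord(ch.lower())] = rank
        if self.is_nucleotide:
            lut[ord("U")] = self.symbols.index("T")
            lut[ord("u")] = self.symbols.index("T")
        object.__setattr__(self, "_lut", lut)

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def is_nucleotide(self) -> bool:
        return self.name in ("dna5", "dna4")

    def encode(self, text: str) -> np.ndarray:
        raw = np.frombuffer(text.encode("ascii", errors="replace"), dtype=np.uint8)
        return self._lut[raw]

    def decode(self, seq: np.ndarray) -> str:
        syms = np.frombuffer(self.symbols.encode(), dtype=np.uint8)
        return syms[np.asarray(seq, dtype=np.uint8)].tobytes().decode()


DNA5 = Alphabet("dna5", "ACGTN", wildcard="N")
DNA4 = Alphabet("dna4", "ACGT")
AA27 = Alphabet("aa27", "ABCDEFGHIJKLMNOPQRSTUVWXYZ*", wildcard="X")
#: bs6 ranks 0-2 are the C=T half (A, T, G), ranks 3-5 the G=A half (a, c, t).
BS6 = Alphabet("bs6", "ATGact")

_DNA5_N = DNA5.encode("N")[0]
_COMPLEMENT = DNA5.encode("TGCAN")  # A<->T, C<->G, N<->N

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"


def encode(text: str, alphabet: Alphabet) -> np.ndarray:
    """Encode ``text`` into ranks; lowercase accepted, U folded to T, unknowns
    become the wildcard rank."""
    return alphabet.encode(text)


def decode(seq: np.ndarray, alphabet: Alphabet) -> str:
    return alphabet.decode(seq)


def reverse_complement(seq: np.ndarray) -> np.ndarray:
    """Reverse complement of a dna5 rank sequence (N self-complementary)."""
    return _COMPLEMENT[np.asarray(seq, dtype=np.uint8)][::-1]


def _codon_lut() -> np.ndarray:
    """64-entry codon->aa27 rank lookup (standard genetic code)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    lut = np.zeros(64, dtype=np.uint8)
    stop_rank = AA27.encode("*")[0]
    for i, b1 in enumerate("ACGT"):
        for j, b2 in enumerate("ACGT"):
            for k, b3 in enumerate("ACGT"):
                codon = b1 + b2 + b3
                aa = table.forward_table.get(codon)
                rank = stop_rank if aa is None else AA27.encode(aa)[0]
                lut[i * 16 + j * 4 + k] = rank
    return lut


_CODON_LUT = _codon_lut()
_AA27_X = AA27.encode("X")[0]


def translate_frame(seq: np.ndarray, frame: int) -> np.ndarray:
    """Translate a dna5 rank sequence in one of six reading frames.

    Frames 0-2 are the forward strand at offsets 0-2; frames 3-5 the reverse
    complement at offsets 0-2.  The trailing partial codon is dropped, any
    codon containing N yields X, stop codons yield ``*``.
    """
    if not 0 <= frame <= 5:
        raise ValueError(f"frame must be 0..5, got {frame}")
    s = np.asarray(seq, dtype=np.uint8)
    if frame >= 3:
        s = reverse_complement(s)
    s = s[frame % 3 :]
    n_codons = len(s) // 3
    if n_codons == 0:
        return np.empty(0, dtype=np.uint8)
    codons = s[: n_codons * 3].reshape(n_codons, 3).astype(np.int64)
    has_n = (codons == _DNA5_N).any(axis=1)
    idx = codons[:, 0] * 16 + codons[:, 1] * 4 + codons[:, 2]
    idx[has_n] = 0  # arbitrary valid index; overwritten with X below
    out = _CODON_LUT[idx]
    out[has_n] = _AA27_X
    return out


# ---------------------------------------------------------------------------
# Reductions


@dataclass(frozen=True)
class ReductionMap:
    """A total rank->rank mapping from ``source`` onto ``target``.

    ``replace_n`` marks nucleotide reductions in which N has no image and is
    substituted by a random base first (seeded, hence reproducible).
    """

    name: str
    source: Alphabet
    target: Alphabet
    table: np.ndarray
    replace_n: bool = False

    def __post_init__(self) -> None:
        if len(self.table) != self.source.size:
            raise ValueError("reduction table must be total over the source alphabet")


def _load_group_file(fname: str) -> list[list[str]]:
    text = (
        importlib.resources.files("trialign.data").joinpath(fname).read_text()
    )
    groups = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        groups.append(line.split())
    return groups


def _protein_reduction(name: str) -> ReductionMap:
    groups = _load_group_file(f"{name}.txt")
    reps = "".join(g[0] for g in groups)
    target = Alphabet(name, reps, wildcard="X" if "X" in reps else None)
    table = np.full(AA27.size, target.symbols.index("X"), dtype=np.uint8)
    for rank, group in enumerate(groups):
        for member in group:
            table[AA27.symbols.index(member)] = rank
    return ReductionMap(name, AA27, target, table)


def _dna4_reduction() -> ReductionMap:
    table = np.array([0, 1, 2, 3, 0], dtype=np.uint8)  # N entry unused
    return ReductionMap("dna4", DNA5, DNA4, table, replace_n=True)


def _bs6_reduction(mode: str) -> ReductionMap:
    if mode == "ct":
        table = np.array([0, 1, 2, 1, 0], dtype=np.uint8)  # A C G T (N unused)
    elif mode == "ga":
        table = np.array([3, 4, 3, 5, 0], dtype=np.uint8)
    else:
        raise ValueError(f"unknown bisulfite mode {mode!r}")
    return ReductionMap(f"bs6_{mode}", DNA5, BS6, table, replace_n=True)


def _identity_reduction(alphabet: Alphabet) -> ReductionMap:
    return ReductionMap(
        "identity", alphabet, alphabet, np.arange(alphabet.size, dtype=np.uint8)
    )


_REDUCTIONS: dict[str, ReductionMap] = {}


def get_reduction(name: str) -> ReductionMap:
    """Look up a reduction by name: li10, mu10, dna4, bs6_ct, bs6_ga, identity."""
    if not _REDUCTIONS:
        _REDUCTIONS["li10"] = _protein_reduction("li10")
        _REDUCTIONS["mu10"] = _protein_reduction("mu10")
        _REDUCTIONS["dna4"] = _dna4_reduction()
        _REDUCTIONS["bs6_ct"] = _bs6_reduction("ct")
        _REDUCTIONS["bs6_ga"] = _bs6_reduction("ga")
        _REDUCTIONS["identity"] = _identity_reduction(AA27)
    try:
        return _REDUCTIONS[name]
    except KeyError:
        raise KeyError(f"unknown reduction {name!r}") from None


def replace_n(seq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace N ranks in a dna5 sequence by random bases (deterministic
    under the generator's state)."""
    seq = np.asarray(seq, dtype=np.uint8)
    mask = seq == _DNA5_N
    if not mask.any():
        return seq
    out = seq.copy()
    out[mask] = rng.integers(0, 4, size=int(mask.sum()), dtype=np.uint8)
    return out


def reduce(
    seq: np.ndarray, rmap: ReductionMap, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Element-wise alphabet reduction; length preserved.

    For reductions with ``replace_n`` (dna4, bs6_*) an ``rng`` is required so
    the N substitution is reproducible.
    """
    seq = np.asarray(seq, dtype=np.uint8)
    if rmap.replace_n and (seq == _DNA5_N).any():
        if rng is None:
            raise ValueError(f"reduction {rmap.name} requires an rng for N replacement")
        seq = replace_n(seq, rng)
    return rmap.table[seq]


def reduce_bisulfite(
    seq: np.ndarray, mode: str, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Reduce a dna5 sequence into the requested half of the bs6 alphabet.

    CT mode collapses C and T (image ranks {0,1,2}); GA mode collapses G and
    A (image ranks {3,4,5}).
    """
    return reduce(seq, get_reduction(f"bs6_{mode.lower()}"), rng)


# ---------------------------------------------------------------------------
# Query frames


class FrameTag(NamedTuple):
    """Identifies one translated/reduced view of a sequence.

    ``strand`` is +1/-1, ``offset`` the translation offset (0 except for
    protein-domain translation of nucleotides), ``conversion`` is "ct"/"ga"
    for bisulfite views and None otherwise.
    """

    strand: int
    offset: int = 0
    conversion: str | None = None


@dataclass(frozen=True)
class QueryFrame:
    tag: FrameTag
    unreduced: np.ndarray  # translated, unreduced ranks (aa27 or dna5)
    reduced: np.ndarray  # same length, in the index's reduced alphabet


def query_frames(
    seq: np.ndarray,
    domain: str,
    *,
    reduction: ReductionMap | None = None,
    nucleotide_query: bool = True,
    rng: np.random.Generator | None = None,
) -> list[QueryFrame]:
    """Generate the per-domain reduced query frames in their fixed order.

    protein: 1 frame for protein input, 6 translated frames for nucleotide
    input; nucleotide: forward + reverse complement, dna4-reduced;
    bisulfite: fwd-CT, fwd-GA, rc-CT, rc-GA in the bs6 alphabet.
    """
    seq = np.asarray(seq, dtype=np.uint8)
    if domain == "protein":
        if reduction is None:
            reduction = get_reduction("li10")
        if not nucleotide_query:
            return [QueryFrame(FrameTag(+1), seq, reduce(seq, reduction))]
        frames = []
        for f in range(6):
            tag = FrameTag(+1 if f < 3 else -1, f % 3)
            prot = translate_frame(seq, f)
            frames.append(QueryFrame(tag, prot, reduce(prot, reduction)))
        return frames
    if domain == "nucleotide":
        rmap = get_reduction("dna4")
        rc = reverse_complement(seq)
        return [
            QueryFrame(FrameTag(+1), seq, reduce(seq, rmap, rng)),
            QueryFrame(FrameTag(-1), rc, reduce(rc, rmap, rng)),
        ]
    if domain == "bisulfite":
        rc = reverse_complement(seq)
        out = []
        for strand, s in ((+1, seq), (-1, rc)):
            for mode in ("ct", "ga"):
                out.append(
                    QueryFrame(
                        FrameTag(strand, conversion=mode),
                        s,
                        reduce_bisulfite(s, mode, rng),
                    )
                )
        # fixed order: fwd-CT, fwd-GA, rc-CT, rc-GA
        return [out[0], out[1], out[2], out[3]]
    raise ValueError(f"unknown domain {domain!r}")
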