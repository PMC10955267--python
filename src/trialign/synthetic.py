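"""Synthetic fixture generator: toy genomes/proteomes, reads with controlled
substitution errors, in-silico bisulfite conversion and toy taxonomies.

Everything is deterministic given the configured seed, so tests and the
acceptance checks run without any external data.  Defaults mirror a typical
short-read experiment: uniform 50% GC genomes, 100 bp reads with a 1%
substitution rate, and a 99% bisulfite conversion rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabets import AA27, CANONICAL_AA

__all__ = [
    "SimConfig",
    "random_genome",
    "random_proteome",
    "sample_reads",
    "bisulfite_convert",
    "sample_bisulfite_reads",
    "toy_taxonomy",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    genome_length: int = 100_000
    gc: float = 0.5
    n_sequences: int = 1
    read_count: int = 500
    read_length: int = 100
    substitution_rate: float = 0.01
    conversion_rate: float = 0.99
    conversion_mode: str = "ct"
    taxonomy_nodes: int = 16

    def __post_init__(self) -> None:
        for attr in ("gc", "substitution_rate", "conversion_rate"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1]")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")


def random_genome(config: SimConfig) -> list[tuple[str, str]]:
    """i.i.d. random genome records at the configured GC fraction."""
    rng = np.random.default_rng([config.seed, 1])
    p = np.array(
        [
            (1 - config.gc) / 2,
            config.gc / 2,
            config.gc / 2,
            (1 - config.gc) / 2,
        ]
    )
    per = config.genome_length // config.n_sequences
    out = []
    for i in range(config.n_sequences):
        n = per if i < config.n_sequences - 1 else config.genome_length - per * (
            config.n_sequences - 1
        )
        seq = _BASES[rng.choice(4, size=n, p=p)].tobytes().decode()
        out.append((f"chr{i + 1}", seq))
    return out


def random_proteome(config: SimConfig) -> list[tuple[str, str]]:
    """Random protein records over the 20 canonical residues; total length
    is ``genome_length`` split across ``n_sequences``."""
    rng = np.random.default_rng([config.seed, 2])
    aa = np.frombuffer(CANONICAL_AA.encode(), dtype=np.uint8)
    per = max(1, config.genome_length // config.n_sequences)
    return [
        (f"prot{i + 1}", aa[rng.integers(0, len(aa), size=per)].tobytes().decode())
        for i in range(config.n_sequences)
    ]


_COMPL = dict(zip("ACGTN", "TGCAN"))


def _revcomp(s: str) -> str:
    return "".join(_COMPL[c] for c in reversed(s))


def sample_reads(
    genome: list[tuple[str, str]], config: SimConfig, alphabet: str = "ACGT"
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Sample reads at uniform positions and strands with i.i.d.
    substitution errors; returns (reads, truth table)."""
    rng = np.random.default_rng([config.seed, 3])
    reads, truth = [], []
    nucleotide = set(alphabet) <= set("ACGTN")
    for k in range(config.read_count):
        origin = int(rng.integers(0, len(genome)))
        rid, seq = genome[origin]
        if len(seq) < config.read_length:
            raise ValueError("read length exceeds genome sequence length")
        start = int(rng.integers(0, len(seq) - config.read_length + 1))
        frag = seq[start : start + config.read_length]
        strand = "+"
        if nucleotide and rng.random() < 0.5:
            frag = _revcomp(frag)
            strand = "-"
        arr = np.frombuffer(frag.encode(), dtype=np.uint8).copy()
        sub_mask = rng.random(len(arr)) < config.substitution_rate
        if sub_mask.any():
            pool = np.frombuffer(alphabet.encode(), dtype=np.uint8)
            for i in np.flatnonzero(sub_mask):
                choices = pool[pool != arr[i]]
                arr[i] = choices[rng.integers(0, len(choices))]
        reads.append((f"read{k}", arr.tobytes().decode()))
        truth.append(
            {
                "read": f"read{k}",
                "origin": rid,
                "strand": strand,
                "start": start,
                "end": start + config.read_length,
                "n_subs": int(sub_mask.sum()),
            }
        )
    return reads, truth


def bisulfite_convert(
    read: str, rate: float, mode: str = "ct", seed: int | np.random.Generator = 0
) -> str:
    """Convert each C to T (CT mode) or each G to A (GA mode) independently
    with probability ``rate``; deterministic under the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    src, dst = ("C", "T") if mode.lower() == "ct" else ("G", "A")
    out = []
    for ch in read:
        if ch == src and rng.random() < rate:
            out.append(dst)
        else:
            out.append(ch)
    return "".join(out)


#: the four bisulfite read types: (take reverse complement of the fragment
#: before conversion?, conversion mode, rc after conversion?)
_READ_TYPES = {
    "OT": (False, "ct", False),  # original top strand
    "OB": (True, "ct", False),  # original bottom strand
    "CTOT": (False, "ct", True),  # complement-to-original-top (amplification)
    "CTOB": (True, "ct", True),
}


def sample_bisulfite_reads(
    genome: list[tuple[str, str]],
    config: SimConfig,
    mode: str = "four-type",
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Sample bisulfite-converted reads.

    ``mode="uniform-strand"`` converts every read in the configured
    direction on its sampled strand (the simplification used for simulated
    benchmark data); ``mode="four-type"`` draws one of the four read types
    (original strands and their amplification reverse complements) uniformly.
    """
    rng = np.random.default_rng([config.seed, 4])
    type_names = list(_READ_TYPES)
    reads, truth = [], []
    for k in range(config.read_count):
        origin = int(rng.integers(0, len(genome)))
        rid, seq = genome[origin]
        start = int(rng.integers(0, len(seq) - config.read_length + 1))
        frag = seq[start : start + config.read_length]
        if mode == "uniform-strand":
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = _revcomp(frag)
            read = bisulfite_convert(frag, config.conversion_rate, config.conversion_mode, rng)
            rtype = f"uniform-{config.conversion_mode}"
        else:
            rtype = type_names[int(rng.integers(0, 4))]
            rc_first, conv, rc_after = _READ_TYPES[rtype]
            s = _revcomp(frag) if rc_first else frag
            s = bisulfite_convert(s, config.conversion_rate, conv, rng)
            read = _revcomp(s) if rc_after else s
            strand = "-" if rc_first else "+"
        reads.append((f"read{k}", read))
        truth.append(
            {
                "read": f"read{k}",
                "origin": rid,
                "strand": strand,
                "type": rtype,
                "start": start,
                "end": start + config.read_length,
            }
        )
    return reads, truth


def toy_taxonomy(config: SimConfig, seq_ids: list[str] | None = None):
    """Random rooted tree (node i's parent drawn from 1..i-1) plus a
    seqid->taxid map over ``seq_ids`` (leaves preferred); returns
    (nodes rows, seq2taxid dict).  Node 1 is the root."""
    rng = np.random.default_rng([config.seed, 5])
    n = max(1, config.taxonomy_nodes)
    parent = {1: 1}
    for i in range(2, n + 1):
        parent[i] = int(rng.integers(1, i))
    rows = [(t, p, "no rank", f"node{t}") for t, p in parent.items()]
    seq2taxid = {}
    if seq_ids:
        internal = {p for t, p in parent.items() if t != p}
        leaves = [t for t in parent if t not in internal] or [1]
        for sid in seq_ids:
            seq2taxid[sid] = int(leaves[int(rng.integers(0, len(leaves)))])
    return rows, seq2taxid


def write_taxonomy(rows, seq2taxid, nodes_path, map_path) -> None:
    with open(nodes_path, "w") as fh:
        for t, p, rank, name in rows:
            fh.write(f"{t}\t{p}\t{rank}\t{name}\n")
    with open(map_path, "w") as fh:
        for sid, t in seq2taxid.items():
            fh.write(f"{sid}\t{t}\n")
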