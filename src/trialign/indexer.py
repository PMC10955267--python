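"""Index construction and the single-file archive format.

``build_index`` frames the subject collection for its domain (six-frame
translation for nucleotide input to the protein domain; CT- and GA-reduced
duplicates in the bisulfite domain), reduces every frame, concatenates the
blocks with separator ranks and builds the FM-index.  The archive stores the
FM-index, the original subjects, the concatenation map, the domain
configuration, the N-replacement seed and (optionally) taxonomy — one file,
optionally zlib-compressed.
"""

from __future__ import annotations

import json
import struct
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import alphabets as ab
from .alphabets import AA27, DNA5, FrameTag
from .fmindex import FmIndex, build_fmindex
from .taxonomy import TaxTree

__all__ = [
    "SubjectStore",
    "ConcatMap",
    "IndexArchive",
    "ArchiveError",
    "BadMagicError",
    "VersionError",
    "TruncatedError",
    "IndexBuildError",
    "detect_alphabet",
    "build_index",
    "save_archive",
    "load_archive",
    "FORMAT_VERSION",
]

MAGIC = b"TRIALGN\x01"
FORMAT_VERSION = 1

#: conversion tag codes for serialization
_CONV_CODE = {None: 0, "ct": 1, "ga": 2}
_CONV_NAME = {v: k for k, v in _CONV_CODE.items()}


class ArchiveError(ValueError):
    pass


class BadMagicError(ArchiveError):
    pass


class VersionError(ArchiveError):
    pass


class TruncatedError(ArchiveError):
    pass


class IndexBuildError(ValueError):
    pass


@dataclass
class SubjectStore:
    """Original subject sequences (dna5 or aa27 ranks) and identifiers."""

    ids: list[str]
    descriptions: list[str]
    sequences: list[np.ndarray]
    alphabet: str  # "dna5" or "aa27"

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise IndexBuildError("subject identifiers must be unique")
        self.lengths = np.array([len(s) for s in self.sequences], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class ConcatMap:
    """Tiling of the concatenated reduced text into (subject, frame) blocks.

    Block i occupies global offsets [starts[i], starts[i]+lengths[i]) and is
    followed by one separator rank."""

    starts: np.ndarray
    lengths: np.ndarray
    subject_idx: np.ndarray
    tags: list[FrameTag]

    def resolve(self, pos: int) -> tuple[int, FrameTag, int]:
        """Map a global text position to (subject index, frame tag, local offset)."""
        i = int(np.searchsorted(self.starts, pos, side="right")) - 1
        local = pos - int(self.starts[i])
        if i < 0 or local >= int(self.lengths[i]):
            raise ValueError(f"position {pos} falls on a separator")
        return int(self.subject_idx[i]), self.tags[i], local

    @property
    def n_frames(self) -> int:
        return len(self.tags)


@dataclass
class IndexArchive:
    domain: str
    reduction_name: str
    fm: FmIndex
    subjects: SubjectStore
    concat: ConcatMap
    rng_seed: int
    seeding_defaults: dict
    taxonomy: TaxTree | None = None
    subject_taxids: np.ndarray | None = None  # per subject, 0 = unassigned
    format_version: int = FORMAT_VERSION
    _frame_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def db_size(self) -> int:
        """Total residue count of the *original* subjects (bisulfite
        duplication and translation frames do not inflate n)."""
        return int(self.subjects.lengths.sum())

    @property
    def subjects_translated(self) -> bool:
        return self.domain == "protein" and self.subjects.alphabet == "dna5"

    def subject_frame_unreduced(self, subject_idx: int, tag: FrameTag) -> np.ndarray:
        """The unreduced (translated) frame a hit's coordinates live in;
        computed on demand from the stored original sequence."""
        key = (subject_idx, tag.strand, tag.offset)
        cached = self._frame_cache.get(key)
        if cached is not None:
            return cached
        seq = self.subjects.sequences[subject_idx]
        if self.subjects_translated:
            frame = tag.offset + (0 if tag.strand > 0 else 3)
            out = ab.translate_frame(seq, frame)
        else:
            out = seq  # nucleotide/bisulfite subject frames are the forward sequence
        if len(self._frame_cache) > 256:
            self._frame_cache.clear()
        self._frame_cache[key] = out
        return out


def detect_alphabet(records) -> str:
    """Classify input as nucleotide or protein: nucleotide iff >= 95% of the
    first 10,000 residues are A/C/G/T/N/U (case-insensitive)."""
    sample = []
    total = 0
    for _rid, seq in records:
        if total >= 10_000:
            break
        sample.append(seq[: 10_000 - total].upper())
        total += len(sample[-1])
    text = "".join(sample)
    if not text:
        raise IndexBuildError("cannot detect alphabet: no sequence data")
    nt = sum(text.count(c) for c in "ACGTNU")
    return "nucleotide" if nt / len(text) >= 0.95 else "protein"


_DEFAULT_SEEDING = {
    "protein": {"seed_length": 10, "seed_offset": 5, "seed_delta": 1, "adaptive_max_occ": 64},
    "nucleotide": {"seed_length": 14, "seed_offset": 7, "seed_delta": 1, "adaptive_max_occ": 64},
    "bisulfite": {"seed_length": 16, "seed_offset": 8, "seed_delta": 1, "adaptive_max_occ": 64},
}


def _subject_frames(store: SubjectStore, domain: str, reduction_name: str, rng):
    """Yield (subject_idx, FrameTag, reduced ranks) in index order."""
    if domain == "protein":
        rmap = ab.get_reduction(reduction_name)
        for i, seq in enumerate(store.sequences):
            if store.alphabet == "dna5":
                for f in range(6):
                    tag = FrameTag(+1 if f < 3 else -1, f % 3)
                    yield i, tag, ab.reduce(ab.translate_frame(seq, f), rmap)
            else:
                yield i, FrameTag(+1), ab.reduce(seq, rmap)
    elif domain == "nucleotide":
        rmap = ab.get_reduction("dna4")
        for i, seq in enumerate(store.sequences):
            yield i, FrameTag(+1), ab.reduce(seq, rmap, rng)
    elif domain == "bisulfite":
        for i, seq in enumerate(store.sequences):
            seq4 = ab.replace_n(seq, rng)
            yield i, FrameTag(+1, conversion="ct"), ab.reduce_bisulfite(seq4, "ct")
            yield i, FrameTag(+1, conversion="ga"), ab.reduce_bisulfite(seq4, "ga")
    else:
        raise ValueError(f"unknown domain {domain!r}")


def build_index(
    subjects,
    domain: str,
    *,
    reduction: str | None = None,
    rng_seed: int = 0,
    occ_rate: int = 64,
    sa_rate: int = 16,
    taxonomy: TaxTree | None = None,
    seq2taxid: dict[str, int] | None = None,
) -> IndexArchive:
    """Build a searchable archive from (id, description, sequence-string)
    records (as produced by :func:`trialign.io_formats.read_sequences`).

    Protein domain: nucleotide subjects are auto-detected and translated in
    six frames, then reduced (li10 default, mu10 or identity optional).
    Nucleotide domain: one dna4-reduced frame per subject.  Bisulfite
    domain: every subject is emitted twice, a CT-reduced copy then a
    GA-reduced copy, so one index serves both strand families.
    """
    records = [(r[0], r[1], r[2]) for r in subjects]
    if not records or all(len(r[2]) == 0 for r in records):
        raise IndexBuildError("no subject sequences")
    kind = detect_alphabet([(r[0], r[2]) for r in records])
    if domain in ("nucleotide", "bisulfite") and kind == "protein":
        raise IndexBuildError(f"the {domain} domain requires nucleotide subjects")
    if domain == "protein":
        reduction = reduction or "li10"
        if reduction not in ("li10", "mu10", "identity"):
            raise IndexBuildError(f"unknown protein reduction {reduction!r}")
        store_alpha = "dna5" if kind == "nucleotide" else "aa27"
    else:
        if reduction is not None and reduction != {"nucleotide": "dna4", "bisulfite": "bs6"}[domain]:
            raise IndexBuildError(f"domain {domain} has a fixed reduction")
        reduction = {"nucleotide": "dna4", "bisulfite": "bs6"}[domain]
        store_alpha = "dna5"
    alphabet = DNA5 if store_alpha == "dna5" else AA27
    store = SubjectStore(
        ids=[r[0] for r in records],
        descriptions=[r[1] for r in records],
        sequences=[ab.encode(r[2], alphabet) for r in records],
        alphabet=store_alpha,
    )
    rng = np.random.default_rng(rng_seed)
    starts, lengths, subject_idx, tags, chunks = [], [], [], [], []
    pos = 0
    sigma = 1
    for i, tag, reduced in _subject_frames(store, domain, reduction, rng):
        starts.append(pos)
        lengths.append(len(reduced))
        subject_idx.append(i)
        tags.append(tag)
        chunks.append(reduced.astype(np.uint8) + 1)  # shift: rank 0 = separator
        chunks.append(np.zeros(1, dtype=np.uint8))
        pos += len(reduced) + 1
    if domain == "protein":
        sigma = ab.get_reduction(reduction).target.size + 1
    elif domain == "nucleotide":
        sigma = 5
    else:
        sigma = 7
    text = np.concatenate(chunks)
    fm = build_fmindex(
        text, sigma, occ_rate=occ_rate, sa_rate=sa_rate,
        mark_positions=np.array(starts, dtype=np.int64),
    )
    concat = ConcatMap(
        starts=np.array(starts, dtype=np.int64),
        lengths=np.array(lengths, dtype=np.int64),
        subject_idx=np.array(subject_idx, dtype=np.int32),
        tags=tags,
    )
    subject_taxids = None
    if taxonomy is not None:
        mapping = seq2taxid or {}
        subject_taxids = np.array(
            [mapping.get(sid, 0) for sid in store.ids], dtype=np.int64
        )
    return IndexArchive(
        domain=domain,
        reduction_name=reduction,
        fm=fm,
        subjects=store,
        concat=concat,
        rng_seed=rng_seed,
        seeding_defaults=dict(_DEFAULT_SEEDING[domain]),
        taxonomy=taxonomy,
        subject_taxids=subject_taxids,
    )


# ---------------------------------------------------------------------------
# Serialization: magic + version + compression flag, then a zlib-optional
# payload of one JSON manifest followed by raw little-endian array bytes.


def _arrays_of(archive: IndexArchive) -> dict[str, np.ndarray]:
    fm = archive.fm
    seq_data = (
        np.concatenate(archive.subjects.sequences)
        if archive.subjects.sequences
        else np.empty(0, dtype=np.uint8)
    )
    seq_offsets = np.zeros(len(archive.subjects) + 1, dtype=np.int64)
    np.cumsum(archive.subjects.lengths, out=seq_offsets[1:])
    arrays = {
        "fm.bwt": fm.bwt,
        "fm.counts": fm.counts,
        "fm.occ_cp": fm.occ_cp,
        "fm.sa_marked": fm.sa_marked.astype(np.uint8),
        "fm.sa_mark_rank": fm.sa_mark_rank,
        "fm.sa_values": fm.sa_values,
        "subj.data": seq_data.astype(np.uint8),
        "subj.offsets": seq_offsets,
        "concat.starts": archive.concat.starts,
        "concat.lengths": archive.concat.lengths,
        "concat.subject_idx": archive.concat.subject_idx,
        "concat.strand": np.array([t.strand for t in archive.concat.tags], dtype=np.int8),
        "concat.offset": np.array([t.offset for t in archive.concat.tags], dtype=np.int8),
        "concat.conv": np.array(
            [_CONV_CODE[t.conversion] for t in archive.concat.tags], dtype=np.uint8
        ),
    }
    if archive.subject_taxids is not None:
        arrays["tax.subject_taxids"] = archive.subject_taxids
    return arrays


def save_archive(archive: IndexArchive, path, compress: bool = False) -> None:
    arrays = _arrays_of(archive)
    manifest = {
        "format_version": archive.format_version,
        "domain": archive.domain,
        "reduction": archive.reduction_name,
        "rng_seed": archive.rng_seed,
        "seeding_defaults": archive.seeding_defaults,
        "subject_alphabet": archive.subjects.alphabet,
        "subject_ids": archive.subjects.ids,
        "subject_descriptions": archive.subjects.descriptions,
        "fm": {
            "occ_rate": archive.fm.occ_rate,
            "sa_rate": archive.fm.sa_rate,
            "text_length": archive.fm.text_length,
            "sigma": archive.fm.sigma,
        },
        "taxonomy": None,
        "arrays": [],
    }
    if archive.taxonomy is not None:
        manifest["taxonomy"] = {
            "parent": list(archive.taxonomy.parent.items()),
            "rank": list(archive.taxonomy.rank.items()),
            "name": list(archive.taxonomy.name.items()),
        }
    blobs = []
    offset = 0
    for name, arr in arrays.items():
        data = np.ascontiguousarray(arr).tobytes()
        manifest["arrays"].append(
            {"name": name, "dtype": str(arr.dtype), "shape": list(arr.shape), "offset": offset, "nbytes": len(data)}
        )
        blobs.append(data)
        offset += len(data)
    mjson = json.dumps(manifest).encode()
    payload = struct.pack("<Q", len(mjson)) + mjson + b"".join(blobs)
    if compress:
        payload = zlib.compress(payload, level=6)
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<IB", archive.format_version, 1 if compress else 0))
        fh.write(payload)


def load_archive(path) -> IndexArchive:
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < len(MAGIC) + 5:
        raise TruncatedError("archive file too short")
    if blob[: len(MAGIC)] != MAGIC:
        raise BadMagicError("bad magic bytes: not a trialign archive")
    version, compressed = struct.unpack_from("<IB", blob, len(MAGIC))
    if version != FORMAT_VERSION:
        raise VersionError(
            f"archive format version {version} not supported (expected {FORMAT_VERSION})"
        )
    payload = blob[len(MAGIC) + 5 :]
    if compressed:
        try:
            payload = zlib.decompress(payload)
        except zlib.error as exc:
            raise TruncatedError(f"corrupt compressed payload: {exc}") from None
    try:
        (mlen,) = struct.unpack_from("<Q", payload, 0)
        manifest = json.loads(payload[8 : 8 + mlen])
        body = payload[8 + mlen :]
        arrays = {}
        for spec in manifest["arrays"]:
            a = np.frombuffer(
                body, dtype=np.dtype(spec["dtype"]), count=int(np.prod(spec["shape"], dtype=np.int64)), offset=spec["offset"]
            ).reshape(spec["shape"])
            arrays[spec["name"]] = a.copy()
    except (struct.error, ValueError, KeyError) as exc:
        raise TruncatedError(f"truncated or corrupt archive: {exc}") from None
    fmmeta = manifest["fm"]
    fm = FmIndex(
        bwt=arrays["fm.bwt"],
        counts=arrays["fm.counts"],
        occ_cp=arrays["fm.occ_cp"],
        occ_rate=fmmeta["occ_rate"],
        sa_marked=arrays["fm.sa_marked"].astype(bool),
        sa_mark_rank=arrays["fm.sa_mark_rank"],
        sa_values=arrays["fm.sa_values"],
        sa_rate=fmmeta["sa_rate"],
        text_length=fmmeta["text_length"],
        sigma=fmmeta["sigma"],
    )
    offsets = arrays["subj.offsets"]
    seqs = [
        arrays["subj.data"][offsets[i] : offsets[i + 1]]
        for i in range(len(offsets) - 1)
    ]
    store = SubjectStore(
        ids=manifest["subject_ids"],
        descriptions=manifest["subject_descriptions"],
        sequences=seqs,
        alphabet=manifest["subject_alphabet"],
    )
    tags = [
        FrameTag(int(s), int(o), _CONV_NAME[int(c)])
        for s, o, c in zip(
            arrays["concat.strand"], arrays["concat.offset"], arrays["concat.conv"]
        )
    ]
    concat = ConcatMap(
        starts=arrays["concat.starts"],
        lengths=arrays["concat.lengths"],
        subject_idx=arrays["concat.subject_idx"],
        tags=tags,
    )
    tax = None
    if manifest["taxonomy"] is not None:
        t = manifest["taxonomy"]
        tax = TaxTree(
            parent={int(k): int(v) for k, v in t["parent"]},
            rank={int(k): v for k, v in t["rank"]},
            name={int(k): v for k, v in t["name"]},
        )
    return IndexArchive(
        domain=manifest["domain"],
        reduction_name=manifest["reduction"],
        fm=fm,
        subjects=store,
        concat=concat,
        rng_seed=manifest["rng_seed"],
        seeding_defaults=manifest["seeding_defaults"],
        taxonomy=tax,
        subject_taxids=arrays.get("tax.subject_taxids"),
        format_version=version,
    )
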