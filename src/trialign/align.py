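"""Gapped affine local alignment of unreduced sequences over seed windows.

The aligner runs exact Smith-Waterman (no X-drop) of the full unreduced
query frame against a subject window around each surviving seed.  In the
bisulfite domain the scoring matrix is asymmetric: hits on the C=T-reduced
subject copy score subject-C/query-T pairs as matches (bisulfite conversion
is not an error) while the reverse T/C pair stays a mismatch; G=A hits are
mirrored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from . import stats as _stats
from ._kernels import OP_MATCH, OP_MISMATCH, sw_affine
from .alphabets import AA27, DNA5, FrameTag

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "LocalAlignment",
    "get_scheme",
    "scheme_for_domain",
    "local_align",
    "extend_hits",
    "filter_and_rank",
]

#: margin added around the seed region when carving the subject window
WINDOW_MARGIN = 16

_OP_CHARS = "=XID"


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix (indexed [subject rank, query rank]) plus affine
    gap costs: a run of g gaps costs ``gap_open_extra + g * gap_extend``."""

    name: str
    matrix: np.ndarray
    gap_extend: int
    gap_open_extra: int

    def substitution(self, subject_rank: int, query_rank: int) -> int:
        return int(self.matrix[subject_rank, query_rank])


def _blosum62_aa27() -> np.ndarray:
    """BLOSUM62 lifted onto the aa27 alphabet.

    Rare letters use their standard resolutions (J->L, U->C, O->K); the stop
    symbol scores a strong negative constant against everything so
    alignments never match through stops.
    """
    b62 = substitution_matrices.load("BLOSUM62")
    resolve = {"J": "L", "U": "C", "O": "K"}
    mat = np.zeros((AA27.size, AA27.size), dtype=np.int16)
    for i, a in enumerate(AA27.symbols):
        for j, b in enumerate(AA27.symbols):
            aa = resolve.get(a, a)
            bb = resolve.get(b, b)
            if a == "*" or b == "*":
                mat[i, j] = -16
            else:
                mat[i, j] = int(b62[aa][bb])
    return mat


def _nt_matrix(match: int = 2, mismatch: int = -3) -> np.ndarray:
    mat = np.full((DNA5.size, DNA5.size), mismatch, dtype=np.int16)
    for i in range(4):
        mat[i, i] = match
    mat[4, :] = mismatch  # N never matches
    mat[:, 4] = mismatch
    return mat


_SCHEMES: dict[str, ScoringScheme] = {}


def get_scheme(name: str) -> ScoringScheme:
    """Presets: blosum62 (gaps -1/-11), nt {2,-3,-2,-5}, bs_ct, bs_ga."""
    if not _SCHEMES:
        _SCHEMES["blosum62"] = ScoringScheme("blosum62", _blosum62_aa27(), -1, -11)
        _SCHEMES["nt"] = ScoringScheme("nt", _nt_matrix(), -2, -5)
        ct = _nt_matrix()
        ct[DNA5.symbols.index("C"), DNA5.symbols.index("T")] = 2
        _SCHEMES["bs_ct"] = ScoringScheme("bs_ct", ct, -2, -5)
        ga = _nt_matrix()
        ga[DNA5.symbols.index("G"), DNA5.symbols.index("A")] = 2
        _SCHEMES["bs_ga"] = ScoringScheme("bs_ga", ga, -2, -5)
    try:
        return _SCHEMES[name]
    except KeyError:
        raise KeyError(f"unknown scoring preset {name!r}") from None


def scheme_for_domain(domain: str, conversion: str | None = None) -> ScoringScheme:
    if domain == "protein":
        return get_scheme("blosum62")
    if domain == "nucleotide":
        return get_scheme("nt")
    if domain == "bisulfite":
        if conversion not in ("ct", "ga"):
            raise ValueError("bisulfite scoring needs a ct/ga conversion tag")
        return get_scheme(f"bs_{conversion}")
    raise ValueError(f"unknown domain {domain!r}")


@dataclass(frozen=True)
class LocalAlignment:
    """Bare Smith-Waterman result in local (frame-window) coordinates."""

    score: int
    q_begin: int
    q_end: int
    s_begin: int
    s_end: int
    transcript: str

    @property
    def columns(self) -> int:
        return len(self.transcript)


def local_align(query: np.ndarray, subject: np.ndarray, scheme: ScoringScheme) -> LocalAlignment:
    """Optimal affine-gap local alignment of ``query`` against ``subject``
    (full matrix, deterministic tie-breaking)."""
    q = np.ascontiguousarray(query, dtype=np.uint8)
    s = np.ascontiguousarray(subject, dtype=np.uint8)
    if q.size == 0 or s.size == 0:
        raise ValueError("local_align requires non-empty sequences")
    score, qb, qe, sb, se, ops, n_ops = sw_affine(
        q, s, scheme.matrix, scheme.gap_extend, scheme.gap_open_extra
    )
    transcript = "".join(_OP_CHARS[o] for o in ops[:n_ops])
    return LocalAlignment(int(score), int(qb), int(qe), int(sb), int(se), transcript)


@dataclass(frozen=True)
class AlignmentResult:
    """A scored, thresholded hit with frame bookkeeping and output coordinates.

    ``q_begin``/``q_end`` and ``s_begin``/``s_end`` are 0-based half-open in
    unreduced *frame* coordinates; ``qstart``..``send`` are the 1-based
    inclusive output coordinates on the *original* sequences, with reverse
    frames having start > end.
    """

    query_id: str
    query_ordinal: int
    query_length: int
    qframe: FrameTag
    subject_idx: int
    subject_id: str
    sframe: FrameTag
    q_begin: int
    q_end: int
    s_begin: int
    s_end: int
    raw_score: int
    bitscore: float
    evalue: float
    n_ident: int
    mismatches: int
    gap_opens: int
    transcript: str
    qstart: int
    qend: int
    sstart: int
    send: int

    @property
    def length(self) -> int:
        return len(self.transcript)

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.n_ident / self.length


def frame_to_original(begin: int, end: int, tag: FrameTag, original_length: int, translated: bool) -> tuple[int, int]:
    """Convert a half-open frame range to 1-based inclusive coordinates on
    the original sequence (start > end on reverse frames)."""
    if translated:
        o = tag.offset
        if tag.strand > 0:
            return 3 * begin + o + 1, 3 * end + o
        return original_length - (o + 3 * begin), original_length - o - 3 * end + 1
    if tag.strand > 0:
        return begin + 1, end
    return original_length - begin, original_length - end + 1


def _transcript_counts(transcript: str) -> tuple[int, int, int]:
    n_ident = transcript.count(_OP_CHARS[OP_MATCH])
    mism = transcript.count(_OP_CHARS[OP_MISMATCH])
    gap_opens = 0
    prev_gap = False
    for ch in transcript:
        is_gap = ch in "ID"
        if is_gap and not prev_gap:
            gap_opens += 1
        prev_gap = is_gap
    return n_ident, mism, gap_opens


def extend_hits(hits, archive, query, schemes=None, db_size=None):
    """Extend verified seed hits into full gapped local alignments.

    ``query`` is a pipeline query context providing the unreduced query
    frames; the subject window is the seed region expanded by
    ``query_frame_length + WINDOW_MARGIN`` on both sides, clipped to the
    subject frame.  Bisulfite hits are scored with the asymmetric preset
    matching their subject copy's reduction tag.  Results are deduplicated
    on identical (subject, query range, subject range) and are independent
    of input hit order.
    """
    domain = archive.domain
    if db_size is None:
        db_size = archive.db_size
    results: dict[tuple, AlignmentResult] = {}
    for hit in hits:
        qframe = query.frames[hit.qframe_index]
        q_unred = qframe.unreduced
        s_unred = archive.subject_frame_unreduced(hit.subject_idx, hit.sframe)
        margin = len(q_unred) + WINDOW_MARGIN
        w_begin = max(0, hit.subject_offset - margin)
        w_end = min(len(s_unred), hit.subject_offset + hit.matched_length + margin)
        if schemes is not None:
            scheme = schemes[hit.sframe.conversion] if isinstance(schemes, dict) else schemes
        else:
            scheme = scheme_for_domain(domain, hit.sframe.conversion)
        aln = local_align(q_unred, s_unred[w_begin:w_end], scheme)
        if aln.score <= 0:
            continue
        s_begin = aln.s_begin + w_begin
        s_end = aln.s_end + w_begin
        key = (hit.subject_idx, hit.sframe, qframe.tag, aln.q_begin, aln.q_end, s_begin, s_end)
        if key in results:
            continue
        kp = _stats.get_karlin_params(scheme.name)
        bits = _stats.bitscore_from_raw(aln.score, kp)
        ev = _stats.evalue_from_bitscore(query.length, db_size, bits)
        n_ident, mism, gap_opens = _transcript_counts(aln.transcript)
        qstart, qend = frame_to_original(
            aln.q_begin, aln.q_end, qframe.tag, query.length, query.translated
        )
        subj_len = archive.subjects.lengths[hit.subject_idx]
        sstart, send = frame_to_original(
            s_begin, s_end, hit.sframe, subj_len, archive.subjects_translated
        )
        results[key] = AlignmentResult(
            query_id=query.id,
            query_ordinal=query.ordinal,
            query_length=query.length,
            qframe=qframe.tag,
            subject_idx=hit.subject_idx,
            subject_id=archive.subjects.ids[hit.subject_idx],
            sframe=hit.sframe,
            q_begin=aln.q_begin,
            q_end=aln.q_end,
            s_begin=s_begin,
            s_end=s_end,
            raw_score=aln.score,
            bitscore=bits,
            evalue=ev,
            n_ident=n_ident,
            mismatches=mism,
            gap_opens=gap_opens,
            transcript=aln.transcript,
            qstart=qstart,
            qend=qend,
            sstart=sstart,
            send=send,
        )
    return sorted(
        results.values(),
        key=lambda r: (-r.bitscore, r.subject_id, r.sstart, r.qstart),
    )


def filter_and_rank(results, thresholds: _stats.ThresholdSpec, max_hits: int = 25):
    """Apply the active thresholds, sort by bit-score (ties: subject id,
    then subject start) and truncate to ``max_hits``."""
    kept = []
    for r in results:
        if thresholds.max_evalue is not None and r.evalue > thresholds.max_evalue:
            continue
        if thresholds.min_bitscore is not None and r.bitscore < thresholds.min_bitscore:
            continue
        if (
            thresholds.min_pct_identity is not None
            and r.pct_identity < thresholds.min_pct_identity
        ):
            continue
        kept.append(r)
    kept.sort(key=lambda r: (-r.bitscore, r.subject_id, r.sstart, r.qstart))
    return kept[:max_hits]
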