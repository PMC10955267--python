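"""Sequence input (FASTA/FASTQ, plain or gzip) and result writers
(BLAST tabular, BLAST pairwise, SAM)."""

from __future__ import annotations

import gzip
from dataclasses import dataclass

from . import __version__
from .alphabets import DNA5, decode, reverse_complement

__all__ = [
    "QueryRecord",
    "FormatError",
    "UnsupportedDomainError",
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "write_blast_tab",
    "write_pairwise",
    "write_sam",
]

BLAST_TAB_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


class FormatError(ValueError):
    pass


class UnsupportedDomainError(ValueError):
    pass


@dataclass(frozen=True)
class QueryRecord:
    """One input sequence; ``ordinal`` preserves input order."""

    id: str
    description: str
    sequence: str
    qualities: str | None
    ordinal: int

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("empty sequence identifier")


def _open_text(path):
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return gzip.open(fh, "rt")
    import io

    return io.TextIOWrapper(fh)


def read_sequences(path):
    """Iterate :class:`QueryRecord` from a FASTA or FASTQ file (plain or
    gzip; auto-detected).  Sequences are upper-cased; the id is the header
    up to the first whitespace.  Truncated FASTQ records raise a
    :class:`FormatError` naming the record number."""
    with _open_text(path) as fh:
        first = fh.read(1)
        if first == ">":
            yield from _read_fasta(fh)
        elif first == "@":
            yield from _read_fastq(fh)
        elif first == "":
            return
        else:
            raise FormatError(f"{path}: unrecognized sequence format")


def _read_fasta(fh):
    ordinal = 0
    header = fh.readline().rstrip("\n")
    while True:
        seq_lines = []
        line = fh.readline()
        while line and not line.startswith(">"):
            seq_lines.append(line.strip())
            line = fh.readline()
        parts = header.split(None, 1)
        if not parts:
            raise FormatError(f"record {ordinal + 1}: empty FASTA header")
        yield QueryRecord(
            id=parts[0],
            description=parts[1] if len(parts) > 1 else "",
            sequence="".join(seq_lines).upper(),
            qualities=None,
            ordinal=ordinal,
        )
        ordinal += 1
        if not line:
            return
        header = line[1:].rstrip("\n")


def _read_fastq(fh):
    ordinal = 0
    header = fh.readline().rstrip("\n")  # first '@' already consumed
    while True:
        seq = fh.readline()
        plus = fh.readline()
        qual = fh.readline()
        if not seq or not plus or not qual.rstrip("\n"):
            raise FormatError(f"truncated FASTQ record {ordinal + 1}")
        if not plus.startswith("+"):
            raise FormatError(f"malformed FASTQ record {ordinal + 1}: missing '+' line")
        seq = seq.strip().upper()
        qual = qual.rstrip("\n")
        if len(qual) != len(seq):
            raise FormatError(
                f"FASTQ record {ordinal + 1}: quality length differs from sequence"
            )
        parts = header.split(None, 1)
        yield QueryRecord(
            id=parts[0] if parts else "",
            description=parts[1] if len(parts) > 1 else "",
            sequence=seq,
            qualities=qual,
            ordinal=ordinal,
        )
        ordinal += 1
        nxt = fh.readline()
        if not nxt:
            return
        if not nxt.startswith("@"):
            raise FormatError(f"malformed FASTQ record {ordinal + 1}")
        header = nxt[1:].rstrip("\n")


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Writers


def _tab_row(r, extra) -> str:
    cols = [
        r.query_id,
        r.subject_id,
        f"{r.pct_identity:.3f}",
        str(r.length),
        str(r.mismatches),
        str(r.gap_opens),
        str(r.qstart),
        str(r.qend),
        str(r.sstart),
        str(r.send),
        f"{r.evalue:.2e}",
        f"{r.bitscore:.1f}",
    ]
    cols.extend(str(x) for x in extra)
    return "\t".join(cols)


def write_blast_tab(query_results, out, extra_columns=()) -> None:
    """Standard 12-column BLAST tabular output, one row per hit, queries in
    input order.  ``extra_columns`` may contain "staxid", "lca", "lca_name";
    these require taxonomy-annotated results."""
    close = False
    if isinstance(out, (str, bytes)):
        out = open(out, "w")
        close = True
    try:
        for qr in query_results:
            for r in qr.results:
                extra = []
                for col in extra_columns:
                    if col == "staxid":
                        extra.append(qr.subject_taxid(r))
                    elif col == "lca":
                        extra.append(qr.lca_taxid)
                    elif col == "lca_name":
                        extra.append(qr.lca_name)
                    else:
                        raise ValueError(f"unknown extra column {col!r}")
                out.write(_tab_row(r, extra) + "\n")
    finally:
        if close:
            out.close()


def write_pairwise(query_results, out) -> None:
    """Human-readable one-block-per-hit format with coordinates and the
    alignment transcript."""
    close = False
    if isinstance(out, (str, bytes)):
        out = open(out, "w")
        close = True
    try:
        for qr in query_results:
            for r in qr.results:
                out.write(
                    f"Query: {r.query_id}  Subject: {r.subject_id}\n"
                    f" Score: {r.raw_score} raw, {r.bitscore:.1f} bits, "
                    f"E-value: {r.evalue:.2e}\n"
                    f" Identity: {r.n_ident}/{r.length} ({r.pct_identity:.1f}%), "
                    f"gap opens: {r.gap_opens}\n"
                    f" Query range: {r.qstart}..{r.qend}  "
                    f"Subject range: {r.sstart}..{r.send}\n"
                    f" Transcript: {r.transcript}\n\n"
                )
    finally:
        if close:
            out.close()


def _cigar(r, frame_len: int) -> str:
    parts = []
    lead = r.q_begin
    if lead:
        parts.append(f"{lead}S")
    run_ch = ""
    run = 0
    for ch in r.transcript:
        op = "M" if ch in "=X" else ch
        if op == run_ch:
            run += 1
        else:
            if run:
                parts.append(f"{run}{run_ch}")
            run_ch = op
            run = 1
    if run:
        parts.append(f"{run}{run_ch}")
    tail = frame_len - r.q_end
    if tail:
        parts.append(f"{tail}S")
    return "".join(parts)


def write_sam(query_results, archive, out, unmapped: bool = False) -> None:
    """SAM output for the nucleotide and bisulfite domains.

    Reverse-frame hits carry FLAG 16 and the reverse-complemented read
    sequence; unaligned query ends are soft-clipped.  Tags: AS (raw score),
    NM (mismatches + gap characters), ZE (e-value), ZB (bit-score) and, in
    the bisulfite domain, ZR (CT/GA subject copy)."""
    if archive.domain == "protein":
        raise UnsupportedDomainError("SAM output is not defined for the protein domain")
    close = False
    if isinstance(out, (str, bytes)):
        out = open(out, "w")
        close = True
    try:
        out.write("@HD\tVN:1.6\tSO:unknown\n")
        for sid, slen in zip(archive.subjects.ids, archive.subjects.lengths):
            out.write(f"@SQ\tSN:{sid}\tLN:{int(slen)}\n")
        out.write(f"@PG\tID:trialign\tPN:trialign\tVN:{__version__}\n")
        for qr in query_results:
            if not qr.results:
                if unmapped:
                    seq = qr.record.sequence or "*"
                    qual = qr.record.qualities or "*"
                    out.write(
                        f"{qr.record.id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\n"
                    )
                continue
            for r in qr.results:
                rev = r.qframe.strand < 0
                flag = 16 if rev else 0
                ranks = DNA5.encode(qr.record.sequence)
                if rev:
                    ranks = reverse_complement(ranks)
                seq = decode(ranks, DNA5)
                qual = qr.record.qualities or "*"
                if rev and qual != "*":
                    qual = qual[::-1]
                gaps = r.transcript.count("I") + r.transcript.count("D")
                tags = [
                    f"AS:i:{r.raw_score}",
                    f"NM:i:{r.mismatches + gaps}",
                    f"ZE:f:{r.evalue:.3g}",
                    f"ZB:f:{r.bitscore:.1f}",
                ]
                if archive.domain == "bisulfite":
                    tags.append(f"ZR:Z:{(r.sframe.conversion or '').upper()}")
                out.write(
                    "\t".join(
                        [
                            r.query_id,
                            str(flag),
                            r.subject_id,
                            str(r.sstart),
                            "255",
                            _cigar(r, len(seq)),
                            "*",
                            "0",
                            "0",
                            seq,
                            qual,
                        ]
                        + tags
                    )
                    + "\n"
                )
    finally:
        if close:
            out.close()
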