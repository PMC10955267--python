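"""Search orchestration: query framing, seeding, verification, alignment,
significance filtering and optional LCA annotation.

Queries are processed in input-order chunks; any number of worker threads
produces byte-identical output because per-query randomness (N replacement)
is keyed on the global seed plus the query ordinal, and results are merged
in input order.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from . import align as _align
from . import alphabets as ab
from . import seeding as _seeding
from . import stats as _stats
from . import taxonomy as _taxonomy
from .indexer import IndexArchive
from .io_formats import QueryRecord

__all__ = ["SearchConfig", "QueryResult", "Searcher", "DomainMismatchError"]

_CHUNK = 32


class DomainMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class SearchConfig:
    """Concrete run configuration (profiles already expanded)."""

    max_evalue: float | None = 0.01
    min_bitscore: float | None = None
    min_pct_identity: float | None = None
    num_matches: int = 25
    profile: str = "default"
    seed_length: int | None = None
    seed_offset: int | None = None
    seed_delta: int | None = None
    adaptive_max_occ: int | None = None
    threads: int = 1
    rng_seed: int = 0


@dataclass
class QueryContext:
    """Per-query state handed to the alignment stage."""

    id: str
    ordinal: int
    length: int
    translated: bool  # frames are six-frame translations of a nucleotide query
    frames: list


@dataclass
class QueryResult:
    record: QueryRecord
    results: list
    pass_indicator: int = 1
    lca_taxid: int | None = None
    lca_name: str | None = None
    _subject_taxids: dict = field(default_factory=dict)

    def subject_taxid(self, result) -> int:
        return self._subject_taxids.get(result.subject_idx, _taxonomy.UNASSIGNED)


class Searcher:
    """Reusable search session over one loaded index archive."""

    def __init__(self, archive: IndexArchive, config: SearchConfig | None = None):
        self.archive = archive
        self.config = config or SearchConfig()
        params = _seeding.profile_params(archive.domain, self.config.profile)
        overrides = {}
        for name in ("seed_length", "seed_offset", "seed_delta", "adaptive_max_occ"):
            v = getattr(self.config, name)
            if v is not None:
                overrides[name] = v
        if overrides:
            from dataclasses import replace

            params = replace(params, **overrides)
            if params.second_pass is not None:
                params = replace(params, second_pass=_seeding.default_params(archive.domain))
        self.params = params
        if archive.domain == "protein":
            self._reduction = ab.get_reduction(archive.reduction_name)
            self._karlin = _stats.get_karlin_params("blosum62")
        else:
            self._reduction = None
            self._karlin = _stats.get_karlin_params("nt")

    # -- per-query steps -----------------------------------------------------

    def _frames(self, record: QueryRecord):
        domain = self.archive.domain
        rng = np.random.default_rng([self.config.rng_seed, record.ordinal])
        if domain == "protein":
            kind = _detect_record(record.sequence)
            nucleotide_query = kind == "nucleotide"
            seq = ab.encode(record.sequence, ab.DNA5 if nucleotide_query else ab.AA27)
            frames = ab.query_frames(
                seq, domain, reduction=self._reduction, nucleotide_query=nucleotide_query
            )
            return frames, nucleotide_query
        seq = ab.encode(record.sequence, ab.DNA5)
        return ab.query_frames(seq, domain, rng=rng), False

    def _report_bitscore(self, m: int) -> float:
        if self.config.min_bitscore is not None:
            return self.config.min_bitscore
        if self.config.max_evalue is not None:
            return _stats.bitscore_threshold_from_evalue(
                m, self.archive.db_size, self.config.max_evalue
            )
        return 0.0

    def search_record(self, record: QueryRecord) -> QueryResult:
        archive = self.archive
        frames, translated = self._frames(record)
        qctx = QueryContext(
            id=record.id,
            ordinal=record.ordinal,
            length=len(record.sequence),
            translated=translated,
            frames=frames,
        )
        if len(record.sequence) == 0:
            return QueryResult(record, [])
        prefilter = (
            self.params.prefilter_min_score
            if self.params.prefilter_min_score is not None
            else _seeding.prefilter_threshold(
                self._report_bitscore(qctx.length), self._karlin
            )
        )

        def verify(hit) -> bool:
            q_unred = frames[hit.qframe_index].unreduced
            s_unred = archive.subject_frame_unreduced(hit.subject_idx, hit.sframe)
            scheme = _align.scheme_for_domain(archive.domain, hit.sframe.conversion)
            return (
                _seeding.gapless_verify(hit, q_unred, s_unred, scheme) >= prefilter
            )

        hits, indicator = _seeding.iterative_search(
            archive.fm, archive.concat, frames, self.params, verify, record.ordinal
        )
        results = _align.extend_hits(hits, archive, qctx)
        thresholds = _stats.ThresholdSpec(
            max_evalue=self.config.max_evalue,
            min_bitscore=self.config.min_bitscore,
            min_pct_identity=self.config.min_pct_identity,
            query_length=max(1, qctx.length),
            db_size=archive.db_size,
        )
        ranked = _align.filter_and_rank(results, thresholds, self.config.num_matches)
        qr = QueryResult(record, ranked, pass_indicator=indicator)
        if archive.taxonomy is not None and archive.subject_taxids is not None:
            taxids = {
                r.subject_idx: int(archive.subject_taxids[r.subject_idx]) for r in ranked
            }
            qr._subject_taxids = taxids
            if ranked:
                qr.lca_taxid = _taxonomy.lca(archive.taxonomy, taxids.values())
                qr.lca_name = archive.taxonomy.name.get(qr.lca_taxid, "")
        return qr

    # -- batch execution ------------------------------------------------------

    def run(self, records) -> list[QueryResult]:
        """Search all records; output order equals input order regardless of
        the worker count."""
        records = list(records)
        if self.config.threads <= 1 or len(records) <= _CHUNK:
            return [self.search_record(r) for r in records]
        chunks = [records[i : i + _CHUNK] for i in range(0, len(records), _CHUNK)]
        with ThreadPoolExecutor(max_workers=self.config.threads) as pool:
            parts = pool.map(lambda c: [self.search_record(r) for r in c], chunks)
            return [qr for part in parts for qr in part]


def _detect_record(sequence: str) -> str:
    s = sequence[:10_000].upper()
    if not s:
        return "nucleotide"
    nt = sum(s.count(c) for c in "ACGTNU")
    return "nucleotide" if nt / len(s) >= 0.95 else "protein"


def expect_domain(archive: IndexArchive, expected: str) -> None:
    if archive.domain != expected:
        raise DomainMismatchError(
            f"index was built for the {archive.domain} domain but the search "
            f"command expects {expected}"
        )
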