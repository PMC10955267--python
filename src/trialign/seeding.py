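"""Seed generation, FM-search orchestration (half-exact, adaptive,
iterative heuristics) and gapless unreduced-space verification.

Seeds are fixed-length windows of the reduced query frames, placed every
``seed_offset`` positions (plus one clamped terminal window).  Each window
is searched in the FM-index allowing ``seed_delta`` mismatches in the second
half of the seed, elongated adaptively while it occurs more than
``adaptive_max_occ`` times, and located.  Because alphabet reduction admits
false positives, every candidate is re-scored in the unreduced space with a
fast gapless X-drop extension before alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._kernels import gapless_extend
from .alphabets import FrameTag, QueryFrame

__all__ = [
    "SeedingParams",
    "SeedHit",
    "default_params",
    "profile_params",
    "generate_seed_windows",
    "search_seeds",
    "gapless_verify",
    "iterative_search",
]

#: X-drop bound (raw-score units) of the gapless prefilter
GAPLESS_XDROP = 16
#: raw-score floor of the gapless prefilter
PREFILTER_FLOOR = 16


@dataclass(frozen=True)
class SeedingParams:
    seed_length: int
    seed_offset: int
    seed_delta: int
    half_exact: bool = True
    adaptive_max_occ: int = 64
    iterative: bool = False
    second_pass: "SeedingParams | None" = None
    prefilter_min_score: int | None = None

    def __post_init__(self) -> None:
        if self.seed_length < 4:
            raise ValueError("seed_length must be >= 4")
        if self.seed_offset < 1:
            raise ValueError("seed_offset must be >= 1")
        if self.seed_delta not in (0, 1):
            raise ValueError("seed_delta must be 0 or 1")
        if self.adaptive_max_occ < 1:
            raise ValueError("adaptive_max_occ must be >= 1")
        if self.iterative != (self.second_pass is not None):
            raise ValueError("second_pass must be present iff iterative")


_DOMAIN_DEFAULTS = {
    "protein": dict(seed_length=10, seed_offset=5, seed_delta=1),
    "nucleotide": dict(seed_length=14, seed_offset=7, seed_delta=1),
    "bisulfite": dict(seed_length=16, seed_offset=8, seed_delta=1),
}


def default_params(domain: str) -> SeedingParams:
    return SeedingParams(**_DOMAIN_DEFAULTS[domain])


def profile_params(domain: str, profile: str = "default") -> SeedingParams:
    """Expand a profile name into concrete parameters.

    fast: doubled offset, no seed mismatch, iterative fallback to the
    default parameters; sensitive: offset = ceil(L/3), mismatch on.
    """
    base = default_params(domain)
    if profile == "default":
        return base
    if profile == "fast":
        return replace(
            base,
            seed_offset=base.seed_offset * 2,
            seed_delta=0,
            iterative=True,
            second_pass=base,
        )
    if profile == "sensitive":
        return replace(base, seed_offset=math.ceil(base.seed_length / 3), seed_delta=1)
    raise ValueError(f"unknown profile {profile!r}")


@dataclass(frozen=True)
class SeedHit:
    """A located, deduplicated seed occurrence (pre-verification)."""

    query_ordinal: int
    qframe_index: int
    qframe_tag: FrameTag
    window_begin: int  # reduced-frame coords, after adaptive elongation
    window_end: int
    subject_idx: int
    sframe: FrameTag
    subject_offset: int  # local offset within the subject frame
    matched_length: int
    occurrences: int

    @property
    def diagonal(self) -> int:
        return self.subject_offset - self.window_begin


def generate_seed_windows(frame_length: int, params: SeedingParams) -> list[tuple[int, int]]:
    """Half-open seed windows: begins at multiples of the offset, plus a
    final window clamped to the frame end; frames shorter than the seed
    yield none."""
    L = params.seed_length
    if frame_length < L:
        return []
    windows = []
    b = 0
    while b + L <= frame_length:
        windows.append((b, b + L))
        b += params.seed_offset
    if b < frame_length and (not windows or windows[-1][0] != frame_length - L):
        windows.append((frame_length - L, frame_length))
    return windows


def search_seeds(
    fm,
    concat,
    frames: list[QueryFrame],
    params: SeedingParams,
    query_ordinal: int = 0,
) -> list[SeedHit]:
    """Search every seed window of every query frame in the index.

    Hits are deduplicated per (query frame, subject frame, diagonal),
    keeping the longest match (ties: smallest subject offset).
    """
    best: dict[tuple, SeedHit] = {}
    for fi, frame in enumerate(frames):
        red = frame.reduced.astype(np.uint8) + 1  # shift past separator rank
        for wb, we in generate_seed_windows(len(red), params):
            seed = red[wb:we]
            found = (
                fm.search_half_exact(seed, params.seed_delta)
                if params.half_exact
                else fm.search_half_exact(seed, params.seed_delta, restrict=False)
            )
            for iv, _mm in found:
                iv2, nb = fm.adaptive_elongate(iv, red, wb, params.adaptive_max_occ)
                matched = we - nb
                for pos in fm.locate(iv2):
                    sidx, stag, local = concat.resolve(int(pos))
                    key = (fi, sidx, stag, local - nb)
                    hit = SeedHit(
                        query_ordinal=query_ordinal,
                        qframe_index=fi,
                        qframe_tag=frame.tag,
                        window_begin=nb,
                        window_end=we,
                        subject_idx=sidx,
                        sframe=stag,
                        subject_offset=local,
                        matched_length=matched,
                        occurrences=iv2.count,
                    )
                    old = best.get(key)
                    if (
                        old is None
                        or hit.matched_length > old.matched_length
                        or (
                            hit.matched_length == old.matched_length
                            and hit.subject_offset < old.subject_offset
                        )
                    ):
                        best[key] = hit
    return sorted(
        best.values(),
        key=lambda h: (h.qframe_index, h.subject_idx, h.sframe, h.diagonal),
    )


def gapless_verify(
    hit: SeedHit,
    query_frame: np.ndarray,
    subject_frame: np.ndarray,
    scheme,
    xdrop: int = GAPLESS_XDROP,
) -> int:
    """Best ungapped raw score of an extension through the seed region, in
    the unreduced space (X-drop bounded)."""
    return int(
        gapless_extend(
            np.ascontiguousarray(query_frame, dtype=np.uint8),
            np.ascontiguousarray(subject_frame, dtype=np.uint8),
            hit.window_begin,
            hit.window_end,
            hit.subject_offset,
            hit.subject_offset + hit.matched_length,
            scheme.matrix,
            xdrop,
        )
    )


def prefilter_threshold(report_bitscore: float, karlin_params) -> int:
    """Raw-score prefilter: 0.4 x the raw equivalent of the report
    threshold, floored at PREFILTER_FLOOR."""
    from .stats import raw_from_bitscore

    raw = raw_from_bitscore(report_bitscore, karlin_params)
    return max(PREFILTER_FLOOR, math.ceil(0.4 * raw))


def iterative_search(
    fm, concat, frames, params: SeedingParams, verify, query_ordinal: int = 0
) -> tuple[list[SeedHit], int]:
    """Run the (cheap) first pass; fall back to the second-pass parameters
    only when no hit survives gapless verification.  Returns the surviving
    hits and the pass indicator (1 or 2)."""
    first = replace(params, iterative=False, second_pass=None)
    hits = [h for h in search_seeds(fm, concat, frames, first, query_ordinal) if verify(h)]
    if hits or not params.iterative:
        return hits, 1
    hits = [
        h
        for h in search_seeds(fm, concat, frames, params.second_pass, query_ordinal)
        if verify(h)
    ]
    return hits, 2
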