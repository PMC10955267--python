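"""Succinct full-text index: BWT backward search, half-exact one-mismatch
seeding and adaptive seed elongation.

The index is built over a rank-encoded text in which rank 0 is reserved as
the per-sequence separator / terminal sentinel (lexicographically smallest);
content symbols occupy ranks ``1..sigma-1``.  Because search patterns never
contain rank 0, matches cannot straddle sequence boundaries.

The suffix array is computed with a numpy prefix-doubling sort
(O(n log^2 n)), which is fast enough for the megabase-scale collections this
engine targets and has no native-code dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import backward_step, occ_count

__all__ = [
    "FmIndex",
    "SaInterval",
    "FmBuildError",
    "suffix_array",
    "build_fmindex",
]


class FmBuildError(ValueError):
    pass


@dataclass(frozen=True)
class SaInterval:
    """Half-open interval [lo, hi) of suffix-array rows; ``depth`` is the
    number of pattern symbols consumed so far."""

    lo: int
    hi: int
    depth: int = 0

    @property
    def count(self) -> int:
        return self.hi - self.lo

    @property
    def empty(self) -> bool:
        return self.hi <= self.lo


def suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort)."""
    t = np.asarray(text, dtype=np.int64)
    n = t.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = t.copy()
    k = 1
    sa = np.argsort(rank, kind="stable")
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        sa = np.lexsort((second, rank))
        new_rank = np.empty(n, dtype=np.int64)
        changed = (rank[sa[1:]] != rank[sa[:-1]]) | (second[sa[1:]] != second[sa[:-1]])
        new_rank[sa] = np.concatenate(([0], np.cumsum(changed)))
        rank = new_rank
        if rank[sa[-1]] == n - 1:
            return sa
        k *= 2


@dataclass
class FmIndex:
    """BWT + checkpointed occurrence table + sampled suffix array.

    ``counts`` is the C array: counts[c] = number of text symbols < c,
    with counts[sigma] == text_length.
    """

    bwt: np.ndarray
    counts: np.ndarray
    occ_cp: np.ndarray  # (n_blocks+1, sigma) cumulative counts at block starts
    occ_rate: int
    sa_marked: np.ndarray  # bool per BWT row
    sa_mark_rank: np.ndarray  # exclusive prefix sums of sa_marked
    sa_values: np.ndarray  # text positions for marked rows
    sa_rate: int
    text_length: int
    sigma: int
    _full: SaInterval = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._full = SaInterval(0, self.text_length, 0)

    # -- core primitives ----------------------------------------------------

    def occ(self, symbol: int, i: int) -> int:
        """Occurrences of ``symbol`` in bwt[0:i]."""
        return int(occ_count(self.bwt, self.occ_cp, self.occ_rate, symbol, i))

    def full_interval(self) -> SaInterval:
        return self._full

    def extend_left(self, interval: SaInterval, symbol: int) -> SaInterval:
        """Backward-search step: occurrences of symbol + matched suffix."""
        if interval.empty:
            return SaInterval(interval.lo, interval.lo, interval.depth + 1)
        lo, hi = backward_step(
            self.bwt, self.occ_cp, self.occ_rate, self.counts, symbol,
            interval.lo, interval.hi,
        )
        return SaInterval(int(lo), int(hi), interval.depth + 1)

    def lf(self, row: int) -> int:
        c = int(self.bwt[row])
        return int(self.counts[c]) + self.occ(c, row)

    # -- searches -----------------------------------------------------------

    def search_exact(self, pattern: np.ndarray) -> SaInterval:
        """Interval of all occurrences of ``pattern`` (empty pattern: full)."""
        iv = self.full_interval()
        for c in pattern[::-1]:
            iv = self.extend_left(iv, int(c))
            if iv.empty:
                return iv
        return iv

    def search_half_exact(
        self, seed: np.ndarray, delta: int, restrict: bool = True
    ) -> list[tuple[SaInterval, int | None]]:
        """Search ``seed`` allowing up to ``delta`` mismatches, restricted to
        the second half of the seed (positions ceil(L/2)..L-1).

        Backward search consumes the second half first, so mismatch branching
        happens early and dead branches are pruned immediately.  Returned
        intervals are pairwise disjoint (each corresponds to a distinct
        pattern string); the second tuple element is the mismatch position or
        None for the exact branch.
        """
        seed = np.asarray(seed, dtype=np.uint8)
        L = len(seed)
        if L < 2:
            raise ValueError("seed length must be >= 2")
        if delta == 0:
            iv = self.search_exact(seed)
            return [] if iv.empty else [(iv, None)]
        half = (L + 1) // 2 if restrict else 0  # first allowed mismatch position
        out: list[tuple[SaInterval, int | None]] = []
        # stack entries: (interval, next position to consume, mismatch position)
        stack: list[tuple[SaInterval, int, int | None]] = [
            (self.full_interval(), L - 1, None)
        ]
        while stack:
            iv, pos, mm = stack.pop()
            if pos < 0:
                out.append((iv, mm))
                continue
            c = int(seed[pos])
            if mm is None and pos >= half:
                for alt in range(1, self.sigma):
                    if alt == c:
                        continue
                    nxt = self.extend_left(iv, alt)
                    if not nxt.empty:
                        stack.append((nxt, pos - 1, pos))
            nxt = self.extend_left(iv, c)
            if not nxt.empty:
                stack.append((nxt, pos - 1, mm))
        return out

    def adaptive_elongate(
        self,
        interval: SaInterval,
        query: np.ndarray,
        begin: int,
        max_occ: int,
    ) -> tuple[SaInterval, int]:
        """Elongate a completed seed leftwards through ``query`` while it
        occurs more than ``max_occ`` times.

        ``begin`` is the query position of the seed's first symbol; returns
        the final interval and the new begin.  Stops at count <= max_occ,
        query exhaustion, or — if an elongation empties the interval — the
        last non-empty interval.
        """
        iv = interval
        while iv.count > max_occ and begin > 0:
            nxt = self.extend_left(iv, int(query[begin - 1]))
            if nxt.empty:
                return iv, begin
            iv = nxt
            begin -= 1
        return iv, begin

    def locate(self, interval: SaInterval) -> np.ndarray:
        """Sorted text positions of the suffixes in ``interval``."""
        positions = np.empty(interval.count, dtype=np.int64)
        for k, row in enumerate(range(interval.lo, interval.hi)):
            steps = 0
            r = row
            while not self.sa_marked[r]:
                r = self.lf(r)
                steps += 1
            positions[k] = int(self.sa_values[self.sa_mark_rank[r]]) + steps
        positions.sort()
        return positions

    def inverse_bwt(self) -> np.ndarray:
        """Reconstruct a single-sequence text (round-trip diagnostic).

        Valid for texts with one terminal separator; multi-sequence
        concatenations would require LF steps across separators, which the
        index does not support (locate avoids them via block-start samples).
        """
        n = self.text_length
        out = np.empty(n, dtype=np.uint8)
        # row of suffix 0 is the marked row with sa value 0
        row = -1
        for r in np.flatnonzero(self.sa_marked):
            if self.sa_values[self.sa_mark_rank[r]] == 0:
                row = int(r)
                break
        for i in range(n - 1, -1, -1):
            out[i] = self.bwt[row]
            row = self.lf(row)
        return out


def build_fmindex(
    text: np.ndarray,
    sigma: int,
    occ_rate: int = 64,
    sa_rate: int = 16,
    mark_positions: np.ndarray | None = None,
) -> FmIndex:
    """Build the index over ``text`` (ranks < sigma, rank 0 = separator).

    The text must be non-empty and end with the separator.  With several
    separator occurrences the LF mapping is only exact for content symbols,
    so every locate walk must terminate before stepping onto a separator:
    callers concatenating multiple sequences pass their block-start offsets
    as ``mark_positions``, which are always added to the suffix-array sample
    (a walk then stops at the block start at the latest and never crosses a
    separator).  Position 0 is always sampled.
    """
    text = np.asarray(text, dtype=np.uint8)
    n = text.size
    if n == 0:
        raise FmBuildError("cannot build an FM-index over an empty text")
    if text[-1] != 0:
        raise FmBuildError("text must end with the separator rank 0")
    if text.max() >= sigma:
        raise FmBuildError("text contains ranks outside the alphabet")
    sa = suffix_array(text)
    bwt = text[(sa - 1) % n]
    counts = np.zeros(sigma + 1, dtype=np.int64)
    sym_counts = np.bincount(text, minlength=sigma)
    counts[1:] = np.cumsum(sym_counts)
    # occurrence checkpoints every occ_rate positions
    n_blocks = (n + occ_rate - 1) // occ_rate
    padded = np.zeros(n_blocks * occ_rate, dtype=np.int64)
    padded[:n] = bwt
    padded[n:] = sigma  # out-of-alphabet filler, never counted
    onehot = padded.reshape(n_blocks, occ_rate)[:, :, None] == np.arange(sigma)[None, None, :]
    per_block = onehot.sum(axis=1, dtype=np.int64)
    occ_cp = np.zeros((n_blocks + 1, sigma), dtype=np.int64)
    np.cumsum(per_block, axis=0, out=occ_cp[1:])
    # SA samples by text position (plus forced block-start samples)
    sampled_pos = (sa % sa_rate) == 0
    if mark_positions is not None and len(mark_positions):
        forced = np.zeros(n, dtype=bool)
        forced[np.asarray(mark_positions, dtype=np.int64)] = True
        sampled_pos |= forced[sa]
    sa_marked = sampled_pos
    sa_values = sa[sa_marked]
    sa_mark_rank = np.zeros(n, dtype=np.int64)
    sa_mark_rank[1:] = np.cumsum(sa_marked[:-1])
    return FmIndex(
        bwt=bwt,
        counts=counts,
        occ_cp=occ_cp,
        occ_rate=occ_rate,
        sa_marked=sa_marked,
        sa_mark_rank=sa_mark_rank,
        sa_values=sa_values,
        sa_rate=sa_rate,
        text_length=n,
        sigma=sigma,
    )
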