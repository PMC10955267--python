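"""FM-index correctness against naive-scan oracles."""

import numpy as np
import pytest

from trialign import fmindex as fmx
from trialign.fmindex import FmBuildError, build_fmindex

from conftest import naive_half_exact, naive_occurrences


def make_text(content: str, alphabet: str) -> np.ndarray:
    """Encode a toy string over a small alphabet with separator rank 0
    appended ('$' maps to the separator)."""
    ranks = {ch: i + 1 for i, ch in enumerate(sorted(set(alphabet)))}
    ranks["$"] = 0
    out = np.array([ranks[c] for c in content], dtype=np.uint8)
    if out[-1] != 0:
        out = np.concatenate([out, [0]]).astype(np.uint8)
    return out


class TestBuild:
    def test_empty_text_is_an_error(self):
        with pytest.raises(FmBuildError):
            build_fmindex(np.empty(0, dtype=np.uint8), 4)

    def test_missing_terminator_is_an_error(self):
        with pytest.raises(FmBuildError):
            build_fmindex(np.array([1, 2, 3], dtype=np.uint8), 4)

    def test_single_pattern_count(self):
        text = make_text("ACGT$", "ACGT")
        fm = build_fmindex(text, 5)
        pat = make_text("CG", "ACGT")[:-1]
        assert fm.search_exact(pat).count == 1

    def test_repeated_symbol(self):
        text = make_text("AAAA$", "ACGT")
        fm = build_fmindex(text, 5)
        assert fm.search_exact(make_text("AA", "ACGT")[:-1]).count == 3

    @pytest.mark.parametrize("trial", range(5))
    def test_inverse_bwt_roundtrip(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(5, 400))
        text = np.concatenate([rng.integers(1, 5, n), [0]]).astype(np.uint8)
        fm = build_fmindex(text, 5)
        assert (fm.inverse_bwt() == text).all()

    def test_counts_invariants(self):
        rng = np.random.default_rng(0)
        text = np.concatenate([rng.integers(1, 5, 200), [0]]).astype(np.uint8)
        fm = build_fmindex(text, 5)
        assert (np.diff(fm.counts) >= 0).all()
        assert fm.counts[-1] == fm.text_length
        # LF is a permutation
        lf = np.array([fm.lf(r) for r in range(fm.text_length)])
        assert sorted(lf.tolist()) == list(range(fm.text_length))


class TestSearchExact:
    def test_mississippi(self):
        text = make_text("mississippi$", "imps")
        fm = build_fmindex(text, 5)
        pat = make_text("ssi$", "imps")[:-2]
        iv = fm.search_exact(pat)
        assert iv.count == 2
        assert list(fm.locate(iv)) == [2, 5]

    def test_empty_pattern_full_interval(self):
        fm = build_fmindex(make_text("ACGT$", "ACGT"), 5)
        iv = fm.search_exact(np.empty(0, dtype=np.uint8))
        assert iv.count == fm.text_length

    def test_absent_pattern(self):
        fm = build_fmindex(make_text("AAAA$", "ACGT"), 5)
        assert fm.search_exact(make_text("CC$", "ACGT")[:-1]).count == 0

    def test_extend_left_first_step_counts_symbol(self):
        rng = np.random.default_rng(3)
        text = np.concatenate([rng.integers(1, 4, 300), [0]]).astype(np.uint8)
        fm = build_fmindex(text, 4)
        for sym in (1, 2, 3):
            iv = fm.extend_left(fm.full_interval(), sym)
            assert iv.count == int(np.count_nonzero(text == sym))

    def test_extending_empty_interval_stays_empty(self):
        fm = build_fmindex(make_text("ACGT$", "ACGT"), 5)
        empty = fmx.SaInterval(2, 2)
        assert fm.extend_left(empty, 1).empty


@pytest.mark.parametrize("sigma_content", [4, 3, 10], ids=["dna4", "bs3", "li10"])
def test_oracle_equivalence_search_locate(sigma_content):
    """search/locate equals naive scanning on random texts, for exact and
    half-exact (delta 1) patterns, across the reduced-alphabet sizes used by
    the three domains."""
    rng = np.random.default_rng(sigma_content)
    for _ in range(70):
        n = int(rng.integers(20, 2000))
        text = np.concatenate([rng.integers(1, sigma_content + 1, n), [0]]).astype(np.uint8)
        fm = build_fmindex(text, sigma_content + 1)
        for _ in range(3):
            m = int(rng.integers(1, 13))
            pat = rng.integers(1, sigma_content + 1, m).astype(np.uint8)
            iv = fm.search_exact(pat)
            expected = naive_occurrences(text[:-1], pat)
            assert iv.count == len(expected)
            assert fm.locate(iv).tolist() == expected
            if m >= 2:
                got = sorted(
                    p
                    for jv, _mm in fm.search_half_exact(pat, 1)
                    for p in fm.locate(jv)
                )
                assert got == naive_half_exact(text[:-1], pat, 1)


def test_half_exact_delta0_equals_exact():
    rng = np.random.default_rng(9)
    text = np.concatenate([rng.integers(1, 5, 500), [0]]).astype(np.uint8)
    fm = build_fmindex(text, 5)
    for _ in range(20):
        pat = rng.integers(1, 5, int(rng.integers(2, 10))).astype(np.uint8)
        exact = fm.search_exact(pat)
        res = fm.search_half_exact(pat, 0)
        total = sum(iv.count for iv, _ in res)
        assert total == exact.count


def test_half_exact_restricts_mismatch_to_second_half():
    # text contains AATA (mismatch at position 2: allowed) and TAAA
    # (mismatch at position 0: not allowed)
    text = make_text("CCAATACCTAAACC$", "ACT")
    fm = build_fmindex(text, 4)
    seed = make_text("AAAA$", "ACT")[:-1]
    found = sorted(
        p for iv, _mm in fm.search_half_exact(seed, 1) for p in fm.locate(iv)
    )
    assert 2 in found  # AATA
    assert 8 not in found  # TAAA


class TestAdaptiveElongation:
    def test_unique_seed_unchanged(self):
        fm = build_fmindex(make_text("ACGTACGA$", "ACGT"), 5)
        q = make_text("ACGA$", "ACGT")[:-1]
        iv = fm.search_exact(q[2:])
        iv2, nb = fm.adaptive_elongate(iv, q, 2, 4)
        assert (iv2.lo, iv2.hi) == (iv.lo, iv.hi) and nb == 2

    def test_elongates_repetitive_seed(self):
        content = "ACACACACACACACACACAC" + "ACGT"
        fm = build_fmindex(make_text(content + "$", "ACGT"), 5)
        q2 = make_text("ACACACAC$", "ACGT")[:-1]
        iv = fm.search_exact(q2[4:])
        assert iv.count > 2
        iv2, nb = fm.adaptive_elongate(iv, q2, 4, 2)
        # naive check of the elongation endpoint
        text = make_text(content + "$", "ACGT")[:-1]
        expect = naive_occurrences(text, q2[nb:])
        assert iv2.count == len(expect)
        assert iv2.count <= 2 or nb == 0

    def test_vacuous_bound_never_elongates(self):
        fm = build_fmindex(make_text("ACACACAC$", "ACGT"), 5)
        q = make_text("ACAC$", "ACGT")[:-1]
        iv = fm.search_exact(q)
        iv2, nb = fm.adaptive_elongate(iv, q, 0, fm.text_length)
        assert (iv2.lo, iv2.hi) == (iv.lo, iv.hi)


def test_locate_independent_of_sa_sampling_rate():
    rng = np.random.default_rng(21)
    text = np.concatenate([rng.integers(1, 5, 800), [0]]).astype(np.uint8)
    pat = rng.integers(1, 5, 4).astype(np.uint8)
    results = []
    for rate in (1, 4, 16):
        fm = build_fmindex(text, 5, sa_rate=rate)
        results.append(fm.locate(fm.search_exact(pat)).tolist())
    assert results[0] == results[1] == results[2]


def test_locate_exact_across_concatenated_sequence_blocks():
    """With many separator-delimited blocks, locate walks must not cross
    separators: block starts are force-sampled, and positions stay exact."""
    rng = np.random.default_rng(55)
    blocks, starts, pos = [], [], 0
    for _ in range(12):
        L = int(rng.integers(20, 200))
        starts.append(pos)
        blocks.append(rng.integers(1, 5, L).astype(np.uint8))
        blocks.append(np.zeros(1, dtype=np.uint8))
        pos += L + 1
    text = np.concatenate(blocks)
    fm = build_fmindex(text, 5, sa_rate=16, mark_positions=np.array(starts))
    for _ in range(100):
        m = int(rng.integers(2, 9))
        pat = rng.integers(1, 5, m).astype(np.uint8)
        expected = naive_occurrences(text[:-1], pat)
        assert fm.locate(fm.search_exact(pat)).tolist() == expected


def test_occurrence_count_monotone_in_pattern_length():
    rng = np.random.default_rng(33)
    text = np.concatenate([rng.integers(1, 5, 1500), [0]]).astype(np.uint8)
    fm = build_fmindex(text, 5)
    for _ in range(30):
        pat = rng.integers(1, 5, 10).astype(np.uint8)
        counts = [fm.search_exact(pat[-k:]).count for k in range(1, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
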