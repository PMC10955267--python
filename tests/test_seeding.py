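"""Seed windows, FM-search orchestration and gapless verification."""

import numpy as np
import pytest

from trialign import align as al
from trialign import alphabets as ab
from trialign import indexer as ix
from trialign import seeding as sd

from conftest import naive_half_exact


def P(**kw):
    base = dict(seed_length=10, seed_offset=5, seed_delta=1)
    base.update(kw)
    return sd.SeedingParams(**base)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            P(seed_length=3)
        with pytest.raises(ValueError):
            P(seed_offset=0)
        with pytest.raises(ValueError):
            P(seed_delta=2)
        with pytest.raises(ValueError):
            P(iterative=True)  # second_pass required iff iterative

    def test_profiles(self):
        d = sd.profile_params("nucleotide", "default")
        f = sd.profile_params("nucleotide", "fast")
        s = sd.profile_params("nucleotide", "sensitive")
        assert f.seed_offset == 2 * d.seed_offset and f.seed_delta == 0
        assert f.iterative and f.second_pass == d
        assert s.seed_offset <= d.seed_offset and s.second_pass is None


class TestSeedWindows:
    @pytest.mark.parametrize(
        "frame_len,L,off,expected",
        [
            (20, 10, 5, [(0, 10), (5, 15), (10, 20)]),
            (9, 10, 5, []),
            (12, 10, 5, [(0, 10), (2, 12)]),  # clamped terminal window
            (10, 10, 5, [(0, 10)]),
            (15, 10, 5, [(0, 10), (5, 15)]),
        ],
    )
    def test_examples(self, frame_len, L, off, expected):
        params = P(seed_length=L, seed_offset=off)
        assert sd.generate_seed_windows(frame_len, params) == expected

    def test_windows_cover_frame_at_offset_one(self):
        params = P(seed_length=10, seed_offset=1)
        wins = sd.generate_seed_windows(50, params)
        assert wins[0] == (0, 10) and wins[-1] == (40, 50)
        assert len(wins) == 41


@pytest.fixture(scope="module")
def micro_nt():
    """Tiny nucleotide archive with a known sequence for oracle scans."""
    rng = np.random.default_rng(99)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
    arch = ix.build_index([("s1", "", seq)], "nucleotide")
    return arch, seq


class TestSearchSeeds:
    def test_exact_read_hits_sampling_diagonal(self, micro_nt):
        arch, seq = micro_nt
        read = seq[500:560]
        frames = ab.query_frames(ab.encode(read, ab.DNA5), "nucleotide")
        hits = sd.search_seeds(arch.fm, arch.concat, frames, P(seed_length=14, seed_offset=7))
        diags = {(h.qframe_index, h.diagonal) for h in hits}
        assert (0, 500) in diags

    def test_foreign_read_yields_nothing(self):
        # subject over {A,C} only; read over {G,T} shares no seed
        arch = ix.build_index([("s", "", "AC" * 300)], "nucleotide")
        frames = ab.query_frames(ab.encode("GT" * 20, ab.DNA5), "nucleotide")
        # rc frame of GT-repeat is AC-repeat, so restrict to the forward frame
        hits = sd.search_seeds(arch.fm, arch.concat, frames[:1], P(seed_length=14, seed_offset=7))
        assert hits == []

    def test_hit_diagonals_match_brute_force(self, micro_nt):
        """Diagonal set of seed hits equals a brute-force restricted-Hamming
        window scan (max_occ set high so adaptive elongation is inert)."""
        arch, seq = micro_nt
        rng = np.random.default_rng(3)
        text = ab.reduce(ab.encode(seq, ab.DNA5), ab.get_reduction("dna4"))
        for _ in range(10):
            start = int(rng.integers(0, len(seq) - 40))
            read = list(seq[start : start + 40])
            # sprinkle a couple of substitutions
            for p in rng.integers(0, 40, 2):
                read[p] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            frames = ab.query_frames(ab.encode(read, ab.DNA5), "nucleotide")
            params = P(seed_length=14, seed_offset=7, adaptive_max_occ=10**6)
            hits = sd.search_seeds(arch.fm, arch.concat, frames, params)
            got = {(h.qframe_index, h.diagonal) for h in hits}
            expected = set()
            for fi, frame in enumerate(frames):
                for wb, we in sd.generate_seed_windows(len(frame.reduced), params):
                    for pos in naive_half_exact(text, frame.reduced[wb:we], 1):
                        expected.add((fi, pos - wb))
            assert got == expected

    def test_result_independent_of_max_occ_when_unique(self, micro_nt):
        arch, seq = micro_nt
        read = seq[100:160]
        frames = ab.query_frames(ab.encode(read, ab.DNA5), "nucleotide")
        h1 = sd.search_seeds(arch.fm, arch.concat, frames, P(seed_length=14, seed_offset=7, adaptive_max_occ=1))
        h2 = sd.search_seeds(arch.fm, arch.concat, frames, P(seed_length=14, seed_offset=7, adaptive_max_occ=10**6))
        assert {(h.qframe_index, h.diagonal) for h in h1} <= {
            (h.qframe_index, h.diagonal) for h in h2
        }


class TestGaplessVerify:
    def test_identical_region_scores_match_times_length(self, micro_nt):
        arch, seq = micro_nt
        read = seq[200:240]
        frames = ab.query_frames(ab.encode(read, ab.DNA5), "nucleotide")
        params = P(seed_length=14, seed_offset=7)
        hits = [h for h in sd.search_seeds(arch.fm, arch.concat, frames, params)
                if h.qframe_index == 0 and h.diagonal == 200]
        assert hits
        scheme = al.get_scheme("nt")
        q = frames[0].unreduced
        s = arch.subject_frame_unreduced(0, hits[0].sframe)
        score = sd.gapless_verify(hits[0], q, s, scheme)
        assert score == 2 * len(read)  # extension covers the whole read

    def test_reduced_space_only_match_scores_lower(self):
        # CT-equal but every unreduced position is a C/T mismatch
        subj = "C" * 30
        read = "T" * 30
        arch = ix.build_index([("s", "", subj + "ACGTACGTACGT")], "nucleotide")
        frames = ab.query_frames(ab.encode(read, ab.DNA5), "nucleotide")
        scheme = al.get_scheme("nt")
        hit = sd.SeedHit(0, 0, frames[0].tag, 0, 14, 0, arch.concat.tags[0], 0, 14, 1)
        s = arch.subject_frame_unreduced(0, hit.sframe)
        score = sd.gapless_verify(hit, frames[0].unreduced, s, scheme)
        perfect = sd.gapless_verify(
            hit, s[:30], s, scheme
        )
        assert score < perfect

    def test_oracle_best_ungapped_segment(self, micro_nt):
        """Verification score equals the best ungapped segment through the
        seed, computed by an exhaustive extent scan."""
        arch, seq = micro_nt
        rng = np.random.default_rng(8)
        scheme = al.get_scheme("nt")
        for _ in range(10):
            start = int(rng.integers(50, len(seq) - 90))
            read = list(seq[start : start + 40])
            for p in rng.integers(2, 38, 2):
                read[p] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            q = ab.encode(read, ab.DNA5)
            s = arch.subject_frame_unreduced(0, arch.concat.tags[0])
            hit = sd.SeedHit(0, 0, None, 10, 24, 0, arch.concat.tags[0], start + 10, 14, 1)
            got = sd.gapless_verify(hit, q, s, scheme)
            # brute force: all ungapped extents [a, b) containing [10, 24)
            best = -(10**9)
            for a in range(0, 11):
                for b in range(24, 41):
                    sc = sum(
                        scheme.substitution(int(s[start + k]), int(q[k]))
                        for k in range(a, b)
                    )
                    best = max(best, sc)
            assert got == best


class TestIterativeSearch:
    def _verify_all(self, hit):
        return True

    def test_exact_query_first_pass(self, micro_nt):
        arch, seq = micro_nt
        frames = ab.query_frames(ab.encode(seq[300:360], ab.DNA5), "nucleotide")
        params = sd.profile_params("nucleotide", "fast")
        hits, indicator = sd.iterative_search(
            arch.fm, arch.concat, frames, params, self._verify_all
        )
        assert hits and indicator == 1

    def test_second_pass_rescues_mismatched_query(self, micro_nt):
        """A read whose pass-1 (exact, offset-14) seeds all contain an error
        is recovered by the pass-2 parameters (delta=1, half-exact)."""
        arch, seq = micro_nt
        read = list(seq[700:730])
        read[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[10]]
        read[24] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[24]]
        frames = ab.query_frames(ab.encode("".join(read), ab.DNA5), "nucleotide")
        params = sd.profile_params("nucleotide", "fast")
        hits, indicator = sd.iterative_search(
            arch.fm, arch.concat, frames, params,
            lambda h: h.qframe_index == 0 and h.diagonal == 700,
        )
        assert indicator == 2
        assert any(h.diagonal == 700 for h in hits)

    def test_absent_query_empty_after_both_passes(self):
        arch = ix.build_index([("s", "", "AC" * 300)], "nucleotide")
        frames = ab.query_frames(ab.encode("GT" * 15, ab.DNA5), "nucleotide")[:1]
        params = sd.profile_params("nucleotide", "fast")
        hits, indicator = sd.iterative_search(
            arch.fm, arch.concat, frames, params, self._verify_all
        )
        assert hits == [] and indicator == 2


def test_decreasing_offset_never_loses_hits(micro_nt):
    """Superset monotonicity: halving the seed offset (divisor chain) only
    adds seed hits."""
    arch, seq = micro_nt
    rng = np.random.default_rng(12)
    for _ in range(5):
        start = int(rng.integers(0, len(seq) - 50))
        read = list(seq[start : start + 50])
        for p in rng.integers(0, 50, 3):
            read[p] = "ACGT"[int(rng.integers(0, 4))]
        frames = ab.query_frames(ab.encode("".join(read), ab.DNA5), "nucleotide")
        sets = []
        for off in (8, 4, 2):
            params = P(seed_length=14, seed_offset=off, adaptive_max_occ=10**6)
            hits = sd.search_seeds(arch.fm, arch.concat, frames, params)
            sets.append({(h.qframe_index, h.diagonal) for h in hits})
        assert sets[0] <= sets[1] <= sets[2]
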