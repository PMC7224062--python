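"""Masked reference, banded aligner (with quadratic DP oracle), coverage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pkdpanel import (Aligner, MaskedReference, ReadErrorModel, Scoring,
                      align_read, build_masked_reference, coverage_profile,
                      simulate_reads)
from pkdpanel.maskalign import ReadAlignment, banded_local_align, encode
from pkdpanel.simlocus import revcomp


def smith_waterman_oracle(ref: str, read: str, match=2, mismatch=-3, gap=-5) -> int:
    """Unbanded full Smith-Waterman (linear gaps), quadratic reference DP."""
    n, m = len(ref), len(read)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if (ref[j - 1] == read[i - 1] and ref[j - 1] != "N") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
            best = max(best, H[i][j])
    return best


class TestMaskedReference:
    def test_definition_example(self):
        seq = "".join("ACGT"[i % 4] for i in range(100))
        ref = build_masked_reference(seq, [(10, 40)])
        assert ref.sequence[:10] == "N" * 10
        assert ref.sequence[40:] == "N" * 60
        assert ref.sequence[10:40] == seq[10:40]
        assert len(ref.sequence) == len(seq)

    def test_full_target_is_identity(self):
        seq = "ACGTACGTAC" * 10
        ref = build_masked_reference(seq, [(0, len(seq))])
        assert ref.sequence == seq

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 190), st.integers(1, 30)), max_size=5),
           st.integers(0, 2 ** 31 - 1))
    def test_random_intervals_brute_force(self, raw, seed):
        """Per-base brute-force check of masking over random disjoint intervals."""
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 200))
        ivs = []
        last = 0
        for start, width in sorted(raw):
            s = max(start, last)
            e = min(200, s + width)
            if e > s:
                ivs.append((s, e))
                last = e
        ref = build_masked_reference(seq, ivs)
        inside = {p for s, e in ivs for p in range(s, e)}
        for p in range(200):
            if p in inside:
                assert ref.sequence[p] == seq[p]
            else:
                assert ref.sequence[p] == "N"
        assert sum(1 for c in ref.sequence if c != "N") == len(inside)

    def test_bad_intervals_rejected(self):
        seq = "ACGT" * 30
        with pytest.raises(ValueError):
            build_masked_reference(seq, [(10, 40), (30, 60)])
        with pytest.raises(ValueError):
            build_masked_reference(seq, [(100, 200)])


class TestAligner:
    def test_exact_substring_perfect_alignment(self, locus, masked_ref):
        s, e = masked_ref.target_intervals[0]
        start = s + 100
        read = locus.gene_sequence[start:start + 200]
        aln = align_read(read, masked_ref)
        assert aln is not None
        assert aln.ref_start == start
        assert aln.n_mismatch == 0
        assert aln.cigar == "200M"
        assert aln.score == 2 * 200

    @pytest.mark.parametrize("case_seed", range(8))
    def test_banded_matches_quadratic_oracle(self, case_seed):
        """Banded DP equals full Smith-Waterman on short reads with edits."""
        rng = np.random.default_rng(case_seed)
        ref_seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 300))
        start = 120
        read = list(ref_seq[start:start + 50])
        # up to two substitutions and one short indel in the middle
        for _ in range(int(rng.integers(0, 3))):
            p = int(rng.integers(5, 45))
            read[p] = "ACGT"[("ACGT".index(read[p]) + 1) % 4]
        if rng.random() < 0.5:
            p = int(rng.integers(10, 40))
            if rng.random() < 0.5:
                del read[p]
            else:
                read.insert(p, "ACGT"[int(rng.integers(0, 4))])
        read = "".join(read)
        oracle = smith_waterman_oracle(ref_seq, read)
        score, _, _, _ = banded_local_align(encode(ref_seq), encode(read), start,
                                            Scoring(), band=16)
        assert score == oracle

    def test_paralog_read_shows_anchor_mismatches(self, locus, masked_ref):
        """A pseudogene-origin read either aligns with its anchor mismatches
        visible or is rejected — it can never look like a clean gene read."""
        s, e = masked_ref.target_intervals[0]
        anchors = [a for a in locus.anchor_sites if s + 10 <= a < e - 210]
        hit = 0
        for a in anchors[:10]:
            read = locus.paralogs[0][a - 5:a + 195]
            aln = align_read(read, masked_ref)
            if aln is None:
                hit += 1
                continue
            assert aln.n_mismatch >= 1
            n_anchors_in_span = sum(1 for x in locus.anchor_sites
                                    if aln.ref_start <= x < aln.ref_start + 200)
            if n_anchors_in_span >= 3:
                assert aln.n_mismatch >= 3
                hit += 1
        assert hit >= 1

    def test_masked_region_attracts_no_reads(self, locus, masked_ref):
        """Reads from masked (off-target) territory are rejected outright."""
        read = locus.gene_sequence[0:60]  # outside the padded exon territory
        if masked_ref.sequence[0:60] == "N" * 60:
            assert align_read(read, masked_ref) is None

    def test_revcomp_invariance(self, locus, masked_ref):
        s, _ = masked_ref.target_intervals[0]
        read = locus.gene_sequence[s + 50:s + 250]
        rc_ref = MaskedReference(revcomp(masked_ref.sequence),
                                 tuple((masked_ref.length - e, masked_ref.length - s2)
                                       for s2, e in reversed(masked_ref.target_intervals)),
                                 "rc")
        a1 = align_read(read, masked_ref)
        a2 = align_read(revcomp(read), rc_ref)
        assert a1 is not None and a2 is not None
        assert a1.score == a2.score

    def test_tie_gets_zero_confidence(self):
        """Equal-scoring locations: leftmost reported, confidence 0."""
        unit = "".join("ACGT"[c] for c in np.random.default_rng(3).integers(0, 4, 120))
        seq = unit + "TTTTGGGGCCCCAAAA" + unit
        ref = MaskedReference(seq, ((0, len(seq)),), "dup")
        read = unit[10:90]
        aln = Aligner(ref).align(read)
        assert aln is not None
        assert aln.ref_start == 10
        assert aln.confidence == 0

    def test_non_iupac_rejected(self, masked_ref):
        with pytest.raises(ValueError, match="non-IUPAC"):
            align_read("XX" + "A" * 40, masked_ref)
        with pytest.raises(ValueError, match=">= 30"):
            align_read("ACGT", masked_ref)


class TestCoverage:
    def test_no_alignments_all_low(self, masked_ref):
        prof = coverage_profile([], masked_ref, threshold=20)
        total_target = sum(e - s for s, e in masked_ref.target_intervals)
        assert prof.fraction_at_least_threshold == 0.0
        assert sum(e - s for s, e in prof.low_coverage_intervals) == total_target

    def test_single_read_still_below_threshold(self, masked_ref):
        s, _ = masked_ref.target_intervals[0]
        aln = ReadAlignment("r", s + 10, "200M", 400, 0, 60, "+", "A" * 200,
                            masked_ref.source_name)
        prof = coverage_profile([aln], masked_ref, threshold=20)
        total_target = sum(e - s for s, e in masked_ref.target_intervals)
        assert sum(e - s for s, e in prof.low_coverage_intervals) == total_target

    def test_uniform_depth_poisson_oracle(self):
        """Uniform random reads: mean depth near nominal, all target >= 20x."""
        rng = np.random.default_rng(8)
        L, rl, depth = 2000, 200, 100
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, L))
        ref = MaskedReference(seq, ((300, 1700),), "u")
        n = depth * L // rl
        alns = [ReadAlignment(f"r{i}", int(rng.integers(0, L - rl)), f"{rl}M",
                              400, 0, 60, "+", "A" * rl, "u") for i in range(n)]
        prof = coverage_profile(alns, ref, threshold=20)
        assert prof.fraction_at_least_threshold == 1.0
        sd = (depth * rl / L * (1 - rl / L) * n) ** 0.5 / (n * rl / L) * depth
        assert abs(prof.mean_depth - depth) < 3 * max(sd, 1.0)

    def test_depth_sums_equal_aligned_span(self, locus, amplicons, masked_ref):
        reads = simulate_reads(locus, amplicons, [], depth=20,
                               error_model=ReadErrorModel.error_free(), seed=2)
        alns = Aligner(masked_ref).align_reads(reads)
        prof = coverage_profile(alns, masked_ref)
        spans = sum(a.ref_end - a.ref_start for a in alns)
        assert int(prof.depth.sum()) == spans
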