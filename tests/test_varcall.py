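"""Pileup, germline calling, QC flags, mosaic scan, allele dropout."""

import pytest

from pkdpanel import (Aligner, MaskedReference, ReadErrorModel, VariantScenario,
                      build_pileup, call_germline, detect_allele_dropout,
                      qc_allele_balance, scan_mosaic, simulate_reads)
from pkdpanel.experiments import make_site_pileup, masked_reference_of
from pkdpanel.maskalign import ReadAlignment, _iter_cigar
from pkdpanel.varcall import (QC_GC_RICH, QC_HOMOPOLYMER, QC_UNBALANCED,
                              VariantCall, left_align_indel)


def _mk_ref(seq: str, name: str = "t") -> MaskedReference:
    return MaskedReference(seq, ((0, len(seq)),), name)


def _aln(seq: str, start: int, cigar: str, strand: str = "+") -> ReadAlignment:
    return ReadAlignment("r", start, cigar, 0, 0, 60, strand, seq, "t")


def naive_recount(alignments, ref_len: int):
    """Brute-force per-read walk: per-position base counts, ignoring indels."""
    counts = {}
    for a in alignments:
        rp, qp = a.ref_start, 0
        for ln, op in _iter_cigar(a.cigar):
            if op == "S":
                qp += ln
            elif op == "M":
                for k in range(ln):
                    counts.setdefault(rp + k, {}).setdefault(a.sequence[qp + k], 0)
                    counts[rp + k][a.sequence[qp + k]] += 1
                rp += ln
                qp += ln
            elif op == "D":
                rp += ln
            elif op == "I":
                qp += ln
    return counts


class TestPileup:
    def test_all_ref_reads(self):
        seq = "ACGTAC" * 20
        ref = _mk_ref(seq)
        alns = [_aln(seq[10:50], 10, "40M") for _ in range(10)]
        pu = build_pileup(alns, ref)
        assert pu.depth[20] == 10
        assert pu.base_counts[:, 20].sum() == 10
        assert pu.alt_counts(20) == {}

    def test_half_alt(self):
        seq = "ACGTACGTAC" * 10
        ref = _mk_ref(seq)
        alt_seq = seq[10:50]
        alt_seq = alt_seq[:10] + "T" + alt_seq[11:]  # position 20, ref G
        alns = [_aln(seq[10:50], 10, "40M") for _ in range(5)]
        alns += [_aln(alt_seq, 10, "40M") for _ in range(5)]
        pu = build_pileup(alns, ref)
        assert pu.depth[20] == 10
        assert pu.alt_counts(20) == {"T": 5}

    def test_random_pileup_matches_naive_walk(self, rng):
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 300))
        ref = _mk_ref(seq)
        alns = []
        for i in range(60):
            start = int(rng.integers(0, 240))
            ln = int(rng.integers(30, 60))
            sub = list(seq[start:start + ln])
            for _ in range(int(rng.integers(0, 3))):
                p = int(rng.integers(0, ln))
                sub[p] = "ACGT"[int(rng.integers(0, 4))]
            alns.append(_aln("".join(sub), start, f"{ln}M",
                             "+" if i % 2 else "-"))
        pu = build_pileup(alns, ref)
        oracle = naive_recount(alns, len(seq))
        for pos, base_counts in oracle.items():
            for b, n in base_counts.items():
                assert pu.base_counts["ACGT".index(b), pos] == n
        # conservation: allele counts sum to depth; strand counts bounded
        assert (pu.base_counts.sum(axis=0) == pu.depth).all()
        assert (pu.base_counts_fwd <= pu.base_counts).all()

    def test_deletion_left_aligned(self):
        #           0123456789
        seq = "ACGTAAAACGTACGTACGTACGTACGTACGTA"
        ref = _mk_ref(seq)
        # read deletes one A of the A-run: alignment reports D at run end;
        # normalization must shift it to the leftmost representation
        read = seq[0:4] + seq[5:24]
        alns = [_aln(read, 0, "4M1D19M")]
        pu = build_pileup(alns, ref)
        assert len(pu.indels) == 1
        (pos, ref_a, alt_a), (cnt, fwd) = next(iter(pu.indels.items()))
        assert cnt == 1
        assert pos == 3  # anchored at the base before the A-run
        assert ref_a == "TA" and alt_a == "T"

    def test_left_align_indel_unit(self):
        seq = "GGCCAAAATTGG"
        # deleting any single A of the run is equivalent; canonical form
        # anchors on the C before the run
        assert left_align_indel(seq, 6, "AA", "A") == (3, "CA", "C")
        assert left_align_indel(seq, 4, "AA", "A") == (3, "CA", "C")
        # insertion of an extra A likewise
        assert left_align_indel(seq, 7, "A", "AA") == (3, "C", "CA")
        # non-repetitive context stays put
        seq2 = "GACGTTACG"
        assert left_align_indel(seq2, 2, "CG", "C") == (2, "CG", "C")


class TestCallGermline:
    def test_simple_het(self):
        pu, _ = make_site_pileup(50, 100)
        calls = call_germline(pu)
        assert len(calls) == 1
        assert calls[0].genotype == "het"
        assert calls[0].vaf == pytest.approx(0.5)

    def test_subthreshold_not_called(self):
        """156 alt reads of 2,193 (VAF 7.1%) stay below the 10% threshold."""
        pu, _ = make_site_pileup(156, 2193, deletion_len=4, seed=5)
        assert call_germline(pu) == []

    def test_threshold_sweep_boundary(self):
        """The call boundary sits exactly at the VAF threshold."""
        for alt in range(5, 30):
            pu, _ = make_site_pileup(alt, 200, seed=alt)
            called = bool(call_germline(pu, call_threshold=0.10))
            assert called == (alt / 200 >= 0.10)

    def test_threshold_ordering_enforced(self):
        pu, _ = make_site_pileup(10, 20)
        with pytest.raises(ValueError):
            call_germline(pu, call_threshold=0.5, het_band=(0.2, 0.8))

    def test_hom_and_ambiguous_states(self):
        pu, _ = make_site_pileup(95, 100, seed=2)
        (call,) = call_germline(pu)
        assert call.genotype == "hom"
        pu, _ = make_site_pileup(17, 100, seed=3)
        (call,) = call_germline(pu)
        assert call.genotype == "ambiguous"
        assert QC_UNBALANCED in call.qc_flags


class TestQcFlags:
    def test_unbalanced_homopolymer_flags(self):
        seq = "ACGT" * 10 + "GGGGGG" + "ACGT" * 10
        ref = _mk_ref(seq)
        pu = build_pileup([_aln(seq[30:70], 30, "40M")], ref)
        call = VariantCall(pos=42, ref="G", alt="A", alt_depth=12, depth=100,
                           genotype="het", ref_name="t")
        flagged = qc_allele_balance(call, pu)
        assert QC_UNBALANCED in flagged.qc_flags
        assert QC_HOMOPOLYMER in flagged.qc_flags

    def test_balanced_clean_context_unflagged(self):
        seq = "ACGT" * 20
        ref = _mk_ref(seq)
        pu = build_pileup([_aln(seq[0:40], 0, "40M")], ref)
        call = VariantCall(pos=20, ref="A", alt="T", alt_depth=50, depth=100,
                           genotype="het", ref_name="t")
        assert qc_allele_balance(call, pu).qc_flags == set()

    def test_gc_rich_flag(self):
        seq = "AT" * 20 + "GCGGGCGCCG" * 6 + "AT" * 20
        ref = _mk_ref(seq)
        pu = build_pileup([_aln(seq[40:80], 40, "40M")], ref)
        call = VariantCall(pos=70, ref=seq[70], alt="A", alt_depth=50, depth=100,
                           genotype="het", ref_name="t")
        assert QC_GC_RICH in qc_allele_balance(call, pu).qc_flags

    def test_homopolymer_sites_flag_more_often(self, small_study):
        """On error-only data, raw sub-threshold artifacts cluster in runs."""
        locus, amps = small_study
        em = ReadErrorModel(substitution_rate=0.01, homopolymer_rate0=0.01)
        reads = simulate_reads(locus, amps, [], depth=300, error_model=em,
                               contamination=0.0, seed=77)
        ref = masked_reference_of(locus)
        pu = build_pileup(Aligner(ref).align_reads(reads), ref)
        # indel artifacts (counted at the first run base right of the anchor)
        # must concentrate in homopolymer context
        hp_mass = plain_mass = 0
        for (pos, _r, _a), (cnt, _f) in pu.indels.items():
            if pu.homopolymer_len[min(pos + 1, len(pu.homopolymer_len) - 1)] >= 3:
                hp_mass += cnt
            else:
                plain_mass += cnt
        assert hp_mass > plain_mass


class TestMosaicScan:
    def test_known_mosaic_regimes(self):
        pu, _ = make_site_pileup(40, 252, seed=1)
        (cand,) = scan_mosaic(pu, error_rate=0.01)
        assert cand.vaf_percent == 15.9
        pu, _ = make_site_pileup(156, 2193, deletion_len=4, seed=2)
        (cand,) = scan_mosaic(pu, error_rate=0.01)
        assert cand.alt_depth == 156 and cand.depth == 2193
        assert cand.p_value < 1e-10

    def test_zero_alt_never_candidate(self):
        pu, _ = make_site_pileup(0, 500, seed=3)
        assert scan_mosaic(pu) == []

    def test_error_level_signal_not_candidate(self):
        """3 alt of 300 at a 1% error rate is exactly the expectation."""
        pu, _ = make_site_pileup(3, 300, seed=4)
        assert scan_mosaic(pu, error_rate=0.01, min_alt=1) == []

    def test_error_rate_domain(self):
        pu, _ = make_site_pileup(10, 100)
        with pytest.raises(ValueError):
            scan_mosaic(pu, error_rate=0.2, germline_threshold=0.1)

    def test_monotonic_in_alt_count(self):
        """Raising the alt count at fixed depth never de-flags a candidate."""
        was_candidate = False
        for alt in range(5, 40):
            pu, _ = make_site_pileup(alt, 300, seed=10 + alt)
            is_cand = bool(scan_mosaic(pu, error_rate=0.01, max_vaf=0.2))
            assert is_cand or not was_candidate or alt / 300 >= 0.2
            was_candidate = was_candidate or is_cand

    def test_type_one_error_control(self, small_study):
        """On error-only simulations the Bonferroni scan stays quiet."""
        locus, amps = small_study
        ref = masked_reference_of(locus)
        n_candidates = n_scans = 0
        for seed in range(10):
            reads = simulate_reads(
                locus, amps, [], depth=150,
                error_model=ReadErrorModel(substitution_rate=0.005,
                                           homopolymer_rate0=0.002),
                contamination=0.0, seed=500 + seed)
            pu = build_pileup(Aligner(ref).align_reads(reads), ref)
            cands = scan_mosaic(pu, error_rate=0.01, alpha=0.05, min_alt=5)
            n_candidates += len(cands)
            n_scans += int(((pu.depth > 0) & ref.is_target()).sum())
        assert n_candidates / n_scans <= 0.05


class TestDropout:
    def _simulate(self, seed, dropout: bool):
        from pkdpanel.experiments import study_locus
        from pkdpanel.intervals import intersect

        locus, amps = study_locus(seed)
        a, b = amps.amplicons[0], amps.amplicons[1]
        ov = intersect(a.interval, b.interval)
        pos = (ov[0] + ov[1]) // 2
        ref_b = locus.gene_sequence[pos]
        alt_b = "ACGT"[("ACGT".index(ref_b) + 1) % 4]
        sc = VariantScenario(position=pos, ref=ref_b, alt=alt_b, zygosity="het",
                             dropout=dropout,
                             dropout_amplicon=a.name if dropout else None)
        reads = simulate_reads(locus, amps, [sc], depth=150, contamination=0.0,
                               seed=seed * 7 + 1)
        ref = masked_reference_of(locus)
        alns = Aligner(ref).align_reads(reads)
        return pos, detect_allele_dropout(alns, ref, amps)

    def test_injected_dropout_flagged(self):
        pos, report = self._simulate(21, dropout=True)
        assert report.possible
        assert any(e["kind"] == "hom_vs_het" and e["pos"] == pos
                   for e in report.events)

    def test_concordant_het_unflagged(self):
        pos, report = self._simulate(22, dropout=False)
        assert report.possible
        assert not any(e["pos"] == pos for e in report.events)

    def test_no_overlap_reported_impossible(self, locus):
        from pkdpanel.simlocus import Amplicon, AmpliconSet

        amps = AmpliconSet((Amplicon("a1", (0, 500), (0, 25), (475, 500)),
                            Amplicon("a2", (600, 1100), (600, 625), (1075, 1100))))
        ref = masked_reference_of(locus)
        report = detect_allele_dropout([], ref, amps)
        assert not report.possible
        assert "not possible" in report.reason
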