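"""Synthetic locus, amplicon design, read/MLPA/cohort simulators."""

import io

import numpy as np
import pytest

from pkdpanel import (ReadErrorModel, VariantScenario, generate_locus,
                      simulate_cohort, simulate_mlpa, simulate_reads)
from pkdpanel.io import write_fastq
from pkdpanel.simlocus import default_probe_panel, revcomp


class TestGenerateLocus:
    @pytest.mark.parametrize("seed,identity,n_par", [(1, 0.98, 6), (2, 0.95, 3), (7, 0.9, 1)])
    def test_invariants(self, seed, identity, n_par):
        loc = generate_locus(seed, n_paralogs=n_par, identity=identity, length=5000)
        assert len(loc.paralogs) == n_par
        for k in range(n_par):
            # pairwise identity within +/- 2 percentage points of the request
            assert abs(loc.identity_to(k) - identity) <= 0.02
            for a in loc.anchor_sites:
                assert loc.paralogs[k][a] != loc.gene_sequence[a]
        # exons sorted, disjoint, in bounds
        prev_end = 0
        for s, e in loc.exon_intervals:
            assert 0 <= prev_end <= s < e <= loc.length
            prev_end = e

    def test_deterministic(self):
        a = generate_locus(5, length=3000)
        b = generate_locus(5, length=3000)
        assert a.gene_sequence == b.gene_sequence
        assert a.paralogs == b.paralogs
        assert a.anchor_sites == b.anchor_sites

    def test_no_paralogs_degenerates(self):
        loc = generate_locus(1, n_paralogs=0, length=2500)
        assert loc.paralogs == ()

    def test_identity_one_rejected(self):
        with pytest.raises(ValueError):
            generate_locus(1, identity=1.0)
        with pytest.raises(ValueError):
            generate_locus(1, length=1000)


class TestAmplicons:
    def test_invariants(self, locus, amplicons):
        # every exon covered, every primer window holds an anchor, one overlap
        from pkdpanel.intervals import merge_intervals

        merged = merge_intervals([a.interval for a in amplicons.amplicons])
        for ex in locus.exon_intervals:
            assert any(s <= ex[0] and ex[1] <= e for s, e in merged)
        anchors = set(locus.anchor_sites)
        for a in amplicons.amplicons:
            for lo, hi in (a.forward_primer, a.reverse_primer):
                assert anchors & set(range(lo, hi))
        assert amplicons.overlaps

    def test_scenario_validation(self, amplicons):
        with pytest.raises(ValueError, match="mosaic_fraction"):
            VariantScenario(position=10, ref="A", alt="T", zygosity="mosaic")
        with pytest.raises(ValueError, match="mosaic_fraction"):
            VariantScenario(position=10, ref="A", alt="T", mosaic_fraction=0.1)
        with pytest.raises(ValueError, match="amplicon"):
            VariantScenario(position=10, ref="A", alt="T", dropout=True)


def _count_alleles(gene: str, reads, pos: int, alt: str) -> tuple[int, int]:
    """Alignment-free allele count for error-free reads: substring membership.

    Reference reads are exact gene substrings; alt reads are exact substrings
    of the gene with the SNV applied. Counts reads covering ``pos`` each way.
    """
    gene_alt = gene[:pos] + alt + gene[pos + 1:]
    n_ref = n_alt = 0
    for r in reads:
        if r.origin != "gene":
            continue
        seq = r.sequence if r.strand == "+" else revcomp(r.sequence)
        idx = gene.find(seq)
        if idx >= 0:
            if idx <= pos < idx + len(seq):
                n_ref += 1
            continue
        idx = gene_alt.find(seq)
        if idx >= 0 and idx <= pos < idx + len(seq):
            n_alt += 1
    return n_ref, n_alt


class TestSimulateReads:
    def test_error_free_reads_are_gene_substrings(self, locus, amplicons):
        reads = simulate_reads(locus, amplicons, [], depth=5,
                               error_model=ReadErrorModel.error_free(),
                               contamination=0.0, seed=3)
        gene = locus.gene_sequence
        for r in reads[:200]:
            seq = r.sequence if r.strand == "+" else revcomp(r.sequence)
            assert seq in gene

    def test_read_count_conservation(self, locus, amplicons):
        em = ReadErrorModel.error_free()
        reads = simulate_reads(locus, amplicons, [], depth=40, error_model=em,
                               contamination=0.0, seed=4)
        expected = sum(round(40 * (e - s) / em.read_length)
                       for a in amplicons.amplicons for s, e in [a.interval])
        assert abs(len(reads) - expected) <= len(amplicons.amplicons)

    def test_het_fraction_binomial(self, locus, amplicons):
        """Injected het recovered at 0.5 within 3 binomial SDs (naive count)."""
        pos = locus.exon_intervals[0][0] + 37
        sc = VariantScenario(position=pos, ref=locus.gene_sequence[pos], alt="A"
                             if locus.gene_sequence[pos] != "A" else "C")
        reads = simulate_reads(locus, amplicons, [sc], depth=100,
                               error_model=ReadErrorModel.error_free(),
                               contamination=0.0, seed=5)
        n_ref, n_alt = _count_alleles(locus.gene_sequence, reads, pos, sc.alt)
        n_cover = n_ref + n_alt
        assert n_cover > 100
        p = 0.5
        sd = (n_cover * p * (1 - p)) ** 0.5
        assert abs(n_alt - p * n_cover) <= 3 * sd

    def test_mosaic_fraction_recovery(self, small_study):
        """Mean injected mosaic fraction recovered over many seeds."""
        locus, amps = small_study
        pos = locus.exon_intervals[0][0] + 50
        ref_b = locus.gene_sequence[pos]
        alt_b = "ACGT"[("ACGT".index(ref_b) + 1) % 4]
        frac = 0.159
        totals = alts = 0
        for seed in range(40):
            sc = VariantScenario(position=pos, ref=ref_b, alt=alt_b,
                                 zygosity="mosaic", mosaic_fraction=frac)
            reads = simulate_reads(locus, amps, [sc], depth=60,
                                   error_model=ReadErrorModel.error_free(),
                                   contamination=0.0, seed=100 + seed)
            n_ref, n_alt = _count_alleles(locus.gene_sequence, reads, pos, alt_b)
            totals += n_ref + n_alt
            alts += n_alt
        sd = (totals * frac * (1 - frac)) ** 0.5
        assert abs(alts - frac * totals) <= 3 * sd

    def test_deterministic_fastq(self, locus, amplicons, tmp_path):
        buf = []
        for _ in range(2):
            reads = simulate_reads(locus, amplicons, [], depth=10, seed=9)
            s = io.StringIO()
            path = tmp_path / "r.fastq"
            write_fastq(path, reads)
            buf.append(path.read_bytes())
        assert buf[0] == buf[1]

    def test_scenario_outside_amplicons_rejected(self, locus, amplicons):
        with pytest.raises(ValueError, match="outside"):
            simulate_reads(locus, amplicons,
                           [VariantScenario(position=locus.length - 1, ref="A", alt="T")],
                           depth=5, seed=1)


class TestSimulateMlpa:
    def test_diploid_no_noise_flat(self):
        probes = default_probe_panel(6)
        t = simulate_mlpa({}, probes, noise_sd=0.0, seed=0)
        assert t["peak"].nunique() == 1

    def test_exon_deletion_half_level(self):
        probes = default_probe_panel(12)
        t = simulate_mlpa({"exon8": 1, "exon9": 1}, probes, noise_sd=0.0, seed=0)
        t = t.set_index("probe")["peak"]
        assert t["ex8"] == pytest.approx(t["ref1"] * 0.5)
        assert t["ex9"] == pytest.approx(t["ref1"] * 0.5)

    def test_whole_gene_deletion(self):
        probes = default_probe_panel(12)
        t = simulate_mlpa({f"exon{i}": 1 for i in range(1, 13)}, probes,
                          noise_sd=0.0, seed=0)
        gene = t[~t["probe"].str.startswith("ref")]
        refs = t[t["probe"].str.startswith("ref")]
        assert np.allclose(gene["peak"], refs["peak"].iloc[0] * 0.5)

    def test_unknown_exon_rejected(self):
        probes = default_probe_panel(6)
        with pytest.raises(ValueError, match="unknown exon"):
            simulate_mlpa({"exon99": 1}, probes)
        with pytest.raises(ValueError, match="copy number"):
            simulate_mlpa({"exon1": 5}, probes)


class TestSimulateCohort:
    def test_class_means_ordered(self):
        records, _ = simulate_cohort(500, seed=2)
        m = records.groupby("genotype_class")["onset_age"].mean()
        assert m["PKD1-T"] < m["PKD1-NT"] < m["PKD2"]

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(0)
        with pytest.raises(ValueError):
            simulate_cohort(9)

    def test_negative_sd_rejected(self):
        bad = {"PKD1-T": {"onset": (26.0, -1.0)}}
        with pytest.raises(ValueError, match="negative SD"):
            simulate_cohort(20, onset_effects=bad)

    def test_deterministic(self):
        a, peds_a = simulate_cohort(50, seed=42)
        b, peds_b = simulate_cohort(50, seed=42)
        assert a.equals(b)
        assert peds_a == peds_b
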