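"""End-to-end validation studies and worked-example fixtures.

These functions run the whole pipeline on simulated data at fixed, declared
study conditions (depth 500 and 5% pseudogene contamination for the masking
studies, depth 100 for dropout, noise SD 0.05 for MLPA) and measure detection
rates. They are used both by the test suite and by the reproduction script, so
the numbers a reader sees always come from the same code path.

The ``reference_*`` fixtures encode the count tables of a large ADPKD
diagnostic cohort (patient groups, variant spectrum, family-history breakdown)
as data frames, so the
reporting operations can be exercised on realistic bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maskalign import (Aligner, MaskedReference, ReadAlignment,
                        build_masked_reference)
from .simlocus import (AmpliconSet, SyntheticLocus, VariantScenario,
                       design_amplicons, generate_locus, simulate_cohort, simulate_mlpa,
                       default_probe_panel)
from .mlpa import ProbePanel, call_rearrangements, normalize_dosage
from .varcall import (Pileup, build_pileup, call_germline,
                      detect_allele_dropout)
from .cohort import anova_onset


# ---------------------------------------------------------------------------
# Small-locus study setup
# ---------------------------------------------------------------------------


def study_locus(seed: int, length: int = 2000, n_exons: int = 1,
                exon_length: int = 500, n_paralogs: int = 6,
                identity: float = 0.98) -> tuple[SyntheticLocus, AmpliconSet]:
    """A compact duplicated locus with two overlapping amplicons.

    Small enough that hundreds of seeds run in minutes at depth 500, while
    keeping the structural features that matter: six paralogs at 98% identity,
    anchored primers, and an overlapping amplicon pair.
    """
    locus = generate_locus(seed, n_paralogs=n_paralogs, identity=identity,
                           length=length, n_exons=n_exons, exon_length=exon_length)
    amps = design_amplicons(locus, amplicon_length=600, min_overlap=200)
    return locus, amps


def masked_reference_of(locus: SyntheticLocus, pad: int = 150) -> MaskedReference:
    """Mask everything outside the padded exon territory of the gene."""
    lo = max(0, min(s for s, _ in locus.exon_intervals) - pad)
    hi = min(locus.length, max(e for _, e in locus.exon_intervals) + pad)
    return build_masked_reference(locus.gene_sequence, [(lo, hi)], "gene")


def two_copy_reference(locus: SyntheticLocus) -> MaskedReference:
    """Unmasked naive reference: the gene followed by one paralog copy."""
    seq = locus.gene_sequence + locus.paralogs[0]
    return MaskedReference(seq, ((0, len(seq)),), "gene+paralog")


def _random_het_scenario(locus: SyntheticLocus, amps: AmpliconSet,
                         rng: np.random.Generator) -> VariantScenario:
    """A het SNV at a uniformly chosen exon position covered by an amplicon."""
    while True:
        exon = locus.exon_intervals[int(rng.integers(len(locus.exon_intervals)))]
        pos = int(rng.integers(exon[0], exon[1]))
        if amps.covering(pos):
            ref = locus.gene_sequence[pos]
            alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(3))) % 4]
            return VariantScenario(position=pos, ref=ref, alt=alt, zygosity="het")


# ---------------------------------------------------------------------------
# Masking benefit (sensitivity + false-call comparison)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaskingStudyResult:
    n_seeds: int
    injected: int
    called: int  # injected variants recovered by the masked pipeline
    masked_false_calls: int
    unmasked_false_calls: int
    per_seed: tuple[tuple[int, int], ...]  # (masked fp, unmasked fp) per seed


def sensitivity_study(n_seeds: int = 100, depth: float = 500.0,
                      contamination: float = 0.05, seed0: int = 0) -> tuple[int, int]:
    """Recovery of injected het germline variants by the masked pipeline.

    One random exonic het SNV per seed; returns (injected, called). A variant
    counts as called when the germline caller reports its exact site/allele.
    """
    from .simlocus import simulate_reads

    injected = called = 0
    for s in range(n_seeds):
        locus, amps = study_locus(seed0 + 1000 + s)
        rng = np.random.default_rng(seed0 + 5000 + s)
        sc = _random_het_scenario(locus, amps, rng)
        reads = simulate_reads(locus, amps, [sc], depth=depth,
                               contamination=contamination, seed=seed0 + 9000 + s)
        ref = masked_reference_of(locus)
        aligner = Aligner(ref)
        alns = aligner.align_reads(reads)
        calls = call_germline(build_pileup(alns, ref))
        injected += 1
        if any(c.pos == sc.position and c.alt == sc.alt for c in calls):
            called += 1
    return injected, called


def masking_benefit_study(n_seeds: int = 20, depth: float = 500.0,
                          contamination: float = 0.05, seed0: int = 0
                          ) -> MaskingStudyResult:
    """False germline calls: masked reference + confidence filter vs naive.

    The same simulated read set (one true het variant, 5% paralog
    contamination) is aligned both to the masked gene reference and to an
    unmasked gene+paralog reference on which variants are called over every
    position. Calls that are not the injected variant are false. Contamination
    reads pile onto the paralog copy of the naive reference at callable depth
    and produce spurious calls at paralog-divergent sites; on the masked
    reference they stay below the 10% germline threshold on the gene.
    """
    from .simlocus import simulate_reads

    per_seed: list[tuple[int, int]] = []
    called = 0
    for s in range(n_seeds):
        locus, amps = study_locus(seed0 + 100 + s)
        rng = np.random.default_rng(seed0 + 200 + s)
        sc = _random_het_scenario(locus, amps, rng)
        reads = simulate_reads(locus, amps, [sc], depth=depth,
                               contamination=contamination, seed=seed0 + 300 + s)

        masked = masked_reference_of(locus)
        alns_m = Aligner(masked).align_reads(reads)
        calls_m = call_germline(build_pileup(alns_m, masked))
        fp_m = sum(1 for c in calls_m if not (c.pos == sc.position and c.alt == sc.alt))
        if any(c.pos == sc.position and c.alt == sc.alt for c in calls_m):
            called += 1

        naive = two_copy_reference(locus)
        alns_u = Aligner(naive).align_reads(reads, min_confidence=0)
        calls_u = call_germline(build_pileup(alns_u, naive))
        fp_u = sum(1 for c in calls_u if not (c.pos == sc.position and c.alt == sc.alt))
        per_seed.append((fp_m, fp_u))
    return MaskingStudyResult(
        n_seeds=n_seeds, injected=n_seeds, called=called,
        masked_false_calls=sum(m for m, _ in per_seed),
        unmasked_false_calls=sum(u for _, u in per_seed),
        per_seed=tuple(per_seed),
    )


# ---------------------------------------------------------------------------
# Allele dropout detection rate
# ---------------------------------------------------------------------------


def dropout_detection_study(n_seeds: int = 100, depth: float = 100.0,
                            seed0: int = 0) -> tuple[int, int]:
    """Detection rate of injected wild-type allele dropout.

    A het variant inside the overlap of two amplicons loses its wild-type
    allele in one of them (variant under the primer site); detection means the
    cross-amplicon comparison reports a hom-vs-het discordance at the site.
    The site is drawn from the central stretch of the overlap, where both
    amplicons retain callable depth — near the overlap edges the second
    amplicon has no informative fragments and cross-checking is impossible by
    construction. Returns (n_seeds, n_detected).
    """
    from .intervals import intersect
    from .simlocus import simulate_reads

    detected = 0
    for s in range(n_seeds):
        locus, amps = study_locus(seed0 + 4000 + s)
        a, b = amps.amplicons[0], amps.amplicons[1]
        ov = intersect(a.interval, b.interval)
        rng = np.random.default_rng(seed0 + 4500 + s)
        mid = (ov[0] + ov[1]) // 2
        pos = int(rng.integers(mid - 30, mid + 31))
        ref_b = locus.gene_sequence[pos]
        alt_b = "ACGT"[("ACGT".index(ref_b) + 1) % 4]
        sc = VariantScenario(position=pos, ref=ref_b, alt=alt_b, zygosity="het",
                             dropout=True, dropout_amplicon=a.name)
        reads = simulate_reads(locus, amps, [sc], depth=depth, contamination=0.0,
                               seed=seed0 + 4800 + s)
        ref = masked_reference_of(locus)
        alns = Aligner(ref).align_reads(reads)
        report = detect_allele_dropout(alns, ref, amps)
        hits = [e for e in report.events
                if e["kind"] == "hom_vs_het" and e["pos"] == pos]
        if hits:
            detected += 1
    return n_seeds, detected


# ---------------------------------------------------------------------------
# MLPA recovery
# ---------------------------------------------------------------------------

MLPA_SCENARIOS = {
    "single_exon_del": {"exon5": 1},
    "exon8_9_del": {"exon8": 1, "exon9": 1},
    "whole_gene_del": {f"exon{i}": 1 for i in range(1, 13)},
    "single_exon_dup": {"exon5": 3},
}


def mlpa_recovery_study(n_seeds: int = 200, noise_sd: float = 0.05,
                        seed0: int = 0) -> dict[str, tuple[int, int]]:
    """Recovery of deletion/duplication events with correct span under noise.

    For each scenario and seed: simulate one sample plus three diploid
    controls, compute dosage quotients, call events, and require exactly one
    event of the right state covering exactly the aberrant exons (the
    whole-gene scenario must additionally raise the whole-gene flag).
    Returns scenario -> (n_seeds, n_correct).
    """
    probes = default_probe_panel(n_exons=12, probes_per_exon=1, n_reference=4)
    panel = ProbePanel(tuple(probes))
    out: dict[str, tuple[int, int]] = {}
    for idx, (name, copy_state) in enumerate(MLPA_SCENARIOS.items()):
        correct = 0
        want_state = "duplication" if any(c == 3 for c in copy_state.values()) else "deletion"
        want_exons = tuple(e for e in panel.gene_exons if e in copy_state)
        for s in range(n_seeds):
            base = seed0 + 100_000 * (idx + 1) + 17 * s
            sample = simulate_mlpa(copy_state, probes, noise_sd=noise_sd, seed=base)
            controls = [simulate_mlpa({}, probes, noise_sd=noise_sd, seed=base + 1 + c)
                        for c in range(3)]
            q = normalize_dosage(sample, controls, panel)
            _, events = call_rearrangements(q, panel)
            if (len(events) == 1 and events[0].state == want_state
                    and events[0].exons == want_exons
                    and events[0].whole_gene == (len(want_exons) == 12)):
                correct += 1
        out[name] = (n_seeds, correct)
    return out


# ---------------------------------------------------------------------------
# ANOVA power at the configured effect sizes
# ---------------------------------------------------------------------------


def anova_power_study(n_seeds: int = 200, n: int = 150, alpha: float = 0.05,
                      seed0: int = 0) -> dict[str, float]:
    """Rejection rate and ordering recovery for genotype-dependent onset ages.

    Cohorts of ~50 probands per genotype class (PKD1-T / PKD1-NT / PKD2) at
    the generator's default onset effects; counts how often one-way ANOVA
    rejects at ``alpha`` and how often the sample means recover the severity
    ordering (PKD1-T earliest).
    """
    mix = {"PKD1-T": 1 / 3, "PKD1-NT": 1 / 3, "PKD2": 1 / 3, "negative": 0.0}
    reject = ordered = 0
    for s in range(n_seeds):
        records, _ = simulate_cohort(n, class_mix=mix, seed=seed0 + 7000 + s)
        res = anova_onset(records, "onset_age", "nosology",
                          ["ADPKD-PKD1-T", "ADPKD-PKD1-NT", "ADPKD-PKD2"])
        if res.p_value < alpha:
            reject += 1
        m = res.group_means
        if m["ADPKD-PKD1-T"] < m["ADPKD-PKD1-NT"] < m["ADPKD-PKD2"]:
            ordered += 1
    return {"n_seeds": n_seeds, "rejection_rate": reject / n_seeds,
            "ordering_rate": ordered / n_seeds}


# ---------------------------------------------------------------------------
# Single-site pileups for the worked mosaic/threshold cases
# ---------------------------------------------------------------------------


def make_site_pileup(n_alt: int, n_total: int, ref_len: int = 240,
                     pos: int = 120, deletion_len: int = 0, seed: int = 0
                     ) -> tuple[Pileup, MaskedReference]:
    """A pileup with exactly ``n_alt`` variant reads among ``n_total`` at one site.

    The variant is a SNV by default or a ``deletion_len``-bp deletion; reads
    are 60 bp alignments built directly, so the pileup/caller path is exercised
    without simulation noise.
    """
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[int(c)] for c in rng.integers(0, 4, ref_len))
    # avoid an ambiguous alt: make the site's neighbourhood non-repetitive
    seq = seq[:pos] + "ACGT"[rng.integers(0, 4)] + seq[pos + 1:]
    ref = MaskedReference(seq, ((0, ref_len),), "site")
    read_len = 60
    alns = []
    for i in range(n_total):
        start = pos - int(rng.integers(10, read_len - 10 - max(1, deletion_len)))
        start = max(0, min(start, ref_len - read_len - deletion_len))
        is_alt = i < n_alt
        if deletion_len and is_alt:
            left = pos - start
            right = read_len - left
            sread = seq[start:pos] + seq[pos + deletion_len:pos + deletion_len + right]
            cigar = f"{left}M{deletion_len}D{right}M"
        elif is_alt:
            alt_base = "ACGT"[("ACGT".index(seq[pos]) + 1) % 4]
            sread = seq[start:pos] + alt_base + seq[pos + 1:start + read_len]
            cigar = f"{read_len}M"
        else:
            sread = seq[start:start + read_len]
            cigar = f"{read_len}M"
        alns.append(ReadAlignment(read_id=f"r{i}", ref_start=start, cigar=cigar,
                                  score=2 * read_len, n_mismatch=0 if not is_alt else 1,
                                  confidence=60, strand="+" if i % 2 == 0 else "-",
                                  sequence=sread, ref_name="site"))
    return build_pileup(alns, ref), ref


# ---------------------------------------------------------------------------
# Published count fixtures (bookkeeping tables)
# ---------------------------------------------------------------------------


def reference_cohort_records() -> pd.DataFrame:
    """212 probands in three arms with a realistic diagnostic-yield structure.

    Arms: validation (21: 12 PKD1-T / 6 PKD1-NT / 3 PKD2), confirmation
    (36: 25 / 3 / 3, 3 VUS-only, 2 plain negative), discovery
    (155: 55 / 17 / 14, 21 VUS-only, 48 plain negative).
    """
    rows = []

    def add(arm, label, k):
        for _ in range(k):
            rows.append({"proband": f"{arm[:1]}{len(rows):04d}", "arm": arm,
                         "nosology": label})

    add("validation", "ADPKD-PKD1-T", 12)
    add("validation", "ADPKD-PKD1-NT", 6)
    add("validation", "ADPKD-PKD2", 3)
    add("confirmation", "ADPKD-PKD1-T", 25)
    add("confirmation", "ADPKD-PKD1-NT", 3)
    add("confirmation", "ADPKD-PKD2", 3)
    add("confirmation", "PKD-VUS-only", 3)
    add("confirmation", "negative", 2)
    add("discovery", "ADPKD-PKD1-T", 55)
    add("discovery", "ADPKD-PKD1-NT", 17)
    add("discovery", "ADPKD-PKD2", 14)
    add("discovery", "PKD-VUS-only", 21)
    add("discovery", "negative", 48)
    return pd.DataFrame(rows)


def reference_variant_spectrum() -> pd.DataFrame:
    """158 distinct variants with realistic marginal counts.

    Gene split 139 PKD1 / 19 PKD2; novel 80 (73/7); truncating 100 (85/15);
    de novo 7 (6/1); categories P 95 (82/13), LP 25 (21/4), VUS 30 (28/2),
    H 8 (8/0). Attributes are assigned independently to match the marginals.
    """
    spec = [("PKD1", 139, 73, 85, 6, {"P": 82, "LP": 21, "VUS": 28, "H": 8}),
            ("PKD2", 19, 7, 15, 1, {"P": 13, "LP": 4, "VUS": 2, "H": 0})]
    rows = []
    for gene, n, novel, trunc, dn, cats in spec:
        cat_list = [c for c, k in cats.items() for _ in range(k)]
        assert len(cat_list) == n
        for i in range(n):
            rows.append({"gene": gene, "novel": i < novel, "truncating": i < trunc,
                         "de_novo": i < dn, "category": cat_list[i]})
    return pd.DataFrame(rows)


def reference_family_history_records() -> pd.DataFrame:
    """193 probands with known family-history status (45 without).

    Among the 45 no-history probands: 16 PKD1-T, 10 PKD1-NT, 5 PKD2,
    14 negative. The 148 with a history are filled with the overall mix.
    """
    rows = []
    for label, k in (("ADPKD-PKD1-T", 16), ("ADPKD-PKD1-NT", 10),
                     ("ADPKD-PKD2", 5), ("negative", 14)):
        rows += [{"family_history": False, "nosology": label}] * k
    for label, k in (("ADPKD-PKD1-T", 76), ("ADPKD-PKD1-NT", 16),
                     ("ADPKD-PKD2", 15), ("negative", 41)):
        rows += [{"family_history": True, "nosology": label}] * k
    return pd.DataFrame(rows)


def reference_early_onset_records() -> pd.DataFrame:
    """30 early-onset probands (7 VEO, 23 EO), 7 of whom carry two variants."""
    rows = []
    for i in range(30):
        rows.append({"proband": f"EO{i:02d}",
                     "onset_class": "VEO" if i < 7 else "EO",
                     "n_variants": 2 if i < 7 else 1})
    return pd.DataFrame(rows)
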