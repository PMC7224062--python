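# Methods

This note documents the models, parameters and numerical choices behind
`pkdpanel`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## The synthetic duplicated locus

`generate_locus` builds a random gene plus `n_paralogs` paralogs at a requested
identity (default 6 paralogs at 0.98, the regime of the *PKD1* pseudogene
family). The paralogs are modelled as copies of a **common duplicated
ancestor**: a shared set of "family" divergent sites at which every paralog
carries the same non-gene base, plus private divergence per paralog. Three
quarters of the divergence budget is shared by default. The shared sites are
exactly the **anchor sites** — positions where the gene differs from every
paralog — and they are laid out on a jittered grid so that a primer-sized
window near any point contains one. This matters twice: it is what makes
anchored long-range PCR representable at all (independent-mutation paralogs
would almost never share divergent sites at 98% identity), and it concentrates
pseudogene contamination into a coherent allele at each shared site, the
failure mode masked alignment exists to control.

Homopolymer runs longer than ~8 bp are suppressed during generation so the
error model's run-length-doubling rate stays bounded.

`design_amplicons` tiles the exon territory with amplicons of fixed length
(default 900 bp at overlap ≥ 250 bp; the compact study locus uses 600/200),
then snaps each end so the primer window contains an anchor. Equimolar pooling
is modelled as equal per-base depth per amplicon; reads (default 200 bp,
emulating enzymatic fragmentation of long-range products) are placed uniformly
within their amplicon, so coverage ramps down linearly toward amplicon ends.

## Read error model

Substitutions occur at `substitution_rate` (default 0.002/bp), multiplied by
`gc_multiplier` (default 3) when the read midpoint lies in a window whose ±25 bp
GC fraction is ≥ 0.75. Homopolymer indels occur per overlapped reference run at
`r(L) = min(r0·2^(L−3), 0.2)` for run length L ≥ 3 (default `r0` = 0.002),
non-decreasing in L by construction. This is not a signal-level simulation of
semiconductor sequencing — no flowgrams, no quality values beyond a constant —
but it reproduces the two artifact classes that matter downstream: indel noise
concentrated in homopolymers and elevated miscalls in GC-rich context.

Pseudogene carry-over after anchored long-range PCR is not quantified anywhere
we know of; the generator's `contamination` default of 0.05 (reads drawn
uniformly from the paralogs) was chosen once as a level that makes the masking
benefit measurable while remaining clearly sub-threshold (5% < the 10% calling
threshold) on the masked reference. It is a free parameter of the simulation,
not an estimate from data.

## Alignment

The aligner is seed-and-extend: exact 16-mer seeds nominate diagonals, diagonals
within the band (default 16) are clustered, each cluster is scored ungapped
(match +2, mismatch −3) and re-scored by banded Smith–Waterman with linear gaps
(−5) when the ungapped score looks indel-degraded. The within-row deletion
chain of the banded DP is resolved exactly with a prefix-max trick, which is
valid only for linear (non-affine) gap penalties — an affine model would need
the usual three-matrix recurrence and is not warranted for near-exact amplicon
reads. Alignment to `N` always scores as a mismatch, so masked territory cannot
attract or anchor reads.

Reads are rejected when the best score falls below 0.6× the maximum attainable,
or when **mapping confidence** — 3× the score gap between the best and
second-best cluster, clipped to [0, 60] — falls below 20. Exact ties report the
leftmost location at confidence 0 and are therefore rejected by the default
filter. This two-best-hits definition is deliberately simple so the filter is
testable; it is not calibrated to any vendor's MAPQ.

## Variant calling

The pileup counts per-base alleles with strand splits; indels are left-aligned
to the canonical VCF representation (chop equal trailing bases, re-anchor
leftward). Depth at a position is the number of reads with an aligned base
there, so SNV allele counts always sum to depth; indel alleles are tabulated
separately at their anchor base.

Germline calling is threshold-based: a site is called when the alternate
fraction is ≥ `call_threshold` (default **0.10**, the defining constant of the
pipeline) at depth ≥ 20. Genotype is `het` in [0.20, 0.80], `hom` at ≥ 0.90,
and `ambiguous` with a `suspect_fp_unbalanced` flag in between — the unbalanced
zone is exactly where residual false positives and strong mosaics live. QC
flags (`homopolymer_context` at runs ≥ 5, `gc_rich_context` at window GC ≥
0.75, unbalanced allele fraction outside [0.30, 0.70]) are advisory and never
delete a call, mirroring a workflow in which every reported variant is
orthogonally confirmed.

The **mosaic scan** tests every covered target position: a site is a candidate
iff its strongest alternate allele has ≥ 10 supporting reads, VAF below
`max_vaf`, and a one-sided binomial tail `P(X ≥ alt | depth, error rate)` below
`alpha/n_scanned` (Bonferroni; conservative by choice — few true mosaics are
expected and diagnostic caution favours type-I control). The per-site error
rate (default 0.01) is doubled in homopolymer/GC-flagged context. `max_vaf`
defaults to the heterozygous-band floor (0.20), not to the 0.10 call threshold:
a 15.9% mosaic is both germline-callable (as an ambiguous, unbalanced call) and
a mosaic candidate, while a 7.1% mosaic is reachable only through the scan.
Both regimes appear in the worked examples.

**Allele dropout** is detected by genotyping each amplicon separately (read
provenance comes from simulated read names, or from span containment as a
fallback) and comparing overlapping amplicons: a site homozygous in one but
heterozygous in its neighbour is flagged, as is a het-VAF shift > 0.35. A
design without overlapping amplicons yields an explicit "detection not
possible" report rather than silent success.

## MLPA dosage

Dosage quotient of a probe = (sample peak / sample reference-probe median) ÷
(the same ratio in a control), averaged over controls; scale-invariant by
construction. Exon state thresholds are 0.70/1.30 (standard MLPA practice),
applied to the exon's probe-median; adjacent same-state exons merge into one
event and an event covering every gene exon sets the whole-gene flag. When an
exon has several probes and exactly one is aberrant, the exon is reported
normal with a "single-probe anomaly" note — isolated probe failures are not
rearrangements.

## Classification and pedigree logic

Classification is a reduced deterministic rule table, not the full 28-criterion
ACMG framework: truncating consequences (frameshift, nonsense, canonical
splice, large rearrangement) are always P; non-truncating variants pass through
an ordered list — common-allele guard (MAF > 0.01 → B unless a curated database
prior P/LP/H overrides), database prior, computational verdict (pathogenic-lean
and absent from populations → LP; benign-lean near the frequency cutoff → LB;
otherwise VUS), segregation in ≥ 2 affected relatives upgrading VUS → LP. Every
decision appends a rule identifier, so the path to any category can be
reconstructed from `applied_rules`. The sixth category H (hypomorphic) is
reachable only by reclassification of an *additional* non-truncating variant in
trans with a main P/LP allele in an early-onset (VEO/EO) proband — or inherited
from an unaffected parent beside a de novo main variant, where phase is
unknowable but the transmission pattern is equivalent.

Phase inference works on unphased carrier states. Unknown parental genotypes
are resolved both ways, the complete-data rule (maternal-only + paternal-only →
trans; both via one parent only → cis; absent from both parents → de novo) is
applied to every resolution, and a label is returned only on unanimity — a
family with an untested parent is `unknown`, never a guess. This matches a
brute-force enumeration over haplotype transmissions on all 3⁴ trio genotype
combinations (tested against an independent oracle). Family categories demand
their preconditions: biallelic needs same-gene trans or homozygosity; bilineal
needs different genes *and* transmission from both parental lines; a carrier
parent at sub-heterozygous VAF (< 0.20) is a mosaic parent; two same-gene
variants whose phase could not be established stay `unresolved`.

## Cohort statistics

Chi-square is computed as Σ(O−E)²/E with the χ² tail from scipy; Fisher's exact
test enumerates the 2×2 hypergeometric distribution and sums point
probabilities ≤ the observed one (two-sided). The selection rule follows small
diagnostic-cohort practice: Fisher whenever an **observed** cell is < 5
(configurable to the expected-count rule); a larger-than-2×2 table with a small
cell falls back to chi-square with a warning note, since the enumeration is
implemented for 2×2 only. One-way ANOVA uses the classical between/within
decomposition and reports group means so the severity ordering (truncating
*PKD1* earliest) is directly inspectable. All printed percentages round
half-up (one decimal in tables, integers in concordance metrics).

The cohort generator's default class mix (43.4 / 12.3 / 9.4 / 34.9 percent for
PKD1-T / PKD1-NT / PKD2 / negative) and onset effects (mean onset 26 / 37 / 46
years, diagnosis 39 / 46 / 55, ESRD 54 / 63 / 68, SD 8) encode the reported
severity gradient: truncating *PKD1* ~11 years earlier at onset than
non-truncating and ~20 years earlier than *PKD2*, with ESRD gaps of ~9 and ~14
years.

## Validation studies and their scale

The studies in `pkdpanel.experiments` (shared by the test suite and
`scripts/acceptance.py`) run on a compact 2 kb locus with one 500 bp exon and
two 600 bp amplicons overlapping by ≥ 200 bp — small enough that hundreds of
seeded replicates finish in minutes on one CPU while keeping six paralogs at
98% identity, anchored primers and an overlapping amplicon pair.

- **Germline sensitivity**: one random exonic het SNV per seed, depth 500, 5%
  contamination, 100 seeds; every injected variant must be called.
- **Masking benefit**: the same read sets aligned both to the masked gene and
  to a naive unmasked gene+paralog reference with calling over every position.
  On the naive reference, contamination reads pile onto the paralog copy at
  callable depth (5% × 500 ≈ 25×) and produce spurious calls at
  paralog-divergent sites; on the masked reference they stay below the 10%
  threshold on the gene. False calls are counted as any germline call that is
  not the injected variant.
- **Allele dropout**: depth 100, 100 seeds; the injected het variant loses its
  wild-type allele in one amplicon. The site is drawn from the central ±30 bp
  of the amplicon overlap: near the overlap edges the second amplicon has no
  informative fragments (its coverage ramps to zero), so cross-amplicon
  comparison is impossible by construction, not by detection failure.
- **MLPA recovery**: single-exon, two-exon, whole-gene deletions and a
  duplication at noise SD 0.05, 200 seeds each; an event counts only with the
  exact state and span (and whole-gene flag where applicable).
- **ANOVA power**: cohorts of ~50 probands per genotype class at the default
  onset effects, 200 seeds; rejection at α = 0.05 and recovery of the mean
  ordering.

What passing these studies shows — and what it does not: the generator
reproduces the *structure* of the diagnostic problem (paralogy, anchored
amplicons, threshold calling, dosage, trio logic), so the studies validate the
pipeline's logic and its failure-mode handling. They do not certify performance
on real semiconductor-sequencer data, whose error processes, amplicon dropout
patterns and pseudogene carry-over levels are richer than the model.

## Known limitations

- The aligner has no paired-end logic, no FM-index, and linear (not affine)
  gaps; it is built for near-exact 200 bp amplicon reads, not shotgun data.
- With contamination present, the mosaic scan flags paralog-divergent sites as
  candidates (they genuinely violate the error model); in diagnostic use such
  sites would be recognized and reviewed. The scan's type-I control is
  verified on contamination-free simulations.
- Copy-number events are observable only through the MLPA module; amplicon
  read depth is not used for CNV calling.
- Genotypes in pedigree logic are binary carrier states; read-backed phasing
  of nearby variants is out of scope.
- The classification table is a reduced, auditable approximation of clinical
  practice; it does not implement the full ACMG criterion set.
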