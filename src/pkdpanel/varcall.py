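"""Pileup construction and VAF-threshold variant calling.

The caller mirrors a deliberately conservative diagnostic pipeline:

* germline calls require a variant allele fraction (VAF) of at least 10%
  (``call_threshold``) and a minimum depth;
* heterozygous / homozygous genotype bands are explicit and anything between is
  reported as ``ambiguous`` with a suspect flag rather than silently dropped;
* allele-balance and sequence-context QC flags (unbalanced het VAF, homopolymer
  or GC-rich context) are advisory only — they never delete a call, mirroring a
  workflow in which every reported variant is orthogonally confirmed;
* a separate mosaic scan tests sub-threshold sites against the platform error
  rate with an exact one-sided binomial tail and Bonferroni correction;
* allele dropout is detected by comparing genotypes of the same site across
  overlapping amplicons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .maskalign import MaskedReference, ReadAlignment, _iter_cigar, encode
from .simlocus import AmpliconSet

BASES = "ACGT"

QC_UNBALANCED = "suspect_fp_unbalanced"
QC_HOMOPOLYMER = "homopolymer_context"
QC_GC_RICH = "gc_rich_context"
QC_DROPOUT = "allele_dropout_suspect"
QC_LOW_COVERAGE = "low_coverage"


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------


@dataclass
class Pileup:
    """Per-position allele counts with strand and local sequence context.

    ``base_counts``/``base_counts_fwd`` are 4 x L arrays (A, C, G, T rows).
    Indel alleles are left-aligned and keyed ``(pos, ref, alt)`` where ``pos``
    is the first affected reference base; their counts are ``[total, forward]``.
    ``depth[p]`` equals the number of reads with an aligned (M) base at ``p``,
    so the per-base allele counts always sum to the depth.
    """

    ref: MaskedReference
    base_counts: np.ndarray
    base_counts_fwd: np.ndarray
    depth: np.ndarray
    indels: dict[tuple[int, str, str], list[int]]
    homopolymer_len: np.ndarray
    gc_fraction: np.ndarray

    def ref_code(self, pos: int) -> int:
        return int(encode(self.ref.sequence[pos])[0])

    def alt_counts(self, pos: int) -> dict[str, int]:
        """Non-reference SNV allele counts at a position."""
        rc = self.ref_code(pos)
        out = {}
        for b in range(4):
            if b != rc and self.base_counts[b, pos] > 0:
                out[BASES[b]] = int(self.base_counts[b, pos])
        return out


def _context_arrays(ref: MaskedReference) -> tuple[np.ndarray, np.ndarray]:
    seq = ref.sequence
    n = len(seq)
    hp = np.zeros(n, dtype=np.int32)
    i = 0
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        hp[i:j] = j - i
        i = j
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.float64)
    cs = np.concatenate([[0.0], np.cumsum(is_gc)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - 25)
    hi = np.minimum(n, idx + 26)
    frac = (cs[hi] - cs[lo]) / (hi - lo)
    return hp, frac


def left_align_indel(ref_seq: str, pos: int, ref_allele: str, alt_allele: str
                     ) -> tuple[int, str, str]:
    """Left-align an indel against the reference (VCF convention).

    ``pos`` is the 0-based first reference base of ``ref_allele``. Pure
    insertions/deletions are shifted left while the flanking base allows it.
    """
    # canonical left-shift: chop equal trailing bases, re-anchoring on the
    # reference base to the left whenever an allele would become empty
    while True:
        if (ref_allele and alt_allele and ref_allele[-1] == alt_allele[-1]
                and (len(ref_allele) > 1 or len(alt_allele) > 1)):
            ref_allele, alt_allele = ref_allele[:-1], alt_allele[:-1]
            if (not ref_allele or not alt_allele) and pos > 0:
                pos -= 1
                b = ref_seq[pos]
                ref_allele, alt_allele = b + ref_allele, b + alt_allele
            continue
        break
    # trim shared leading bases of a multi-base substitution
    while len(ref_allele) > 1 and len(alt_allele) > 1 and ref_allele[0] == alt_allele[0]:
        ref_allele, alt_allele = ref_allele[1:], alt_allele[1:]
        pos += 1
    return pos, ref_allele, alt_allele


def build_pileup(alignments: Sequence[ReadAlignment], ref: MaskedReference) -> Pileup:
    """Accumulate alignments into a pileup (counts, strands, indels, context)."""
    n = ref.length
    counts = np.zeros((4, n), dtype=np.int32)
    counts_fwd = np.zeros((4, n), dtype=np.int32)
    indels: dict[tuple[int, str, str], list[int]] = {}
    for a in alignments:
        codes = encode(a.sequence)
        rp = a.ref_start
        qp = 0
        fwd = a.strand == "+"
        for ln, op in _iter_cigar(a.cigar):
            if op == "S":
                qp += ln
            elif op == "M":
                window = codes[qp:qp + ln]
                pos = np.arange(rp, rp + ln)
                ok = window < 4
                if ok.all():
                    np.add.at(counts, (window, pos), 1)
                    if fwd:
                        np.add.at(counts_fwd, (window, pos), 1)
                else:
                    np.add.at(counts, (window[ok], pos[ok]), 1)
                    if fwd:
                        np.add.at(counts_fwd, (window[ok], pos[ok]), 1)
                rp += ln
                qp += ln
            elif op == "D":
                ref_allele = ref.sequence[rp - 1:rp + ln]
                alt_allele = ref.sequence[rp - 1]
                key = left_align_indel(ref.sequence, rp - 1, ref_allele, alt_allele)
                rec = indels.setdefault(key, [0, 0])
                rec[0] += 1
                rec[1] += int(fwd)
                rp += ln
            elif op == "I":
                inserted = a.sequence[qp:qp + ln]
                ref_allele = ref.sequence[rp - 1] if rp > 0 else ""
                alt_allele = ref_allele + inserted
                key = left_align_indel(ref.sequence, rp - 1, ref_allele, alt_allele)
                rec = indels.setdefault(key, [0, 0])
                rec[0] += 1
                rec[1] += int(fwd)
                qp += ln
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")
    hp, gc = _context_arrays(ref)
    return Pileup(ref=ref, base_counts=counts, base_counts_fwd=counts_fwd,
                  depth=counts.sum(axis=0), indels=indels,
                  homopolymer_len=hp, gc_fraction=gc)


# ---------------------------------------------------------------------------
# Variant calls
# ---------------------------------------------------------------------------


@dataclass
class VariantCall:
    """A called site with VAF, genotype state and advisory QC flags."""

    pos: int  # 0-based
    ref: str
    alt: str
    alt_depth: int
    depth: int
    genotype: str  # het | hom | ambiguous | mosaic-candidate | none
    qc_flags: set[str] = field(default_factory=set)
    p_value: float | None = None
    amplicon: str | None = None
    ref_name: str = "locus"

    @property
    def vaf(self) -> float:
        return self.alt_depth / self.depth if self.depth else 0.0

    @property
    def vaf_percent(self) -> float:
        """VAF as a percentage rounded half-up to one decimal."""
        return round_half_up(100.0 * self.vaf, 1)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (the convention used in all printed percentages)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def call_germline(
    pileup: Pileup,
    call_threshold: float = 0.10,
    het_band: tuple[float, float] = (0.20, 0.80),
    hom_threshold: float = 0.90,
    min_depth: int = 20,
) -> list[VariantCall]:
    """Germline calls at every target site with VAF >= ``call_threshold``.

    Genotype is ``het`` inside ``het_band``, ``hom`` at or above
    ``hom_threshold`` and ``ambiguous`` (with an unbalanced-allele suspect
    flag) in between — the unbalanced zone is exactly where both residual
    false positives and genuine mosaics above the call threshold live.
    """
    if not (call_threshold < het_band[0] <= het_band[1] < hom_threshold):
        raise ValueError("thresholds must satisfy call < het_low <= het_high < hom")
    calls: list[VariantCall] = []
    tmask = pileup.ref.is_target()
    depth = pileup.depth
    counts = pileup.base_counts
    ref_codes = encode(pileup.ref.sequence)
    eligible = np.flatnonzero(tmask & (depth >= min_depth))
    # vectorized pre-filter: any non-ref count above threshold
    for pos in eligible:
        d = int(depth[pos])
        rc = int(ref_codes[pos])
        for b in range(4):
            if b == rc:
                continue
            c = int(counts[b, pos])
            if c == 0 or c / d < call_threshold:
                continue
            calls.append(_genotype_call(int(pos), pileup.ref.sequence[pos], BASES[b],
                                        c, d, het_band, hom_threshold,
                                        pileup.ref.source_name))
    for (pos, ref_a, alt_a), (cnt, _fwd) in pileup.indels.items():
        d = int(depth[pos]) if pos < len(depth) else 0
        if d < min_depth or not tmask[pos]:
            continue
        if cnt / d >= call_threshold:
            calls.append(_genotype_call(pos, ref_a, alt_a, cnt, d, het_band,
                                        hom_threshold, pileup.ref.source_name))
    calls.sort(key=lambda c: (c.pos, c.alt))
    return calls


def _genotype_call(pos, ref_a, alt_a, alt_depth, depth, het_band, hom_threshold,
                   ref_name) -> VariantCall:
    vaf = alt_depth / depth
    if het_band[0] <= vaf <= het_band[1]:
        gt = "het"
        flags: set[str] = set()
    elif vaf >= hom_threshold:
        gt = "hom"
        flags = set()
    else:
        gt = "ambiguous"
        flags = {QC_UNBALANCED}
    return VariantCall(pos=pos, ref=ref_a, alt=alt_a, alt_depth=alt_depth,
                       depth=depth, genotype=gt, qc_flags=flags, ref_name=ref_name)


def qc_allele_balance(call: VariantCall, pileup: Pileup,
                      balance_band: tuple[float, float] = (0.30, 0.70),
                      homopolymer_min: int = 5,
                      gc_min: float = 0.75) -> VariantCall:
    """Attach advisory context flags to a call; never removes it.

    Heterozygous (or ambiguous) calls whose VAF falls outside ``balance_band``
    are flagged as suspect false positives; homopolymer runs >= 5 and GC-rich
    windows are flagged because that is where the platform's miscalls cluster.
    """
    flags = set(call.qc_flags)
    if call.genotype in ("het", "ambiguous") and not (
            balance_band[0] <= call.vaf <= balance_band[1]):
        flags.add(QC_UNBALANCED)
    if pileup.homopolymer_len[call.pos] >= homopolymer_min:
        flags.add(QC_HOMOPOLYMER)
    if pileup.gc_fraction[call.pos] >= gc_min:
        flags.add(QC_GC_RICH)
    return replace(call, qc_flags=flags)


# ---------------------------------------------------------------------------
# Mosaic scan
# ---------------------------------------------------------------------------


def scan_mosaic(
    pileup: Pileup,
    error_rate: float = 0.01,
    germline_threshold: float = 0.10,
    alpha: float = 0.05,
    min_alt: int = 10,
    max_vaf: float = 0.20,
    context_rate_multiplier: float = 2.0,
) -> list[VariantCall]:
    """Scan for sub-heterozygous mosaic candidates.

    A site is a candidate iff its strongest alternate allele has VAF below
    ``max_vaf`` (the heterozygous band floor — everything below it is
    sub-heterozygous, including the zone under the germline ``call_threshold``
    where no call is made at all), at least ``min_alt`` supporting reads, and a
    one-sided binomial tail ``P(X >= alt | depth, site error rate)`` below
    ``alpha`` after Bonferroni correction over all scanned positions. The site
    error rate is doubled in homopolymer/GC-rich context. Raw p-values are
    recorded on the candidates.
    """
    if not (0.0 < error_rate < germline_threshold):
        raise ValueError("error_rate must lie in (0, germline_threshold)")
    tmask = pileup.ref.is_target()
    depth = pileup.depth
    scanned = np.flatnonzero(tmask & (depth > 0))
    n_tests = max(1, scanned.size)
    cutoff = alpha / n_tests
    out: list[VariantCall] = []

    def consider(pos: int, ref_a: str, alt_a: str, alt: int, d: int) -> None:
        if alt < min_alt or d == 0:
            return
        vaf = alt / d
        if vaf >= max_vaf:
            return
        rate = error_rate
        if (pileup.homopolymer_len[pos] >= 5) or (pileup.gc_fraction[pos] >= 0.75):
            rate = min(0.99, rate * context_rate_multiplier)
        p = float(stats.binom.sf(alt - 1, d, rate))
        if p < cutoff:
            out.append(VariantCall(pos=int(pos), ref=ref_a, alt=alt_a, alt_depth=alt,
                                   depth=d, genotype="mosaic-candidate",
                                   p_value=p, ref_name=pileup.ref.source_name))

    counts = pileup.base_counts
    ref_codes = encode(pileup.ref.sequence)
    for pos in scanned:
        rc = int(ref_codes[pos])
        d = int(depth[pos])
        best_b, best_c = -1, 0
        for b in range(4):
            if b != rc and counts[b, pos] > best_c:
                best_b, best_c = b, int(counts[b, pos])
        if best_b >= 0:
            consider(int(pos), pileup.ref.sequence[pos], BASES[best_b], best_c, d)
    for (pos, ref_a, alt_a), (cnt, _fwd) in pileup.indels.items():
        if 0 <= pos < len(depth) and tmask[pos]:
            consider(pos, ref_a, alt_a, cnt, int(depth[pos]))
    out.sort(key=lambda c: c.pos)
    return out


# ---------------------------------------------------------------------------
# Allele dropout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DropoutReport:
    """Cross-amplicon genotype discordances suggesting allele dropout."""

    possible: bool
    reason: str = ""
    events: tuple[dict, ...] = ()


def amplicon_of_read(read_id: str) -> str | None:
    """Amplicon provenance encoded in simulated read names (``amp|serial|origin``)."""
    if "|" in read_id:
        return read_id.split("|", 1)[0]
    return None


def detect_allele_dropout(
    alignments: Sequence[ReadAlignment],
    ref: MaskedReference,
    amplicons: AmpliconSet,
    call_kwargs: dict | None = None,
    vaf_shift: float = 0.35,
) -> DropoutReport:
    """Compare per-amplicon genotypes at shared sites across overlapping amplicons.

    A site homozygous in one amplicon but heterozygous in an overlapping one is
    flagged as an allele-dropout suspect (the classic signature of a variant
    under a primer site); independently, a het-site VAF shift larger than
    ``vaf_shift`` between overlapping amplicons is reported. When the amplicon
    design has no overlapping pair the report says detection is not possible
    rather than silently succeeding.
    """
    pairs = amplicons.overlaps
    if not pairs:
        return DropoutReport(False, "dropout detection not possible: no overlapping amplicons")
    kw = dict(call_kwargs or {})
    by_amp: dict[str, list[ReadAlignment]] = {}
    for a in alignments:
        amp = amplicon_of_read(a.read_id)
        if amp is None:
            amp = _assign_by_span(a, amplicons)
        if amp is not None:
            by_amp.setdefault(amp, []).append(a)
    calls_by_amp: dict[str, dict[tuple[int, str, str], VariantCall]] = {}
    pileups: dict[str, Pileup] = {}
    for amp, alns in by_amp.items():
        pu = build_pileup(alns, ref)
        pileups[amp] = pu
        calls_by_amp[amp] = {(c.pos, c.ref, c.alt): c for c in call_germline(pu, **kw)}
    events: list[dict] = []
    for a_name, b_name in pairs:
        for first, second in ((a_name, b_name), (b_name, a_name)):
            for key, call in calls_by_amp.get(first, {}).items():
                other = calls_by_amp.get(second, {}).get(key)
                if call.genotype == "hom" and other is not None and other.genotype == "het":
                    events.append({
                        "pos": key[0], "ref": key[1], "alt": key[2],
                        "hom_amplicon": first, "het_amplicon": second,
                        "vaf_hom": call.vaf, "vaf_het": other.vaf,
                        "kind": "hom_vs_het",
                    })
                elif (other is not None and call.genotype == "het"
                      and other.genotype == "het"
                      and abs(call.vaf - other.vaf) > vaf_shift
                      and first < second):
                    events.append({
                        "pos": key[0], "ref": key[1], "alt": key[2],
                        "hom_amplicon": None,
                        "amplicons": (first, second),
                        "vaf_shift": abs(call.vaf - other.vaf),
                        "kind": "vaf_shift",
                    })
    return DropoutReport(True, events=tuple(events))


def _assign_by_span(a: ReadAlignment, amplicons: AmpliconSet) -> str | None:
    """Fallback amplicon assignment: smallest amplicon containing the span."""
    best = None
    for amp in amplicons.amplicons:
        s, e = amp.interval
        if s <= a.ref_start and a.ref_end <= e:
            if best is None or (e - s) < (best[1] - best[0]):
                best = (s, e, amp.name)
    return best[2] if best else None


def flag_dropout_suspects(calls: list[VariantCall], report: DropoutReport) -> list[VariantCall]:
    """Mark pooled calls whose site appears in a dropout report."""
    flagged_sites = {(e["pos"], e["ref"], e["alt"]) for e in report.events
                     if e["kind"] == "hom_vs_het"}
    out = []
    for c in calls:
        if (c.pos, c.ref, c.alt) in flagged_sites:
            c = replace(c, qc_flags=set(c.qc_flags) | {QC_DROPOUT})
        out.append(c)
    return out
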