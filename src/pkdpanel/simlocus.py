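"""Synthetic duplicated-locus simulator.

Generates every input the diagnostic pipeline needs: a gene embedded in a family
of high-identity paralogs (pseudogenes), long-range-PCR amplicons whose primers
sit on the rare positions where the gene differs from *every* paralog, fragmented
amplicon reads with a semiconductor-sequencing style error profile (homopolymer
indels, elevated miscall rate in GC-rich windows), germline / mosaic / allele-
dropout variant scenarios, MLPA probe peak tables, and cohorts with genotype-
dependent onset, diagnosis, and end-stage renal disease (ESRD) ages.

Paralog model
-------------
The paralogs are modelled as copies of a common duplicated ancestor: a shared set
of "family" divergent sites at which every paralog carries the same non-gene base
(these are the anchor sites usable for locus-specific primers), plus a small
amount of private divergence per paralog. This mirrors the structure of real
pseudogene families, where the copies resemble each other more than the parent
gene, and is what makes anchored long-range PCR possible at all.

All randomness flows through :class:`numpy.random.Generator` seeded explicitly;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import Interval, contains, overlaps, validate_intervals

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGTN", "TGCAN")

#: VAF below which the pipeline's germline caller refuses to call (see varcall).
GERMLINE_THRESHOLD = 0.10


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def _mutate_base(rng: np.random.Generator, code: int) -> int:
    """A uniformly random base different from ``code``."""
    return (code + int(rng.integers(1, 4))) % 4


# ---------------------------------------------------------------------------
# Locus
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticLocus:
    """A gene plus a family of high-identity paralogs.

    ``anchor_sites`` are the positions where the gene differs from every paralog;
    ``exon_intervals`` are disjoint, sorted half-open intervals on the gene.
    """

    gene_sequence: str
    paralogs: tuple[str, ...]
    paralog_identity: float
    anchor_sites: tuple[int, ...]
    exon_intervals: tuple[Interval, ...]
    seed: int

    def __post_init__(self) -> None:
        n = len(self.gene_sequence)
        for p in self.paralogs:
            if len(p) != n:
                raise ValueError("paralog length differs from gene length")
        validate_intervals(self.exon_intervals, n)
        for a in self.anchor_sites:
            for p in self.paralogs:
                if p[a] == self.gene_sequence[a]:
                    raise ValueError(f"anchor site {a} does not differ in every paralog")

    @property
    def length(self) -> int:
        return len(self.gene_sequence)

    def identity_to(self, paralog_index: int) -> float:
        g = np.frombuffer(self.gene_sequence.encode(), dtype=np.uint8)
        p = np.frombuffer(self.paralogs[paralog_index].encode(), dtype=np.uint8)
        return float(np.mean(g == p))


def generate_locus(
    seed: int,
    n_paralogs: int = 6,
    identity: float = 0.98,
    length: int = 10_000,
    n_anchors: int | None = None,
    n_exons: int = 6,
    exon_length: int = 300,
) -> SyntheticLocus:
    """Generate a gene plus ``n_paralogs`` paralogs at the requested identity.

    ``n_anchors`` controls how many shared (family) divergent sites exist; these
    are exactly the anchor positions. By default three quarters of the total
    divergence budget is shared, the rest private per paralog. Deterministic for
    a fixed seed.
    """
    if length < 2000:
        raise ValueError("length must be >= 2000")
    if not (0.8 <= identity < 1.0):
        raise ValueError("identity must be in [0.8, 1): identical paralogs leave no anchors")
    if n_paralogs < 0:
        raise ValueError("n_paralogs must be >= 0")

    rng = np.random.default_rng(seed)
    gene = _random_seq(rng, length)
    # collapse homopolymer runs > 8 so that error-model rates stay bounded
    for i in range(3, length):
        if gene[i - 3] == gene[i - 2] == gene[i - 1] == gene[i] and rng.random() < 0.5:
            gene[i] = _mutate_base(rng, int(gene[i]))

    n_divergent = int(round((1.0 - identity) * length))
    if n_anchors is None:
        n_anchors = max(4, int(round(0.75 * n_divergent)))
    if n_anchors < 2:
        raise ValueError("need at least 2 anchor sites")
    if n_paralogs > 0 and n_anchors > n_divergent:
        raise ValueError("n_anchors exceeds the divergence budget implied by identity")
    n_private = max(0, n_divergent - n_anchors)

    def _spread_sites(k: int) -> np.ndarray:
        # roughly even spacing with jitter, so every primer-sized window within
        # ~2 spacings of any point contains a site
        spacing = length / k
        jitter = rng.random(k) * spacing * 0.6
        sites = np.unique((np.arange(k) * spacing + jitter).astype(int))
        return np.clip(sites, 0, length - 1)

    anchors: tuple[int, ...] = ()
    paralogs: list[str] = []
    if n_paralogs > 0:
        shared = _spread_sites(n_anchors)
        shared_set = set(int(x) for x in shared)
        ancestor_alt = {int(s): _mutate_base(rng, int(gene[s])) for s in shared}
        anchors = tuple(int(s) for s in shared)
        free = np.array([i for i in range(length) if i not in shared_set])
        for _ in range(n_paralogs):
            par = gene.copy()
            for s, alt in ancestor_alt.items():
                par[s] = alt
            if n_private:
                priv = rng.choice(free, size=n_private, replace=False)
                for p in priv:
                    par[p] = _mutate_base(rng, int(par[p]))
            paralogs.append(_codes_to_str(par))
    else:
        # single-copy degenerate case: keep nominal anchors for primer placement
        anchors = tuple(int(x) for x in _spread_sites(n_anchors))

    # evenly spaced exons with a margin at each end
    margin = 200
    usable = length - 2 * margin
    if n_exons * exon_length > usable:
        raise ValueError("exons do not fit: reduce n_exons or exon_length")
    gap = (usable - n_exons * exon_length) // max(1, n_exons - 1) if n_exons > 1 else 0
    exons = []
    pos = margin
    for _ in range(n_exons):
        exons.append((pos, pos + exon_length))
        pos += exon_length + gap

    return SyntheticLocus(
        gene_sequence=_codes_to_str(gene),
        paralogs=tuple(paralogs),
        paralog_identity=identity,
        anchor_sites=anchors,
        exon_intervals=tuple(exons),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Amplicons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Amplicon:
    name: str
    interval: Interval
    forward_primer: Interval
    reverse_primer: Interval


@dataclass(frozen=True)
class AmpliconSet:
    """Long-range PCR amplicons tiling the exons, anchored on paralog mismatches."""

    amplicons: tuple[Amplicon, ...]

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.amplicons]

    def __getitem__(self, name: str) -> Amplicon:
        for a in self.amplicons:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def overlaps(self) -> list[tuple[str, str]]:
        out = []
        amps = self.amplicons
        for i in range(len(amps)):
            for j in range(i + 1, len(amps)):
                if overlaps(amps[i].interval, amps[j].interval):
                    out.append((amps[i].name, amps[j].name))
        return out

    def covering(self, pos: int) -> list[str]:
        return [a.name for a in self.amplicons if contains(a.interval, pos)]


def design_amplicons(
    locus: SyntheticLocus,
    amplicon_length: int = 1200,
    min_overlap: int = 250,
    primer_length: int = 25,
) -> AmpliconSet:
    """Tile the exon territory with overlapping amplicons anchored on anchor sites.

    Each primer interval is snapped so that it contains at least one anchor site
    (the locus-specific mismatch the primer exploits). Consecutive amplicons
    overlap by at least ``min_overlap`` so that allele dropout in one amplicon is
    detectable from its neighbour.
    """
    anchors = np.asarray(locus.anchor_sites)
    if anchors.size == 0:
        raise ValueError("locus has no anchor sites; cannot place anchored primers")
    lo = min(s for s, _ in locus.exon_intervals)
    hi = max(e for _, e in locus.exon_intervals)

    def snap_left(target: int) -> int:
        """Forward-primer start: an anchor at/left of target (first anchor if none)."""
        cand = anchors[anchors <= target]
        a = int(cand[-1]) if cand.size else int(anchors[0])
        return max(0, min(a, locus.length - primer_length))

    def snap_right(target: int) -> int:
        """Reverse-primer end (exclusive): an anchor at/right of target - primer."""
        cand = anchors[anchors >= target - primer_length]
        a = int(cand[0]) if cand.size else int(anchors[-1])
        return min(locus.length, max(a + 1, primer_length))

    span = hi - lo
    step_len = max(1, amplicon_length - min_overlap)
    n_amp = max(2, int(np.ceil((span - min_overlap) / step_len)))
    total = n_amp * amplicon_length - (n_amp - 1) * min_overlap
    start0 = max(0, lo - max(0, total - span) // 2)
    amps: list[Amplicon] = []
    for i in range(n_amp):
        want_start = start0 + i * step_len
        want_end = min(locus.length, want_start + amplicon_length)
        start = snap_left(max(0, want_start))
        end = snap_right(want_end)
        fwd = (start, start + primer_length)
        rev = (end - primer_length, end)
        amps.append(Amplicon(f"amp{i + 1:02d}", (start, end), fwd, rev))

    aset = AmpliconSet(tuple(amps))
    _validate_amplicons(aset, locus)
    return aset


def _validate_amplicons(aset: AmpliconSet, locus: SyntheticLocus) -> None:
    anchors = set(locus.anchor_sites)
    covered = []
    for a in aset.amplicons:
        covered.append(a.interval)
        for primer in (a.forward_primer, a.reverse_primer):
            if not any(primer[0] <= x < primer[1] for x in anchors):
                raise ValueError(f"{a.name}: primer {primer} contains no anchor site")
    from .intervals import merge_intervals

    merged = merge_intervals(covered)
    for ex in locus.exon_intervals:
        if not any(s <= ex[0] and ex[1] <= e for s, e in merged):
            raise ValueError(f"exon {ex} not covered by amplicons")
    if len(aset.amplicons) > 1 and not aset.overlaps:
        raise ValueError("no overlapping amplicon pair; dropout detection impossible")


# ---------------------------------------------------------------------------
# Variant scenarios and the read error model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantScenario:
    """A variant to inject into simulated reads.

    ``zygosity`` is one of ``het``, ``hom``, ``mosaic``. For mosaics,
    ``mosaic_fraction`` is the expected fraction of reads carrying the variant
    at the site (sub-heterozygous by definition). ``dropout`` marks the
    wild-type allele as failing to amplify in ``dropout_amplicon``, so that
    amplicon emits reads from the variant haplotype only.
    """

    position: int
    ref: str
    alt: str
    zygosity: str = "het"
    mosaic_fraction: float | None = None
    dropout: bool = False
    dropout_amplicon: str | None = None
    truth_category: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.zygosity not in ("het", "hom", "mosaic"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.zygosity == "mosaic":
            if self.mosaic_fraction is None or not (0.0 < self.mosaic_fraction < 0.5):
                raise ValueError("mosaic scenarios need mosaic_fraction in (0, 0.5)")
        elif self.mosaic_fraction is not None:
            raise ValueError("mosaic_fraction only allowed for zygosity='mosaic'")
        if self.dropout and not self.dropout_amplicon:
            raise ValueError("dropout scenarios must name the affected amplicon")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")

    @property
    def label(self) -> str:
        return self.name or f"{self.position}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class ReadErrorModel:
    """Semiconductor-sequencing style error profile.

    Homopolymer indel rate follows ``r(L) = min(r0 * 2**(L - 3), cap)`` for run
    length ``L >= 3`` and is zero below; it is non-decreasing in ``L`` by
    construction. Substitutions in GC-rich windows (fraction >= ``gc_threshold``
    in a +/-25 bp window) are multiplied by ``gc_multiplier``.
    """

    substitution_rate: float = 0.002
    homopolymer_rate0: float = 0.002
    homopolymer_cap: float = 0.2
    gc_multiplier: float = 3.0
    gc_threshold: float = 0.75
    read_length: int = 200

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.homopolymer_rate0, self.homopolymer_cap):
            if not (0.0 <= r < 1.0):
                raise ValueError("error rates must be in [0, 1)")
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")

    def homopolymer_rate(self, run_length: int) -> float:
        if run_length < 3:
            return 0.0
        return min(self.homopolymer_rate0 * 2.0 ** (run_length - 3), self.homopolymer_cap)

    @classmethod
    def error_free(cls, read_length: int = 200) -> "ReadErrorModel":
        return cls(substitution_rate=0.0, homopolymer_rate0=0.0, homopolymer_cap=0.0,
                   read_length=read_length)


@dataclass(frozen=True)
class SimulatedRead:
    """A single simulated read with its provenance.

    ``name`` encodes ``amplicon|serial|origin`` so downstream per-amplicon
    analyses (allele dropout) know the amplicon of origin without re-inference.
    """

    name: str
    sequence: str
    amplicon: str
    origin: str  # "gene" or "paralogK"
    strand: str  # "+" or "-"

    @property
    def quality(self) -> str:
        return "I" * len(self.sequence)


def homopolymer_runs(seq: str, min_len: int = 3) -> list[tuple[int, int]]:
    """Maximal homopolymer runs of length >= min_len, as (start, end) intervals."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs


def gc_rich_mask(seq: str, window: int = 25, threshold: float = 0.75) -> np.ndarray:
    """Boolean mask of positions whose +/-window GC fraction is >= threshold."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.float64)
    cs = np.concatenate([[0.0], np.cumsum(is_gc)])
    n = len(seq)
    idx = np.arange(n)
    lo = np.maximum(0, idx - window)
    hi = np.minimum(n, idx + window + 1)
    frac = (cs[hi] - cs[lo]) / (hi - lo)
    return frac >= threshold


def _apply_variant_to_window(
    gene: str, start: int, read_len: int, variants: list[VariantScenario]
) -> str:
    """Extract a read window from the gene with the given variants spliced in.

    The read keeps its nominal length by extending (or trimming) at the 3' end
    when indels change the window's span.
    """
    # splice variants in ascending position order
    pieces: list[str] = []
    cursor = start
    end = start + read_len + sum(max(0, len(v.ref) - len(v.alt)) for v in variants) + 8
    end = min(end, len(gene))
    for v in sorted(variants, key=lambda x: x.position):
        if v.position < cursor:
            continue
        pieces.append(gene[cursor:v.position])
        pieces.append(v.alt)
        cursor = v.position + len(v.ref)
    pieces.append(gene[cursor:end])
    out = "".join(pieces)
    return out[:read_len]


def simulate_reads(
    locus: SyntheticLocus,
    amplicons: AmpliconSet,
    scenarios: Sequence[VariantScenario],
    depth: float,
    error_model: ReadErrorModel | None = None,
    contamination: float = 0.05,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Simulate fragmented amplicon reads.

    Equimolar pooling of amplicons means equal molecule counts per amplicon and
    hence per-base depth ``depth`` on each; the read count per amplicon is
    ``depth * len(amplicon) / read_length`` (rounded). A ``contamination``
    fraction of reads is drawn from a uniformly chosen paralog instead of the
    gene, emulating residual pseudogene amplification.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0.0 <= contamination < 1.0):
        raise ValueError("contamination must be in [0, 1)")
    em = error_model or ReadErrorModel()
    rng = np.random.default_rng(seed)

    for sc in scenarios:
        if not amplicons.covering(sc.position):
            raise ValueError(f"scenario {sc.label} lies outside every amplicon")
        if sc.dropout and sc.dropout_amplicon not in amplicons.names:
            raise ValueError(f"scenario {sc.label}: unknown amplicon {sc.dropout_amplicon}")

    gene = locus.gene_sequence
    hp_runs = homopolymer_runs(gene)
    run_of_pos: dict[int, tuple[int, int]] = {}
    for s, e in hp_runs:
        for p in range(s, e):
            run_of_pos[p] = (s, e)
    gc_mask = gc_rich_mask(gene, threshold=em.gc_threshold) if em.substitution_rate > 0 else None

    hom_vars = [v for v in scenarios if v.zygosity == "hom"]
    het_vars = [v for v in scenarios if v.zygosity == "het"]
    mos_vars = [v for v in scenarios if v.zygosity == "mosaic"]

    reads: list[SimulatedRead] = []
    rl = em.read_length
    for amp in amplicons.amplicons:
        a_start, a_end = amp.interval
        a_len = a_end - a_start
        eff_rl = min(rl, a_len)
        n_reads = max(1, int(round(depth * a_len / eff_rl)))
        dropout_here = [v for v in scenarios if v.dropout and v.dropout_amplicon == amp.name]
        starts = rng.integers(a_start, max(a_start + 1, a_end - eff_rl + 1), size=n_reads)
        is_contam = rng.random(n_reads) < contamination if (contamination > 0 and locus.paralogs) else np.zeros(n_reads, bool)
        hap_choice = rng.random(n_reads) < 0.5
        strand_rev = rng.random(n_reads) < 0.5
        for i in range(n_reads):
            start = int(starts[i])
            window = (start, start + eff_rl)
            if is_contam[i]:
                k = int(rng.integers(0, len(locus.paralogs)))
                seq = locus.paralogs[k][window[0]:window[1]]
                origin = f"paralog{k + 1}"
            else:
                origin = "gene"
                carried: list[VariantScenario] = []
                for v in hom_vars:
                    if window[0] <= v.position < window[1]:
                        carried.append(v)
                # het variants ride haplotype 2; a dropout amplicon emits the
                # variant haplotype only (wild-type allele failed to amplify)
                on_hap2 = bool(hap_choice[i]) or bool(dropout_here)
                if on_hap2:
                    for v in het_vars:
                        if window[0] <= v.position < window[1]:
                            carried.append(v)
                for v in mos_vars:
                    if window[0] <= v.position < window[1] and rng.random() < v.mosaic_fraction:
                        carried.append(v)
                if carried:
                    seq = _apply_variant_to_window(gene, start, eff_rl, carried)
                else:
                    seq = gene[window[0]:window[1]]
            seq = _apply_errors(seq, start, em, rng, run_of_pos, gc_mask)
            strand = "-" if strand_rev[i] else "+"
            if strand == "-":
                seq = revcomp(seq)
            reads.append(SimulatedRead(
                name=f"{amp.name}|{len(reads)}|{origin}",
                sequence=seq, amplicon=amp.name, origin=origin, strand=strand,
            ))
    return reads


def _apply_errors(
    seq: str,
    ref_start: int,
    em: ReadErrorModel,
    rng: np.random.Generator,
    run_of_pos: dict[int, tuple[int, int]],
    gc_mask: np.ndarray | None,
) -> str:
    """Inject substitution and homopolymer-indel errors into one read."""
    n = len(seq)
    out = seq
    # substitutions
    if em.substitution_rate > 0:
        rate = em.substitution_rate
        if gc_mask is not None:
            mid = min(len(gc_mask) - 1, ref_start + n // 2)
            if gc_mask[mid]:
                rate = min(0.99, rate * em.gc_multiplier)
        k = rng.binomial(n, rate)
        if k:
            chars = list(out)
            for p in rng.integers(0, n, size=k):
                c = chars[int(p)]
                if c in _BASE_TO_CODE:
                    chars[int(p)] = BASES[_mutate_base(rng, _BASE_TO_CODE[c])]
            out = "".join(chars)
    # homopolymer indels (evaluated on reference runs overlapped by the read)
    if em.homopolymer_rate0 > 0:
        seen: set[tuple[int, int]] = set()
        edits: list[tuple[int, int]] = []  # (read offset, +1 ins / -1 del)
        for p in range(ref_start, ref_start + n):
            run = run_of_pos.get(p)
            if run and run not in seen:
                seen.add(run)
                if rng.random() < em.homopolymer_rate(run[1] - run[0]):
                    off = max(0, min(n - 1, run[0] - ref_start))
                    edits.append((off, 1 if rng.random() < 0.5 else -1))
        if edits:
            chars = list(out)
            for off, kind in sorted(edits, reverse=True):
                if kind == 1:
                    chars.insert(off, chars[off])
                else:
                    del chars[off]
            out = "".join(chars)[:n]
    return out


# ---------------------------------------------------------------------------
# MLPA peak simulation
# ---------------------------------------------------------------------------


def simulate_mlpa(
    copy_state: dict[str, int],
    probes: Sequence[tuple[str, str, bool]],
    noise_sd: float = 0.05,
    seed: int = 0,
    sample: str = "sample",
    base_peak: float = 1000.0,
) -> pd.DataFrame:
    """Simulate an MLPA probe peak table for one sample.

    ``probes`` is a list of ``(probe_id, exon_label, is_reference)``; reference
    probes always behave as copy 2. Expected peak is proportional to
    ``copy_number / 2`` with multiplicative Gaussian noise of SD ``noise_sd``.
    Returns a tidy frame with columns sample, probe, exon, peak.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    exon_labels = {exon for _, exon, is_ref in probes if not is_ref}
    for exon in copy_state:
        if exon not in exon_labels:
            raise ValueError(f"unknown exon {exon!r} in copy_state")
    for exon, c in copy_state.items():
        if c not in (0, 1, 2, 3):
            raise ValueError(f"copy number {c} for exon {exon!r} not in {{0,1,2,3}}")
    rng = np.random.default_rng(seed)
    rows = []
    for probe_id, exon, is_ref in probes:
        copy = 2 if is_ref else copy_state.get(exon, 2)
        noise = 1.0 + rng.normal(0.0, noise_sd) if noise_sd > 0 else 1.0
        peak = base_peak * (copy / 2.0) * max(0.0, noise)
        rows.append((sample, probe_id, exon, peak))
    return pd.DataFrame(rows, columns=["sample", "probe", "exon", "peak"])


def default_probe_panel(n_exons: int = 12, probes_per_exon: int = 1, n_reference: int = 4
                        ) -> list[tuple[str, str, bool]]:
    """A simple probe list: per-exon gene probes plus reference probes."""
    probes = []
    for e in range(1, n_exons + 1):
        for r in range(probes_per_exon):
            suffix = chr(ord("a") + r) if probes_per_exon > 1 else ""
            probes.append((f"ex{e}{suffix}", f"exon{e}", False))
    for r in range(n_reference):
        probes.append((f"ref{r + 1}", f"ref{r + 1}", True))
    return probes


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

COHORT_CLASSES = ("PKD1-T", "PKD1-NT", "PKD2", "negative")

#: Default class mix follows the overall yield structure of a mixed diagnostic
#: cohort (roughly 43/12/9/35 percent for PKD1-T / PKD1-NT / PKD2 / negative).
DEFAULT_CLASS_MIX = {"PKD1-T": 0.434, "PKD1-NT": 0.123, "PKD2": 0.094, "negative": 0.349}

#: Mean onset / diagnosis / ESRD ages per genotype class (years) with SDs.
#: Truncating PKD1 runs ~11 years earlier at onset than non-truncating PKD1 and
#: ~20 years earlier than PKD2; ESRD gaps are ~9 and ~14 years.
DEFAULT_ONSET_EFFECTS = {
    "PKD1-T": {"onset": (26.0, 8.0), "diagnosis": (39.0, 8.0), "esrd": (54.0, 8.0)},
    "PKD1-NT": {"onset": (37.0, 8.0), "diagnosis": (46.0, 8.0), "esrd": (63.0, 8.0)},
    "PKD2": {"onset": (46.0, 8.0), "diagnosis": (55.0, 8.0), "esrd": (68.0, 8.0)},
    "negative": {"onset": (35.0, 12.0), "diagnosis": (45.0, 12.0), "esrd": (65.0, 10.0)},
}

_LABEL_OF_CLASS = {
    "PKD1-T": "ADPKD-PKD1-T",
    "PKD1-NT": "ADPKD-PKD1-NT",
    "PKD2": "ADPKD-PKD2",
    "negative": "negative",
}


def simulate_cohort(
    n: int,
    class_mix: dict[str, float] | None = None,
    onset_effects: dict[str, dict[str, tuple[float, float]]] | None = None,
    seed: int = 0,
    family_history_rate: float = 0.767,
) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate a proband cohort with genotype-dependent ages.

    Returns a cohort table (one row per proband) and a list of trio pedigree
    records. Ages are drawn from class-specific normal distributions truncated
    at 1 year; ESRD age is forced >= onset age. Deterministic for a fixed seed.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    mix = class_mix or DEFAULT_CLASS_MIX
    if abs(sum(mix.values()) - 1.0) > 1e-6:
        raise ValueError("class_mix proportions must sum to 1")
    effects = onset_effects or DEFAULT_ONSET_EFFECTS
    for cls, spec in effects.items():
        for _, (_, sd) in spec.items():
            if sd < 0:
                raise ValueError(f"negative SD for class {cls}")
    rng = np.random.default_rng(seed)
    classes = list(mix)
    draws = rng.choice(len(classes), size=n, p=[mix[c] for c in classes])
    rows = []
    pedigrees = []
    for i in range(n):
        cls = classes[int(draws[i])]
        eff = effects[cls]
        onset = max(1.0, rng.normal(*eff["onset"]))
        diagnosis = max(onset, rng.normal(*eff["diagnosis"]))
        esrd = max(onset, rng.normal(*eff["esrd"]))
        has_esrd = bool(rng.random() < (0.35 if cls == "PKD1-T" else 0.2 if cls != "negative" else 0.1))
        fh = bool(rng.random() < family_history_rate)
        pid = f"P{i + 1:04d}"
        onset_class = "VEO" if onset < 1.5 else "EO" if onset < 15 else "adult"
        rows.append({
            "proband": pid,
            "arm": "discovery",
            "genotype_class": cls,
            "nosology": _LABEL_OF_CLASS[cls],
            "family_history": fh,
            "onset_age": round(onset, 1),
            "diagnosis_age": round(diagnosis, 1),
            "esrd_age": round(esrd, 1) if has_esrd else np.nan,
            "onset_class": onset_class,
            "hypertension_before_35": bool(rng.random() < (0.5 if cls == "PKD1-T" else 0.3)),
            "urological_before_35": bool(rng.random() < (0.35 if cls == "PKD1-T" else 0.2)),
            "transplantation": bool(rng.random() < (0.3 if cls == "PKD1-T" else 0.15)),
        })
        carrier = cls != "negative"
        inherited = fh and carrier
        pedigrees.append({
            "family": pid,
            "proband": pid,
            "father": f"{pid}-F",
            "mother": f"{pid}-M",
            "proband_carrier": carrier,
            "father_carrier": bool(inherited and rng.random() < 0.5),
            "mother_carrier": False,
        })
        if inherited and not pedigrees[-1]["father_carrier"]:
            pedigrees[-1]["mother_carrier"] = True
    return pd.DataFrame(rows), pedigrees
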