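"""Masked-reference construction, read alignment, and coverage profiling.

The diagnostic trick of the pipeline is to align amplicon reads against a
reference in which everything outside the target locus is replaced by ``N``:
pseudogene copies cannot attract reads because alignment to ``N`` always scores
as a mismatch. The aligner here is a seed-and-extend banded local aligner
(linear gap penalties) with an explicit two-best-locations mapping-confidence
score, so every filtering decision of the pipeline is inspectable.

Alignment strategy per read: exact k-mer seeds nominate candidate diagonals;
diagonals within a band are clustered; each cluster is scored first ungapped
(pure Hamming, the common case for near-exact amplicon reads) and re-scored by
banded Smith-Waterman when the ungapped score looks indel-degraded. Mapping
confidence is the score gap between the best and second-best cluster, scaled to
[0, 60]; ties report the leftmost location at confidence 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .intervals import Interval, validate_intervals
from .simlocus import SimulatedRead, revcomp

_ENC = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
_IUPAC = set("ACGTNRYSWKMBDHV")


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# Masked reference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaskedReference:
    """A reference whose off-target bases are the ambiguity symbol 'N'."""

    sequence: str
    target_intervals: tuple[Interval, ...]
    source_name: str = "locus"

    def __post_init__(self) -> None:
        validate_intervals(self.target_intervals, len(self.sequence))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def is_target(self) -> np.ndarray:
        mask = np.zeros(self.length, dtype=bool)
        for s, e in self.target_intervals:
            mask[s:e] = True
        return mask


def build_masked_reference(
    genome: str, target_intervals: Sequence[Interval], source_name: str = "locus"
) -> MaskedReference:
    """Mask every base outside ``target_intervals`` with 'N'.

    Length and within-target bases are preserved exactly; overlapping or
    out-of-bounds intervals raise ``ValueError``.
    """
    ivs = validate_intervals(target_intervals, len(genome))
    arr = np.frombuffer(genome.upper().encode(), dtype=np.uint8).copy()
    keep = np.zeros(len(genome), dtype=bool)
    for s, e in ivs:
        keep[s:e] = True
    arr[~keep] = ord("N")
    masked = arr.tobytes().decode()
    for s, e in ivs:
        if any(c not in "ACGT" for c in masked[s:e]):
            raise ValueError("target intervals contain non-ACGT bases")
    return MaskedReference(masked, tuple(ivs), source_name)


# ---------------------------------------------------------------------------
# Alignment records and scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -3
    gap: int = -5
    min_score_frac: float = 0.6  # of the maximum attainable (match * read length)
    min_confidence: int = 20

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap >= 0:
            raise ValueError("need positive match and negative mismatch/gap")


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    ref_start: int
    cigar: str
    score: int
    n_mismatch: int
    confidence: int
    strand: str
    sequence: str  # read in reference orientation
    ref_name: str = "locus"

    @property
    def ref_end(self) -> int:
        """End (exclusive) of the aligned reference span, from the CIGAR."""
        span = 0
        for ln, op in _iter_cigar(self.cigar):
            if op in "MD":
                span += ln
        return self.ref_start + span


def _iter_cigar(cigar: str):
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield int(num), c
            num = ""


# ---------------------------------------------------------------------------
# Aligner
# ---------------------------------------------------------------------------


class ReferenceIndex:
    """k-mer index over a (possibly masked) reference for seed lookup."""

    def __init__(self, ref: MaskedReference, k: int = 16):
        self.ref = ref
        self.k = k
        self.codes = encode(ref.sequence)
        self.kmers: dict[int, list[int]] = {}
        n = len(self.codes)
        if n >= k:
            valid = self.codes < 4
            # rolling 2-bit hash; skip windows containing N
            run = np.zeros(n, dtype=np.int32)
            c = 0
            for i in range(n):
                c = c + 1 if valid[i] else 0
                run[i] = c
            h = 0
            mask = (1 << (2 * k)) - 1
            for i in range(n):
                h = ((h << 2) | int(self.codes[i] & 3)) & mask
                if i >= k - 1 and run[i] >= k:
                    self.kmers.setdefault(h, []).append(i - k + 1)

    def seed_positions(self, read_codes: np.ndarray, max_seeds: int = 6) -> dict[int, int]:
        """Candidate diagonals (ref_start guesses) with seed vote counts."""
        k = self.k
        L = len(read_codes)
        if L < k:
            return {}
        offsets = sorted({0, L // 4, L // 2, (3 * L) // 4, L - k})
        votes: dict[int, int] = {}
        mask = (1 << (2 * k)) - 1
        clean = int(read_codes.max(initial=0)) < 4
        read_list = read_codes.tolist()
        for off in offsets[:max_seeds]:
            window = read_list[off:off + k]
            if not clean and max(window) >= 4:
                continue
            h = 0
            for c in window:
                h = ((h << 2) | c) & mask
            for pos in self.kmers.get(h, ())[:50]:
                diag = pos - off
                votes[diag] = votes.get(diag, 0) + 1
        return votes


def _cluster_diagonals(votes: dict[int, int], band: int) -> list[list[int]]:
    diags = sorted(votes)
    clusters: list[list[int]] = []
    for d in diags:
        if clusters and d - clusters[-1][-1] <= band:
            clusters[-1].append(d)
        else:
            clusters.append([d])
    return clusters


def _ungapped_score(ref_codes: np.ndarray, read_codes: np.ndarray, start: int,
                    scoring: Scoring) -> tuple[int, int]:
    L = len(read_codes)
    if start < 0 or start + L > len(ref_codes):
        return -(10 ** 9), L
    ref_win = ref_codes[start:start + L]
    mm = int(np.count_nonzero((ref_win != read_codes) | (ref_win >= 4)))
    return scoring.match * (L - mm) + scoring.mismatch * mm, mm


def banded_local_align(
    ref_codes: np.ndarray,
    read_codes: np.ndarray,
    ref_start: int,
    scoring: Scoring,
    band: int = 16,
) -> tuple[int, int, str, int]:
    """Banded Smith-Waterman with linear gaps around the diagonal ``ref_start``.

    Returns (score, aligned ref_start, CIGAR, mismatch count). The band covers
    reference offsets ``read_pos + ref_start + [-band, band]``. Within-row gap
    chains are resolved exactly with a prefix-max trick, which is valid for
    linear (non-affine) gap penalties. Alignment to 'N' scores as a mismatch and
    never as a match.
    """
    L = len(read_codes)
    width = 2 * band + 1
    n_ref = len(ref_codes)
    NEG = -(10 ** 9)
    H = np.zeros((L + 1, width), dtype=np.int32)
    g = scoring.gap
    ar = np.arange(width)
    g_ar = g * ar
    # cell (i, j) aligns read[i-1] with reference index ref_start + (i-1) + (j-band);
    # a padded reference makes out-of-bounds indices score as mismatch (code 4)
    pad = L + band + 1
    padded = np.full(n_ref + 2 * pad, 4, dtype=ref_codes.dtype)
    padded[pad:pad + n_ref] = ref_codes
    ins = np.empty(width, dtype=np.int32)
    for i in range(1, L + 1):
        off = pad + ref_start + (i - 1) - band
        ref_row = padded[off:off + width]
        sub = np.where((ref_row == read_codes[i - 1]) & (ref_row < 4),
                       scoring.match, scoring.mismatch)
        prev = H[i - 1]
        base = prev + sub  # diagonal move
        ins[:-1] = prev[1:] + g  # read base vs gap: from (i-1, j+1)
        ins[-1] = NEG
        np.maximum(base, ins, out=base)
        np.maximum(base, 0, out=base)
        # deletion chains within the row (ref base vs gap, from (i, j-1)),
        # resolved exactly for linear gaps with a prefix-max trick
        prefix = np.maximum.accumulate(base - g_ar)
        base[1:] = np.maximum(base[1:], prefix[:-1] + g_ar[1:])
        H[i] = np.maximum(base, 0)
    i_best, j_best = np.unravel_index(int(np.argmax(H)), H.shape)
    score = int(H[i_best, j_best])
    # traceback, recomputing move scores cell by cell
    cigar_ops: list[str] = []
    mismatches = 0
    i, j = int(i_best), int(j_best)
    end_clip = L - i
    while i > 0 and H[i, j] > 0:
        ref_idx = ref_start + (i - 1) + (j - band)
        ref_c = int(ref_codes[ref_idx]) if 0 <= ref_idx < n_ref else 4
        is_match = ref_c == int(read_codes[i - 1]) and ref_c < 4
        sub = scoring.match if is_match else scoring.mismatch
        if H[i, j] == H[i - 1, j] + sub:
            cigar_ops.append("M")
            if not is_match:
                mismatches += 1
            i -= 1
        elif j + 1 < width and H[i, j] == H[i - 1, j + 1] + g:
            cigar_ops.append("I")
            j += 1
            i -= 1
        elif j - 1 >= 0 and H[i, j] == H[i, j - 1] + g:
            cigar_ops.append("D")
            j -= 1
        else:  # local alignment start
            break
    start_clip = i
    first_ref = ref_start + i + (j - band)
    cigar_ops.reverse()
    cigar = _compress_cigar(start_clip, cigar_ops, end_clip)
    return score, first_ref, cigar, mismatches


def _compress_cigar(start_clip: int, ops: list[str], end_clip: int) -> str:
    parts = []
    if start_clip:
        parts.append(f"{start_clip}S")
    if ops:
        cur, cnt = ops[0], 1
        for o in ops[1:]:
            if o == cur:
                cnt += 1
            else:
                parts.append(f"{cnt}{cur}")
                cur, cnt = o, 1
        parts.append(f"{cnt}{cur}")
    if end_clip:
        parts.append(f"{end_clip}S")
    return "".join(parts) or "*"


class Aligner:
    """Seed-and-extend aligner over a masked (or plain) reference."""

    def __init__(self, ref: MaskedReference, scoring: Scoring | None = None,
                 band: int = 16, k: int = 16):
        self.ref = ref
        self.scoring = scoring or Scoring()
        self.band = band
        self.index = ReferenceIndex(ref, k=k)

    def align(self, read: str, read_id: str = "read") -> ReadAlignment | None:
        """Align one read; returns None when rejected (low score/confidence)."""
        if len(read) < 30:
            raise ValueError("read length must be >= 30")
        read = read.upper()
        if not set(read) <= _IUPAC:
            raise ValueError(f"read {read_id} contains non-IUPAC symbols")
        best = self._best_candidates(read)
        if not best:
            return None
        sc = self.scoring
        max_score = sc.match * len(read)
        # sort: score desc, then leftmost
        best.sort(key=lambda t: (-t[0], t[2]))
        top = best[0]
        second_score = best[1][0] if len(best) > 1 else 0
        if len(best) > 1 and best[1][0] == top[0]:
            confidence = 0
        else:
            confidence = int(min(60, 3 * (top[0] - second_score)))
        score, strand, ref_s, cigar, mm, oriented = top
        if score < sc.min_score_frac * max_score:
            return None
        aln = ReadAlignment(read_id=read_id, ref_start=ref_s, cigar=cigar, score=score,
                            n_mismatch=mm, confidence=confidence, strand=strand,
                            sequence=oriented, ref_name=self.ref.source_name)
        return aln

    def align_reads(self, reads: Iterable[SimulatedRead | tuple[str, str]],
                    min_confidence: int | None = None) -> list[ReadAlignment]:
        """Align many reads, dropping rejections and low-confidence mappings."""
        min_conf = self.scoring.min_confidence if min_confidence is None else min_confidence
        out = []
        for r in reads:
            if isinstance(r, SimulatedRead):
                name, seq = r.name, r.sequence
            else:
                name, seq = r
            aln = self.align(seq, name)
            if aln is not None and aln.confidence >= min_conf:
                out.append(aln)
        return out

    # internal ------------------------------------------------------------

    def _best_candidates(self, read: str):
        """Score candidate locations on both strands.

        Returns a list of (score, strand, ref_start, cigar, mismatches,
        oriented read sequence) across all diagonal clusters.
        """
        results = []
        sc = self.scoring
        ref_codes = self.index.codes
        for strand, seq in (("+", read), ("-", revcomp(read))):
            codes = encode(seq)
            votes = self.index.seed_positions(codes)
            if not votes:
                continue
            clusters = _cluster_diagonals(votes, self.band)
            # strongest clusters first; cap work per read
            clusters.sort(key=lambda cl: -max(votes[d] for d in cl))
            for cl in clusters[:6]:
                diag = max(cl, key=lambda d: votes[d])
                score, mm = _ungapped_score(ref_codes, codes, diag, sc)
                cigar = f"{len(seq)}M"
                ref_s = diag
                # rescue with banded DP when the ungapped alignment looks
                # indel-degraded (split diagonals or heavy mismatch load)
                if len(cl) > 1 or score < sc.min_score_frac * sc.match * len(seq):
                    d_score, d_start, d_cigar, d_mm = banded_local_align(
                        ref_codes, codes, diag, sc, self.band)
                    if d_score > score:
                        score, ref_s, cigar, mm = d_score, d_start, d_cigar, d_mm
                results.append((score, strand, ref_s, cigar, mm, seq))
        return results


def align_read(read: str, ref: MaskedReference, scoring: Scoring | None = None,
               band: int = 16, read_id: str = "read") -> ReadAlignment | None:
    """One-shot alignment of a single read (builds a fresh index).

    For many reads against the same reference use :class:`Aligner` directly.
    """
    return Aligner(ref, scoring, band).align(read, read_id)


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoverageProfile:
    depth: np.ndarray  # per-base depth over the full reference
    target_intervals: tuple[Interval, ...]
    threshold: int
    mean_depth: float
    fraction_at_least_threshold: float
    low_coverage_intervals: tuple[Interval, ...]


def coverage_profile(alignments: Sequence[ReadAlignment], ref: MaskedReference,
                     threshold: int = 20) -> CoverageProfile:
    """Per-base depth over the target, with low-coverage (< threshold) intervals.

    The low-coverage intervals are exactly the maximal runs of target bases
    whose depth is below ``threshold``; in the diagnostic workflow these are the
    regions sent to orthogonal (Sanger) confirmation.
    """
    n = ref.length
    diff = np.zeros(n + 1, dtype=np.int64)
    for a in alignments:
        s, e = a.ref_start, a.ref_end
        diff[max(0, s)] += 1
        diff[min(n, e)] -= 1
    depth = np.cumsum(diff[:-1])
    tmask = ref.is_target()
    target_depth = depth[tmask]
    mean = float(target_depth.mean()) if target_depth.size else 0.0
    frac = float(np.mean(target_depth >= threshold)) if target_depth.size else 0.0
    low = tmask & (depth < threshold)
    lows: list[Interval] = []
    i = 0
    idx = np.flatnonzero(low)
    if idx.size:
        start = prev = int(idx[0])
        for p in idx[1:]:
            p = int(p)
            if p == prev + 1:
                prev = p
            else:
                lows.append((start, prev + 1))
                start = prev = p
        lows.append((start, prev + 1))
    return CoverageProfile(depth=depth, target_intervals=ref.target_intervals,
                           threshold=threshold, mean_depth=mean,
                           fraction_at_least_threshold=frac,
                           low_coverage_intervals=tuple(lows))
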