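"""Variant classification rule engine and proband nosology.

A reduced, fully deterministic classification table in the spirit of the ACMG
five-tier system, extended with a sixth *hypomorphic* (H) category for
partially functional, incompletely penetrant alleles:

* protein-truncating consequences (frameshift, nonsense, canonical splice,
  large rearrangement) are always pathogenic (P);
* non-truncating variants are scored by an ordered rule list combining a
  database prior, segregation evidence, a computational verdict and population
  frequency — every decision appends a rule identifier so the path to each
  category is auditable;
* the H category is reachable only by explicit reclassification of an
  *additional* variant found in trans with a main pathogenic allele in an
  early-onset proband (or inherited from an unaffected parent beside a de novo
  main variant).

Proband nosology follows the gene/type convention: ADPKD-PKD1-T, ADPKD-PKD1-NT,
ADPKD-PKD2, PKD-VUS-only, negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

TRUNCATING_CONSEQUENCES = frozenset(
    {"frameshift", "nonsense", "canonical_splice", "large_rearrangement"})
NON_TRUNCATING_CONSEQUENCES = frozenset(
    {"missense", "synonymous", "inframe_indel", "intronic"})
CONSEQUENCES = TRUNCATING_CONSEQUENCES | NON_TRUNCATING_CONSEQUENCES

VERDICTS = ("pathogenic_lean", "benign_lean", "conflicting", "unavailable")
CATEGORIES = ("P", "LP", "VUS", "LB", "B", "H")

#: Severity order used for main-variant ranking (most severe first).
CATEGORY_RANK = {"P": 0, "LP": 1, "VUS": 2, "H": 3, "LB": 4, "B": 5}


@dataclass(frozen=True)
class AnnotatedVariant:
    gene: str  # "PKD1" | "PKD2" | other cystogene
    hgvs: str
    consequence: str
    maf: float = 0.0
    verdict: str = "unavailable"
    db_class: str | None = None  # prior classification from a curated database
    segregating_relatives: int = 0  # affected relatives sharing the variant
    position: int = 0

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if not (0.0 <= self.maf <= 1.0):
            raise ValueError("MAF must be in [0, 1]")
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown computational verdict {self.verdict!r}")
        if self.db_class is not None and self.db_class not in CATEGORIES:
            raise ValueError(f"unknown database class {self.db_class!r}")

    @property
    def truncating(self) -> bool:
        return self.consequence in TRUNCATING_CONSEQUENCES


@dataclass(frozen=True)
class ClassifiedVariant:
    variant: AnnotatedVariant
    category: str
    applied_rules: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.applied_rules:
            raise ValueError("applied_rules must be non-empty")

    @property
    def truncating(self) -> bool:
        return self.variant.truncating

    @property
    def gene(self) -> str:
        return self.variant.gene


def filter_by_frequency(
    variants: Sequence[AnnotatedVariant], maf_cutoff: float = 0.01
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Split variants into (retained rare alleles, frequency-filtered audit log).

    Retains minor allele frequency <= ``maf_cutoff``; a missing MAF is treated
    as 0 (never seen in the population).
    """
    kept, removed = [], []
    for v in variants:
        (kept if v.maf <= maf_cutoff else removed).append(v)
    return kept, removed


def classify_variant(v: AnnotatedVariant, maf_cutoff: float = 0.01) -> ClassifiedVariant:
    """Deterministically classify one variant, recording every applied rule.

    Rule order for non-truncating variants: common-allele guard, database
    prior, computational verdict with population absence, segregation upgrade.
    """
    rules: list[str] = []
    if v.truncating:
        rules.append("TRUNCATING_P")
        return ClassifiedVariant(v, "P", tuple(rules))

    rules.append("NON_TRUNCATING")
    if v.maf > maf_cutoff:
        # common allele: benign end of the spectrum unless a curated database
        # says otherwise (e.g. a known hypomorphic allele that is frequent)
        if v.db_class in ("P", "LP", "H"):
            rules.append(f"DB_PRIOR_{v.db_class}")
            return ClassifiedVariant(v, v.db_class, tuple(rules))
        rules.append("COMMON_ALLELE_B")
        return ClassifiedVariant(v, "B", tuple(rules))

    if v.db_class in ("P", "LP", "H"):
        rules.append(f"DB_PRIOR_{v.db_class}")
        return ClassifiedVariant(v, v.db_class, tuple(rules))

    if v.verdict == "pathogenic_lean" and v.maf == 0.0:
        rules.append("INSILICO_PATH_ABSENT_LP")
        category = "LP"
    elif v.verdict == "benign_lean" and v.maf >= maf_cutoff / 10.0:
        rules.append("INSILICO_BENIGN_NEAR_CUTOFF_LB")
        category = "LB"
    else:
        rules.append("DEFAULT_VUS")
        category = "VUS"

    if category == "VUS" and v.segregating_relatives >= 2:
        rules.append("SEGREGATION_UPGRADE_LP")
        category = "LP"
    return ClassifiedVariant(v, category, tuple(rules))


def reclassify_hypomorphic(
    v: ClassifiedVariant,
    main: ClassifiedVariant,
    onset_class: str,
    phase: str,
    main_de_novo: bool = False,
    inherited_from_unaffected_parent: bool = False,
) -> ClassifiedVariant:
    """Reclassify an *additional* non-truncating variant as hypomorphic (H).

    Applies iff the proband has early-onset disease (onset class VEO or EO) and
    the additional variant is in trans with the main P/LP variant — or the main
    variant is de novo and the additional one was inherited from an unaffected
    parent (phase then unknowable but the transmission pattern is equivalent).
    Any other configuration returns the variant unchanged.
    """
    if v is main or (v.variant.hgvs == main.variant.hgvs and v.gene == main.gene):
        raise ValueError("reclassify_hypomorphic must not be applied to the main variant")
    if main.category not in ("P", "LP"):
        return v
    if v.truncating:
        return v
    trans_like = phase == "trans" or (main_de_novo and inherited_from_unaffected_parent)
    if trans_like and onset_class in ("VEO", "EO"):
        return ClassifiedVariant(v.variant, "H",
                                 v.applied_rules + ("TRANS_EARLY_ONSET_H",))
    return v


@dataclass(frozen=True)
class Nosology:
    proband: str
    label: str  # ADPKD-PKD1-T | ADPKD-PKD1-NT | ADPKD-PKD2 | PKD-VUS-only | negative
    main_variant: ClassifiedVariant | None
    additional_variants: tuple[ClassifiedVariant, ...] = ()


def _rank_key(c: ClassifiedVariant):
    gene_order = 0 if c.gene == "PKD1" else 1 if c.gene == "PKD2" else 2
    return (CATEGORY_RANK[c.category], 0 if c.truncating else 1,
            c.variant.maf, gene_order, c.variant.position)


def assign_nosology(proband: str, variants: Sequence[ClassifiedVariant]) -> Nosology:
    """Derive the proband's nosology label from the highest-ranked (main) variant.

    Ranking: category severity (P > LP > VUS > H > LB > B), then truncating
    before non-truncating, then lower population frequency, then gene order
    PKD1 < PKD2, then position. A proband with no P/LP in PKD1/PKD2 is
    ``PKD-VUS-only`` if a VUS is present there, else ``negative``.
    """
    pk = [v for v in variants if v.gene in ("PKD1", "PKD2")]
    ranked = sorted(pk, key=_rank_key)
    causative = [v for v in ranked if v.category in ("P", "LP")]
    if causative:
        main = causative[0]
        if main.gene == "PKD1":
            label = "ADPKD-PKD1-T" if main.truncating else "ADPKD-PKD1-NT"
        else:
            label = "ADPKD-PKD2"
        extras = tuple(v for v in ranked if v is not main)
        return Nosology(proband, label, main, extras)
    vus = [v for v in ranked if v.category == "VUS"]
    if vus:
        main = vus[0]
        return Nosology(proband, "PKD-VUS-only", main,
                        tuple(v for v in ranked if v is not main))
    return Nosology(proband, "negative", None, tuple(ranked))
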