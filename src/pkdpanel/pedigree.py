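"""Trio and pedigree logic: phase inference, de novo detection, family category.

Genotypes are unphased carrier states (``carrier`` / ``non-carrier`` /
``unknown``) per member and variant — amplicon reads rarely span two variants,
so read-backed phasing is out of reach and everything is inferred from
transmission. Unknown parental states are handled conservatively: each unknown
is resolved both ways, the complete-data rule is applied to every resolution,
and a phase label is returned only when all resolutions agree; otherwise the
phase is ``unknown``, matching diagnostic practice when a parent is unavailable.

Onset classes: VEO (diagnosed in utero or before 18 months), EO (before
15 years), adult, unaffected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

CARRIER = "carrier"
NON_CARRIER = "non-carrier"
UNKNOWN = "unknown"
GENOTYPE_STATES = (CARRIER, NON_CARRIER, UNKNOWN)

PHASE_TRANS = "trans"
PHASE_CIS = "cis"
PHASE_UNKNOWN = "unknown"
PHASE_DE_NOVO = "de_novo_unknown"

ONSET_CLASSES = ("VEO", "EO", "adult", "unaffected")


@dataclass(frozen=True)
class FamilyMember:
    member_id: str
    relationship: str  # proband | father | mother | sibling | ...
    affected: bool
    onset_class: str = "unaffected"

    def __post_init__(self) -> None:
        if self.onset_class not in ONSET_CLASSES:
            raise ValueError(f"unknown onset class {self.onset_class!r}")


@dataclass(frozen=True)
class FamilyGenotypes:
    """Members plus a member x variant carrier-state table."""

    members: tuple[FamilyMember, ...]
    genotypes: Mapping[str, Mapping[str, str]]  # member_id -> variant -> state

    def __post_init__(self) -> None:
        if not any(m.relationship == "proband" for m in self.members):
            raise ValueError("family must include a proband")
        for member, row in self.genotypes.items():
            for state in row.values():
                if state not in GENOTYPE_STATES:
                    raise ValueError(f"bad genotype state {state!r} for {member}")

    def state(self, member_id: str, variant: str) -> str:
        return self.genotypes.get(member_id, {}).get(variant, UNKNOWN)

    @property
    def proband(self) -> FamilyMember:
        return next(m for m in self.members if m.relationship == "proband")


def _phase_complete(mother: tuple[str, str], father: tuple[str, str]) -> str:
    """Phase of two proband-het variants given complete parental genotypes.

    ``mother``/``father`` hold the parent's state for (v1, v2), each carrier or
    non-carrier. A variant carried by neither parent is de novo.
    """
    origins = []
    for k in range(2):
        m, f = mother[k] == CARRIER, father[k] == CARRIER
        if not m and not f:
            return PHASE_DE_NOVO
        origins.append(("M" if m else "") + ("P" if f else ""))
    o1, o2 = origins
    if len(o1) == 1 and len(o2) == 1:
        return PHASE_TRANS if o1 != o2 else PHASE_CIS
    return PHASE_UNKNOWN


def infer_phase(
    family: FamilyGenotypes,
    v1: str,
    v2: str,
    mother_id: str = "mother",
    father_id: str = "father",
) -> str:
    """Infer the phase of two heterozygous proband variants from the trio.

    One variant maternal-only and the other paternal-only gives ``trans``;
    both transmissible only by the same single parent gives ``cis``; a variant
    absent from both parents makes the pair ``de_novo_unknown``; anything
    under-determined (including any unknown parental genotype that changes the
    answer) is ``unknown``. Missing proband genotypes are an error.
    """
    pid = family.proband.member_id
    for v in (v1, v2):
        st = family.state(pid, v)
        if st == UNKNOWN:
            raise ValueError(f"proband genotype for {v!r} is missing")
        if st != CARRIER:
            raise ValueError(f"proband is not a carrier of {v!r}")
    mother = (family.state(mother_id, v1), family.state(mother_id, v2))
    father = (family.state(father_id, v1), family.state(father_id, v2))
    slots = [(who, k) for who, states in (("M", mother), ("P", father))
             for k in range(2) if states[k] == UNKNOWN]
    labels = set()
    for combo in itertools.product((CARRIER, NON_CARRIER), repeat=len(slots)):
        m, f = list(mother), list(father)
        for (who, k), state in zip(slots, combo):
            (m if who == "M" else f)[k] = state
        labels.add(_phase_complete(tuple(m), tuple(f)))
        if len(labels) > 1:
            return PHASE_UNKNOWN
    return labels.pop()


@dataclass(frozen=True)
class DeNovoResult:
    status: str  # "de_novo" | "inherited" | "indeterminate"
    caveat: str = ""

    def __bool__(self) -> bool:
        return self.status == "de_novo"


def detect_de_novo(family: FamilyGenotypes, variant: str,
                   mother_id: str = "mother", father_id: str = "father") -> DeNovoResult:
    """De novo iff the proband carries the variant and both parents do not.

    A missing parental genotype yields ``indeterminate`` rather than a negative
    answer. Every de novo verdict carries the caveat that an apparently de novo
    variant can reflect somatic/germline mosaicism in a parent.
    """
    pid = family.proband.member_id
    if family.state(pid, variant) != CARRIER:
        return DeNovoResult("indeterminate", "proband genotype missing or non-carrier")
    m = family.state(mother_id, variant)
    f = family.state(father_id, variant)
    if UNKNOWN in (m, f):
        return DeNovoResult("indeterminate", "parental genotype unavailable")
    if m == NON_CARRIER and f == NON_CARRIER:
        return DeNovoResult(
            "de_novo",
            "apparent de novo may reflect somatic/germline mosaicism in a parent",
        )
    return DeNovoResult("inherited")


FAMILY_CATEGORIES = ("monoallelic", "biallelic", "digenic", "bilineal",
                     "mosaic_parent", "unresolved")


@dataclass(frozen=True)
class VariantObservation:
    """Classification context for one proband variant used in family categorization."""

    name: str
    gene: str
    category: str  # classification category (P/LP/VUS/H/...)
    homozygous: bool = False
    parental_origin: str | None = None  # "mother" | "father" | "de_novo" | None
    parent_vaf: float | None = None  # carrier parent's VAF, if measured


@dataclass(frozen=True)
class FamilyFinding:
    phase: str | None
    de_novo: tuple[str, ...]
    category: str


def categorize_family(
    observations: Sequence[VariantObservation],
    phase: str | None = None,
    germline_threshold: float = 0.10,
    het_floor: float = 0.20,
) -> FamilyFinding:
    """Family-level category from variant genes, phase and parental origins.

    Priority: a carrier parent with sub-heterozygous VAF (below ``het_floor``)
    is a mosaic parent; two same-gene variants in trans, or one homozygous
    variant, are biallelic; variants in two genes are digenic — bilineal when
    the parental origins establish transmission from both parental lines; a
    single pathogenic/likely pathogenic variant is monoallelic; otherwise the
    family is unresolved.
    """
    de_novo = tuple(o.name for o in observations if o.parental_origin == "de_novo")
    for o in observations:
        if o.parent_vaf is not None and o.parent_vaf < het_floor:
            return FamilyFinding(phase, de_novo, "mosaic_parent")
    causative = [o for o in observations if o.category in ("P", "LP", "VUS", "H")]
    if any(o.homozygous for o in causative):
        return FamilyFinding(phase, de_novo, "biallelic")
    genes = {o.gene for o in causative}
    if len(causative) >= 2:
        if len(genes) == 1 and phase == PHASE_TRANS:
            return FamilyFinding(phase, de_novo, "biallelic")
        if len(genes) >= 2:
            origins = {o.parental_origin for o in causative if o.parental_origin}
            lines = {("mother" if x in ("mother", "de_novo_mother") else
                      "father" if x == "father" else x) for x in origins}
            both_lines = ("mother" in lines and "father" in lines) or (
                "de_novo" in origins and ("mother" in lines or "father" in lines))
            if both_lines:
                return FamilyFinding(phase, de_novo, "bilineal")
            return FamilyFinding(phase, de_novo, "digenic")
    # a lone P/LP variant is monoallelic disease; anything else (single VUS/H,
    # or multiple same-gene variants whose phase could not be established)
    # stays unresolved rather than over-claiming
    if len(causative) == 1 and causative[0].category in ("P", "LP"):
        return FamilyFinding(phase, de_novo, "monoallelic")
    return FamilyFinding(phase, de_novo, "unresolved")
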