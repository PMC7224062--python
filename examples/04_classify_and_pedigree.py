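"""Variant classification, hypomorphic reclassification and trio phase.

Walks a two-variant early-onset proband through the rule engine: a de novo
frameshift (pathogenic by the truncating rule) plus a relatively frequent
missense inherited from a healthy parent, which is reclassified hypomorphic.
Then infers trio phase labels and the family category.
"""

from pkdpanel import (AnnotatedVariant, FamilyGenotypes, FamilyMember,
                      VariantObservation, assign_nosology, categorize_family,
                      classify_variant, detect_de_novo, infer_phase,
                      reclassify_hypomorphic)
from pkdpanel.pedigree import CARRIER, NON_CARRIER

main_v = classify_variant(AnnotatedVariant(
    gene="PKD1", hgvs="c.3236del", consequence="frameshift"))
extra_v = classify_variant(AnnotatedVariant(
    gene="PKD1", hgvs="c.6749C>T", consequence="missense", maf=0.006,
    verdict="benign_lean"))
print(f"main {main_v.variant.hgvs}: {main_v.category} via {main_v.applied_rules}")
print(f"additional {extra_v.variant.hgvs}: {extra_v.category} via {extra_v.applied_rules}")

family = FamilyGenotypes(
    members=(FamilyMember("kid", "proband", True, "EO"),
             FamilyMember("mother", "mother", False),
             FamilyMember("father", "father", False)),
    genotypes={"kid": {"main": CARRIER, "extra": CARRIER},
               "mother": {"main": NON_CARRIER, "extra": NON_CARRIER},
               "father": {"main": NON_CARRIER, "extra": CARRIER}})

dn = detect_de_novo(family, "main")
phase = infer_phase(family, "main", "extra")
print(f"main variant de novo: {dn.status} ({dn.caveat})")
print(f"pair phase: {phase}")

extra_v = reclassify_hypomorphic(extra_v, main_v, onset_class="EO", phase=phase,
                                 main_de_novo=True,
                                 inherited_from_unaffected_parent=True)
print(f"additional after reclassification: {extra_v.category} "
      f"via {extra_v.applied_rules}")

nos = assign_nosology("kid", [main_v, extra_v])
print(f"nosology: {nos.label} (main variant {nos.main_variant.variant.hgvs})")

finding = categorize_family(
    [VariantObservation("main", "PKD1", main_v.category, parental_origin="de_novo"),
     VariantObservation("extra", "PKD1", extra_v.category, parental_origin="father")],
    phase=phase)
print(f"family category: {finding.category}")
# The frequent missense only matters because it sits beside a de novo
# truncating allele in an early-onset child - the hypomorphic pattern. With a
# de novo main variant the phase is unknowable from the trio, so the family
# category stays "unresolved" rather than claiming biallelic disease.
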