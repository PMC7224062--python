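"""Sub-threshold mosaicism: why a 7% variant needs the binomial scan.

Reproduces the two mosaic regimes the pipeline must handle: a 4-bp deletion
supported by 156 of 2,193 reads (7.1% - below the 10% germline threshold, so
the germline caller stays silent) and an SNV at 40 of 252 reads (15.9% -
called with an unbalanced-allele warning and confirmed by the mosaic scan).
"""

from pkdpanel import call_germline, scan_mosaic
from pkdpanel.experiments import make_site_pileup

print("case 1: 156 alt reads among 2,193 (4-bp deletion)")
pileup, _ = make_site_pileup(156, 2193, deletion_len=4, seed=1)
germline = call_germline(pileup, call_threshold=0.10)
print(f"  germline calls at the 10% threshold: {len(germline)}")
for cand in scan_mosaic(pileup, error_rate=0.01):
    print(f"  mosaic scan: {cand.ref}>{cand.alt}  {cand.alt_depth}/{cand.depth} reads"
          f" = {cand.vaf_percent}%  binomial p = {cand.p_value:.2e}")
# The deletion is invisible to threshold calling but wildly incompatible with
# a 1% error rate, so the Bonferroni-corrected scan flags it.

print("\ncase 2: 40 alt reads among 252 (SNV)")
pileup, _ = make_site_pileup(40, 252, seed=2)
for call in call_germline(pileup):
    print(f"  germline caller: VAF {call.vaf_percent}%  genotype {call.genotype}"
          f"  flags {sorted(call.qc_flags)}")
for cand in scan_mosaic(pileup, error_rate=0.01):
    print(f"  mosaic scan: {cand.alt_depth}/{cand.depth} = {cand.vaf_percent}%"
          f"  p = {cand.p_value:.2e}")
# 15.9% sits below the heterozygous band (20-80%), so the call is genotyped
# "ambiguous" with an unbalanced-allele flag and the scan confirms mosaicism.
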