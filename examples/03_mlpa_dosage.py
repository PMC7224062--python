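"""MLPA dosage analysis: an exon 8-9 deletion and a whole-gene deletion.

Simulates probe peak tables for a sample carrying a heterozygous two-exon
deletion (and one with a whole-gene deletion), normalizes them against three
diploid controls and calls rearrangement events. Deleted exons show dosage
quotients near 0.5; diploid exons near 1.0.
"""

from pkdpanel import ProbePanel, call_rearrangements, normalize_dosage, simulate_mlpa
from pkdpanel.simlocus import default_probe_panel

probes = default_probe_panel(n_exons=12, probes_per_exon=1, n_reference=4)
panel = ProbePanel(tuple(probes))
controls = [simulate_mlpa({}, probes, noise_sd=0.04, seed=100 + i) for i in range(3)]

for title, copy_state in [
    ("heterozygous deletion of exons 8-9", {"exon8": 1, "exon9": 1}),
    ("whole-gene heterozygous deletion", {f"exon{i}": 1 for i in range(1, 13)}),
]:
    sample = simulate_mlpa(copy_state, probes, noise_sd=0.04, seed=7)
    quotients = normalize_dosage(sample, controls, panel)
    calls, events = call_rearrangements(quotients, panel, low=0.70, high=1.30)
    print(title)
    shown = [c for c in calls if c.exon in ("exon1", "exon8", "exon9")]
    for c in shown:
        print(f"  {c.exon}: dosage quotient {c.quotient:.2f} -> {c.state}")
    for e in events:
        span = f"{e.exons[0]}..{e.exons[-1]}" if len(e.exons) > 1 else e.exons[0]
        print(f"  event: {e.state} spanning {span}"
              + ("  [whole gene]" if e.whole_gene else ""))
    print()
# Quotients near 0.5 are one lost copy out of two; the event merger turns
# per-exon states into a single deletion call with its span.
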