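"""MLPA dosage-quotient analysis for exon-level deletions and duplications.

Implements the standard dosage-quotient computation: each probe peak is
normalized to the median of the reference probes within its own sample, then
divided by the same ratio in control samples and averaged over controls. A
copy-2 probe therefore has an expected quotient of 1, a heterozygous deletion
~0.5 and a heterozygous duplication ~1.5. Exon-level states are thresholded on
the exon's probe-median quotient and adjacent same-state exons are merged into
events; a whole-gene flag marks events covering every gene exon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ProbePanel:
    """Probe layout: (probe id, exon label, is_reference)."""

    probes: tuple[tuple[str, str, bool], ...]

    def __post_init__(self) -> None:
        n_ref = sum(1 for _, _, is_ref in self.probes if is_ref)
        if n_ref < 2:
            raise ValueError("panel needs at least 2 reference probes")
        if not any(not is_ref for _, _, is_ref in self.probes):
            raise ValueError("panel has no gene probes")

    @property
    def reference_probes(self) -> list[str]:
        return [p for p, _, is_ref in self.probes if is_ref]

    @property
    def gene_exons(self) -> list[str]:
        """Gene exon labels in panel order (first occurrence)."""
        seen: list[str] = []
        for _, exon, is_ref in self.probes:
            if not is_ref and exon not in seen:
                seen.append(exon)
        return seen

    def probes_of_exon(self, exon: str) -> list[str]:
        return [p for p, e, is_ref in self.probes if not is_ref and e == exon]


@dataclass(frozen=True)
class DosageCall:
    exon: str
    quotient: float
    state: str  # deletion | normal | duplication
    note: str = ""


@dataclass(frozen=True)
class DosageEvent:
    """Maximal run of adjacent same-state exons."""

    state: str
    exons: tuple[str, ...]
    whole_gene: bool


def _peaks_as_series(peaks: pd.DataFrame | pd.Series) -> pd.Series:
    if isinstance(peaks, pd.Series):
        return peaks
    return peaks.set_index("probe")["peak"]


def normalize_dosage(
    sample_peaks: pd.DataFrame | pd.Series,
    control_peaks: Sequence[pd.DataFrame | pd.Series],
    panel: ProbePanel,
) -> pd.Series:
    """Per-probe dosage quotients of a sample against >= 1 control samples.

    quotient(probe) = mean over controls of
    ``(sample_peak / sample_ref_median) / (control_peak / control_ref_median)``.
    Raises on a zero reference-probe median or on missing panel probes.
    """
    if not control_peaks:
        raise ValueError("need at least one control sample")
    sample = _peaks_as_series(sample_peaks)
    probe_ids = [p for p, _, _ in panel.probes]
    for pid in probe_ids:
        if pid not in sample.index:
            raise ValueError(f"sample is missing probe {pid!r}")
    ref_ids = panel.reference_probes
    s_ref = float(np.median(sample.loc[ref_ids]))
    if s_ref == 0:
        raise ValueError("zero reference-probe median in sample")
    s_norm = sample.loc[probe_ids] / s_ref
    quotients = np.zeros(len(probe_ids))
    for ctrl in control_peaks:
        c = _peaks_as_series(ctrl)
        for pid in probe_ids:
            if pid not in c.index:
                raise ValueError(f"control is missing probe {pid!r}")
        c_ref = float(np.median(c.loc[ref_ids]))
        if c_ref == 0:
            raise ValueError("zero reference-probe median in control")
        c_norm = c.loc[probe_ids] / c_ref
        quotients += (s_norm / c_norm).to_numpy()
    quotients /= len(control_peaks)
    return pd.Series(quotients, index=probe_ids, name="quotient")


def call_rearrangements(
    quotients: pd.Series,
    panel: ProbePanel,
    low: float = 0.70,
    high: float = 1.30,
) -> tuple[list[DosageCall], list[DosageEvent]]:
    """Exon-level dosage calls and merged deletion/duplication events.

    The exon state comes from the median quotient over the exon's probes. When
    an exon has several probes and only a single one is aberrant, the exon is
    reported normal with a "single-probe anomaly" note instead of an event —
    isolated probe failures are not rearrangements.
    """
    if not (0.0 < low < 1.0 < high):
        raise ValueError("thresholds must satisfy 0 < low < 1 < high")

    def state_of(q: float) -> str:
        return "deletion" if q < low else "duplication" if q > high else "normal"

    calls: list[DosageCall] = []
    for exon in panel.gene_exons:
        probes = panel.probes_of_exon(exon)
        qs = quotients.loc[probes].to_numpy(dtype=float)
        med = float(np.median(qs))
        st = state_of(med)
        note = ""
        if len(probes) > 1:
            aberrant = [p for p, q in zip(probes, qs) if state_of(float(q)) != "normal"]
            if st == "normal" and len(aberrant) == 1:
                note = f"single-probe anomaly: {aberrant[0]}"
        calls.append(DosageCall(exon=exon, quotient=med, state=st, note=note))

    events: list[DosageEvent] = []
    run: list[DosageCall] = []
    n_exons = len(calls)
    for c in calls + [DosageCall("_end", 1.0, "normal")]:
        if run and c.state == run[0].state:
            run.append(c)
        else:
            if run and run[0].state != "normal":
                events.append(DosageEvent(
                    state=run[0].state,
                    exons=tuple(r.exon for r in run),
                    whole_gene=len(run) == n_exons,
                ))
            run = [c]
    return calls, events
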