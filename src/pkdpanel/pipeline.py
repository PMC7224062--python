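"""Pipeline orchestration: simulate -> mask -> align -> call -> report.

Each stage writes its outputs under the run directory and records a SHA-256
checksum in the manifest, so two runs with the same configuration and seed can
be compared file by file. A stage failure aborts the run with the stage name.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import io as pio
from .classify import AnnotatedVariant, assign_nosology, classify_variant
from .config import RunConfig
from .cohort import anova_onset, yield_table
from .maskalign import Aligner, Scoring, coverage_profile
from .mlpa import ProbePanel, call_rearrangements, normalize_dosage
from .pedigree import (CARRIER, NON_CARRIER, FamilyGenotypes, FamilyMember,
                       detect_de_novo)
from .simlocus import (ReadErrorModel, VariantScenario, default_probe_panel,
                       design_amplicons, generate_locus, simulate_cohort,
                       simulate_mlpa, simulate_reads)
from .varcall import (build_pileup, call_germline, detect_allele_dropout,
                      flag_dropout_suspects, qc_allele_balance, scan_mosaic)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages; returns the manifest (also written as JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "files": {}}
    state: dict = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["files"][name] = _sha256(path)

    stage_fns = {
        "locus": _stage_locus, "reads": _stage_reads, "align": _stage_align,
        "call": _stage_call, "mlpa": _stage_mlpa, "classify": _stage_classify,
        "pedigree": _stage_pedigree, "cohort": _stage_cohort,
    }
    for stage in config.stages:
        try:
            stage_fns[stage](config, state, emit)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - surface the failing stage
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"].append(stage)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# --- stages ----------------------------------------------------------------


def _stage_locus(cfg: RunConfig, state: dict, emit) -> None:
    lc = cfg.locus
    locus = generate_locus(cfg.seed, n_paralogs=lc.n_paralogs, identity=lc.identity,
                           length=lc.length, n_anchors=lc.n_anchors,
                           n_exons=lc.n_exons, exon_length=lc.exon_length)
    amps = design_amplicons(locus, cfg.amplicons.amplicon_length,
                            cfg.amplicons.min_overlap, cfg.amplicons.primer_length)
    state["locus"], state["amplicons"] = locus, amps
    records = {"gene": locus.gene_sequence}
    records.update({f"paralog{i + 1}": p for i, p in enumerate(locus.paralogs)})
    emit("locus.fasta", lambda p: pio.write_fasta(p, records))
    emit("exons.bed", lambda p: pio.write_bed(p, locus.exon_intervals, "gene"))
    emit("anchors.bed", lambda p: pio.write_bed(
        p, [(a, a + 1) for a in locus.anchor_sites], "gene"))
    emit("amplicons.bed", lambda p: pio.write_bed(
        p, [(a.interval[0], a.interval[1], a.name) for a in amps.amplicons], "gene"))


def _resolve_scenarios(cfg: RunConfig, state: dict) -> list[VariantScenario]:
    locus = state["locus"]
    out = []
    for sc in cfg.reads.scenarios:
        ref = sc.ref
        alt = sc.alt
        if ref == "auto":
            ref = locus.gene_sequence[sc.position]
        if alt == "auto":
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        out.append(VariantScenario(position=sc.position, ref=ref, alt=alt,
                                   zygosity=sc.zygosity,
                                   mosaic_fraction=sc.mosaic_fraction,
                                   dropout=sc.dropout,
                                   dropout_amplicon=sc.dropout_amplicon,
                                   name=sc.name))
    return out


def _stage_reads(cfg: RunConfig, state: dict, emit) -> None:
    rc = cfg.reads
    em = ReadErrorModel(substitution_rate=rc.substitution_rate,
                        homopolymer_rate0=rc.homopolymer_rate0,
                        gc_multiplier=rc.gc_multiplier, read_length=rc.read_length)
    scenarios = _resolve_scenarios(cfg, state)
    reads = simulate_reads(state["locus"], state["amplicons"], scenarios,
                           depth=rc.depth, error_model=em,
                           contamination=rc.contamination, seed=cfg.seed + 1)
    state["reads"], state["scenarios"] = reads, scenarios
    emit("reads.fastq", lambda p: pio.write_fastq(p, reads))


def _stage_align(cfg: RunConfig, state: dict, emit) -> None:
    from .experiments import masked_reference_of

    locus = state["locus"]
    ref = masked_reference_of(locus)
    ac = cfg.align
    scoring = Scoring(match=ac.match, mismatch=ac.mismatch, gap=ac.gap,
                      min_score_frac=ac.min_score_frac,
                      min_confidence=ac.min_confidence)
    aligner = Aligner(ref, scoring, band=ac.band)
    alns = aligner.align_reads(state["reads"])
    state["ref"], state["alignments"] = ref, alns
    emit("masked.fasta", lambda p: pio.write_fasta(p, {ref.source_name: ref.sequence}))
    emit("alignments.sam", lambda p: pio.write_sam(p, alns, ref))
    cov = coverage_profile(alns, ref, cfg.call.coverage_threshold)
    state["coverage"] = cov
    emit("coverage.bedgraph", lambda p: pio.write_bedgraph(p, cov.depth, ref.source_name))
    emit("low_coverage.bed", lambda p: pio.write_bed(
        p, cov.low_coverage_intervals, ref.source_name))


def _stage_call(cfg: RunConfig, state: dict, emit) -> None:
    cc = cfg.call
    ref = state["ref"]
    pileup = build_pileup(state["alignments"], ref)
    calls = call_germline(pileup, cc.threshold, (cc.het_low, cc.het_high),
                          cc.hom_threshold, cc.min_depth)
    calls = [qc_allele_balance(c, pileup) for c in calls]
    mosaic = scan_mosaic(pileup, cc.error_rate, cc.threshold, cc.alpha,
                         cc.min_alt, max_vaf=cc.het_low) if cc.mosaic else []
    report = detect_allele_dropout(state["alignments"], ref, state["amplicons"],
                                   call_kwargs={"call_threshold": cc.threshold,
                                                "het_band": (cc.het_low, cc.het_high),
                                                "hom_threshold": cc.hom_threshold,
                                                "min_depth": cc.min_depth})
    if report.possible:
        calls = flag_dropout_suspects(calls, report)
    state["calls"], state["mosaic_calls"], state["dropout"] = calls, mosaic, report
    emit("variants.vcf", lambda p: pio.write_vcf(p, calls, ref, mosaic))
    rows = [{"pos": e.get("pos"), "kind": e.get("kind"),
             "detail": json.dumps({k: v for k, v in e.items()
                                   if k not in ("pos", "kind")})}
            for e in report.events]
    frame = pd.DataFrame(rows, columns=["pos", "kind", "detail"])
    emit("dropout.tsv", lambda p: pio.write_tsv(p, frame))


def _stage_mlpa(cfg: RunConfig, state: dict, emit) -> None:
    mc = cfg.mlpa
    probes = default_probe_panel(mc.n_exons, mc.probes_per_exon, mc.n_reference_probes)
    panel = ProbePanel(tuple(probes))
    sample = simulate_mlpa(mc.copy_state, probes, mc.noise_sd, cfg.seed + 2, "case")
    controls = [simulate_mlpa({}, probes, mc.noise_sd, cfg.seed + 3 + i, f"ctrl{i}")
                for i in range(mc.n_controls)]
    q = normalize_dosage(sample, controls, panel)
    calls, events = call_rearrangements(q, panel, mc.low, mc.high)
    state["mlpa_events"] = events
    frame = pd.DataFrame([{"exon": c.exon, "quotient": round(c.quotient, 3),
                           "state": c.state, "note": c.note} for c in calls])
    emit("dosage.tsv", lambda p: pio.write_tsv(p, frame))
    emit("mlpa_events.bed", lambda p: pio.write_bed(
        p, [(i, i + 1, f"{e.state}:{','.join(e.exons)}")
            for i, e in enumerate(events)], "mlpa"))


def _stage_classify(cfg: RunConfig, state: dict, emit) -> None:
    # classify the injected scenarios as if annotated: SNVs as missense with a
    # pathogenic-leaning verdict, indels as frameshift
    scenarios = state.get("scenarios", [])
    variants = []
    for sc in scenarios:
        consequence = "missense" if len(sc.ref) == len(sc.alt) else "frameshift"
        variants.append(AnnotatedVariant(
            gene="PKD1", hgvs=f"c.{sc.position + 1}{sc.ref}>{sc.alt}",
            consequence=consequence, maf=0.0, verdict="pathogenic_lean",
            position=sc.position))
    classified = [classify_variant(v) for v in variants]
    nos = assign_nosology("demo", classified)
    state["nosology"] = nos
    frame = pd.DataFrame([{
        "gene": c.gene, "hgvs": c.variant.hgvs, "consequence": c.variant.consequence,
        "category": c.category, "applied_rules": ";".join(c.applied_rules),
    } for c in classified])
    emit("classified.tsv", lambda p: pio.write_tsv(p, frame))
    nos_frame = pd.DataFrame([{
        "proband": nos.proband, "label": nos.label,
        "main_variant": nos.main_variant.variant.hgvs if nos.main_variant else "",
    }])
    emit("nosology.tsv", lambda p: pio.write_tsv(p, nos_frame))


def _stage_pedigree(cfg: RunConfig, state: dict, emit) -> None:
    _, peds = simulate_cohort(cfg.cohort.n, seed=cfg.seed + 11,
                              family_history_rate=cfg.cohort.family_history_rate)
    rows = []
    for fam in peds:
        family = FamilyGenotypes(
            members=(FamilyMember(fam["proband"], "proband", True, "adult"),
                     FamilyMember(fam["father"], "father", False),
                     FamilyMember(fam["mother"], "mother", False)),
            genotypes={
                fam["proband"]: {"v1": CARRIER if fam["proband_carrier"] else NON_CARRIER},
                fam["father"]: {"v1": CARRIER if fam["father_carrier"] else NON_CARRIER},
                fam["mother"]: {"v1": CARRIER if fam["mother_carrier"] else NON_CARRIER},
            })
        if fam["proband_carrier"]:
            dn = detect_de_novo(family, "v1", fam["mother"], fam["father"])
            rows.append({"family": fam["family"], "de_novo": dn.status,
                         "caveat": dn.caveat})
    state["pedigree_rows"] = rows
    emit("pedigree.ped", lambda p: pio.write_ped(p, peds, ("v1",)))
    emit("de_novo.tsv", lambda p: pio.write_tsv(p, pd.DataFrame(rows)))


def _stage_cohort(cfg: RunConfig, state: dict, emit) -> None:
    records, _ = simulate_cohort(cfg.cohort.n, seed=cfg.seed + 11,
                                 family_history_rate=cfg.cohort.family_history_rate)
    emit("cohort.tsv", lambda p: pio.write_tsv(p, records))
    yt = yield_table(records)
    emit("yield.tsv", lambda p: pio.write_tsv(p, yt, index=True))
    positive = records[records["nosology"] != "negative"]
    res = anova_onset(positive, "onset_age", "nosology")
    lines = ["Cohort report", "=============", "",
             f"probands: {len(records)}",
             f"positive: {len(positive)} ({100 * len(positive) / len(records):.1f}%)",
             "",
             "onset-age ANOVA across genotype classes:",
             f"  F = {res.f_statistic:.2f}, p = {res.p_value:.2e}"]
    for g, m in res.group_means.items():
        lines.append(f"  mean onset {g}: {m:.1f} y (n={res.group_sizes[g]})")
    emit("report.txt", lambda p: Path(p).write_text("\n".join(lines) + "\n"))
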