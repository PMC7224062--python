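"""Plain-text readers/writers for the pipeline's interchange formats.

Everything here is line-oriented text: FASTA/FASTQ, BED (0-based half-open),
minimal SAM, VCF 4.3 with the pipeline's INFO fields, PED with per-variant
carrier columns, and TSV via pandas. VCF and SAM use 1-based coordinates at
the serialization boundary only.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .maskalign import MaskedReference, ReadAlignment
from .simlocus import SimulatedRead
from .varcall import VariantCall


def write_fasta(path: str | Path, records: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    records: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                records[name] = []
            elif name is not None:
                records[name].append(line)
    return {k: "".join(v) for k, v in records.items()}


def write_fastq(path: str | Path, reads: Iterable[SimulatedRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read (name, sequence) pairs from an uncompressed FASTQ."""
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((header.strip()[1:], seq))
    return out


def write_bed(path: str | Path, intervals: Iterable[tuple], chrom: str = "locus") -> None:
    """BED3/BED4: rows are (start, end) or (start, end, name), half-open 0-based."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = f"\t{iv[2]}" if len(iv) > 2 else ""
            fh.write(f"{chrom}\t{iv[0]}\t{iv[1]}{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str | None]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            rows.append((parts[0], int(parts[1]), int(parts[2]),
                         parts[3] if len(parts) > 3 else None))
    return rows


def write_bedgraph(path: str | Path, depth, chrom: str = "locus") -> None:
    """Run-length-compressed per-base depth track."""
    with open(path, "w") as fh:
        start = 0
        cur = int(depth[0]) if len(depth) else 0
        for i in range(1, len(depth)):
            if int(depth[i]) != cur:
                fh.write(f"{chrom}\t{start}\t{i}\t{cur}\n")
                start, cur = i, int(depth[i])
        if len(depth):
            fh.write(f"{chrom}\t{start}\t{len(depth)}\t{cur}\n")


def write_sam(path: str | Path, alignments: Sequence[ReadAlignment],
              ref: MaskedReference) -> None:
    """Minimal SAM: header plus QNAME/FLAG/RNAME/POS/MAPQ/CIGAR/SEQ columns."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{ref.source_name}\tLN:{ref.length}\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            fh.write("\t".join([
                a.read_id.replace(" ", "_"), str(flag), a.ref_name,
                str(a.ref_start + 1), str(a.confidence), a.cigar,
                "*", "0", "0", a.sequence, "*",
            ]) + "\n")


def write_vcf(path: str | Path, calls: Sequence[VariantCall], ref: MaskedReference,
              mosaic: Sequence[VariantCall] = ()) -> None:
    """VCF 4.3 with DP, AD, VAF, QCFLAGS and MOSAIC_P INFO fields."""
    lines = [
        "##fileformat=VCFv4.3",
        f"##contig=<ID={ref.source_name},length={ref.length}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##INFO=<ID=AD,Number=1,Type=Integer,Description="Alternate allele depth">',
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction, percent">',
        '##INFO=<ID=GT_STATE,Number=1,Type=String,Description="Genotype state">',
        '##INFO=<ID=QCFLAGS,Number=.,Type=String,Description="Advisory QC flags">',
        '##INFO=<ID=MOSAIC_P,Number=1,Type=Float,Description="Binomial tail p for mosaic candidates">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in sorted(list(calls) + list(mosaic), key=lambda x: (x.pos, x.alt)):
        info = [f"DP={c.depth}", f"AD={c.alt_depth}", f"VAF={c.vaf_percent}",
                f"GT_STATE={c.genotype}"]
        if c.qc_flags:
            info.append("QCFLAGS=" + ",".join(sorted(c.qc_flags)))
        if c.p_value is not None:
            info.append(f"MOSAIC_P={c.p_value:.3e}")
        lines.append("\t".join([
            c.ref_name, str(c.pos + 1), ".", c.ref, c.alt, ".", "PASS",
            ";".join(info),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_ped(path: str | Path, families: Sequence[dict],
              variant_names: Sequence[str] = ()) -> None:
    """Standard 6-column PED plus one column per variant (0/1/2 = missing/non-carrier/carrier).

    Each family dict needs family/proband/father/mother ids plus
    ``<member>_carrier`` booleans for the listed variants (or a single
    ``*_carrier`` flag when there is one variant).
    """
    with open(path, "w") as fh:
        for fam in families:
            fid = fam["family"]
            rows = [
                (fam["father"], "0", "0", "1", "1"),
                (fam["mother"], "0", "0", "2", "1"),
                (fam["proband"], fam["father"], fam["mother"], "0", "2"),
            ]
            carrier_flags = {
                fam["father"]: fam.get("father_carrier", False),
                fam["mother"]: fam.get("mother_carrier", False),
                fam["proband"]: fam.get("proband_carrier", False),
            }
            for iid, f, m, sex, phen in rows:
                geno = []
                for _ in variant_names or ("v1",):
                    geno.append("2" if carrier_flags.get(iid) else "1")
                fh.write("\t".join([fid, iid, f, m, sex, phen] + geno) + "\n")


def write_tsv(path: str | Path, frame: pd.DataFrame, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
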