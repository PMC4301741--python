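"""File I/O for the standard formats the pipeline emits and consumes.

FASTA/FASTQ go through Biopython SeqIO; VCF 4.2 is emitted by a small
writer (records carry GT and DP per sample plus the QUAL column) and read
back through pysam; callable masks travel as 3-column BED; gene models as
GFF3.  Coordinates are 0-based half-open internally and 1-based in
VCF/GFF emissions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .audit import CallableMask, VariantCall
from .effects import GeneModel
from .screen import Read


# ---------------------------------------------------------------- FASTA/FASTQ


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_fastq(path: str | Path, reads: list[Read]) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.name, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[Read]:
    return [
        Read(r.id, str(r.seq), np.array(r.letter_annotations["phred_quality"]))
        for r in SeqIO.parse(str(path), "fastq")
    ]


# ---------------------------------------------------------------- VCF


_ZYG_TO_GT = {"het": "0/1", "hom_alt": "1/1"}
_GT_TO_ZYG = {(0, 1): "het", (1, 1): "hom_alt"}


def write_vcf(path: str | Path, calls: list[VariantCall], line: str,
              contigs: dict[str, int]) -> None:
    """One-sample VCF 4.2 with GT and DP (supporting reads) per call."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, size in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                 'Description="Supporting read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{line}\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            gt = _ZYG_TO_GT[c.zygosity]
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref_allele}\t{c.alt_allele}\t"
                f"{c.quality:g}\t.\t.\tGT:DP\t{gt}:{c.depth}\n"
            )


def read_vcf(path: str | Path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        (sample,) = list(vf.header.samples)
        for rec in vf:
            s = rec.samples[sample]
            gt = tuple(sorted(a for a in s["GT"] if a is not None))
            zyg = _GT_TO_ZYG.get(gt)
            if zyg is None:
                continue
            calls.append(VariantCall(
                line=sample, chrom=rec.chrom, pos=rec.pos,
                ref_allele=rec.ref, alt_allele=rec.alts[0],
                zygosity=zyg, depth=int(s["DP"]), quality=float(rec.qual),
            ))
    return calls


# ---------------------------------------------------------------- BED


def write_bed(path: str | Path, mask: CallableMask) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(mask.chroms):
            for a, b in mask.intervals(chrom):
                fh.write(f"{chrom}\t{a}\t{b}\n")


def read_bed(path: str | Path, chrom_sizes: dict[str, int]) -> CallableMask:
    """BED intervals -> boolean mask; unsorted input is normalised."""
    mask = CallableMask({c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()})
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith(("#", "track")):
                continue
            parts = raw.split()
            try:
                chrom, a, b = parts[0], int(parts[1]), int(parts[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED record") from exc
            if chrom not in mask.chroms:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            mask.chroms[chrom][a:b] = True
    return mask


# ---------------------------------------------------------------- GFF3


def write_gff3(path: str | Path, models: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gid = m.gene_id
            fh.write(f"{m.chrom}\tgtaudit\tgene\t{m.tx_start + 1}\t{m.tx_end}\t.\t"
                     f"{m.strand}\t.\tID={gid}\n")
            fh.write(f"{m.chrom}\tgtaudit\tmRNA\t{m.tx_start + 1}\t{m.tx_end}\t.\t"
                     f"{m.strand}\t.\tID={gid}.1;Parent={gid}\n")
            for a, b in m.exons:
                fh.write(f"{m.chrom}\tgtaudit\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t"
                         f"Parent={gid}.1\n")
            for a, b in m.cds:
                fh.write(f"{m.chrom}\tgtaudit\tCDS\t{a + 1}\t{b}\t.\t{m.strand}\t0\t"
                         f"Parent={gid}.1\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 record")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            iv = (int(start) - 1, int(end))
            if ftype == "gene":
                gid = attr["ID"]
                genes[gid] = {"chrom": chrom, "strand": strand,
                              "exons": [], "cds": []}
                order.append(gid)
            elif ftype in ("exon", "CDS"):
                gid = attr["Parent"].rsplit(".", 1)[0]
                genes[gid]["exons" if ftype == "exon" else "cds"].append(iv)
    return [
        GeneModel(gene_id=gid, chrom=g["chrom"], strand=g["strand"],
                  exons=tuple(sorted(g["exons"])), cds=tuple(sorted(g["cds"])))
        for gid, g in ((gid, genes[gid]) for gid in order)
    ]
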