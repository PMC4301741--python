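"""Variant effect classification against gene models.

Each variant is classified once per overlapping or nearby transcript into
one of sixteen categories (frameshift, non-synonymous, splice site, UTR,
upstream/downstream, ... intergenic), mirroring the vocabulary of snpEff
for plant genome annotation.  Eight categories are flagged "impactful" —
predicted to change the quantity and/or quality of the encoded protein.

Coordinates are 0-based half-open internally; variant positions arrive
1-based (VCF convention).  Indels are anchored: ref and alt share a 1 bp
anchor base and the altered span starts one base to its right.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

from .dnautil import CODON_TABLE, STOP_CODONS, revcomp

log = logging.getLogger(__name__)

CATEGORIES = (
    "FRAME_SHIFT",
    "NON_SYNONYMOUS_CODING",
    "CODON_CHANGE_PLUS_CODON_DELETION",
    "START_GAINED",
    "START_LOST",
    "STOP_GAINED",
    "SPLICE_SITE_ACCEPTOR",
    "SPLICE_SITE_DONOR",
    "SYNONYMOUS_CODING",
    "EXON",
    "INTRON",
    "UTR_3_PRIME",
    "UTR_5_PRIME",
    "UPSTREAM",
    "DOWNSTREAM",
    "INTERGENIC",
)

#: categories predicted to affect protein quantity and/or quality
IMPACTFUL_CATEGORIES = frozenset(CATEGORIES[:8])

SPLICE_SITE_WIDTH = 2  # bases of intron at each boundary


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript protein-coding (or non-coding) gene model.

    ``exons`` and ``cds`` are sorted, non-overlapping genomic intervals
    (0-based half-open); CDS intervals lie inside exons.  UTRs are derived:
    exonic positions outside the CDS span, assigned 5' or 3' by strand.
    """

    gene_id: str
    chrom: str
    strand: str                       # "+" | "-"
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        for (a, b) in self.exons + self.cds:
            if a >= b:
                raise ValueError("empty interval in gene model")
        for (_, b), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 <= b:
                raise ValueError("exons overlap or are unsorted")

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @cached_property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (b, a2) for (_, b), (a2, _) in zip(self.exons, self.exons[1:])
        )

    @cached_property
    def cds_positions(self) -> list[int]:
        """Genomic CDS positions in transcript (5'->3') order."""
        pos = [p for (a, b) in self.cds for p in range(a, b)]
        return pos if self.strand == "+" else pos[::-1]

    @cached_property
    def _cds_index(self) -> dict[int, int]:
        return {p: i for i, p in enumerate(self.cds_positions)}

    @cached_property
    def _exonic(self) -> set[int]:
        return {p for (a, b) in self.exons for p in range(a, b)}

    @cached_property
    def _cds_set(self) -> set[int]:
        return set(self._cds_index)

    @cached_property
    def utr5_positions(self) -> list[int]:
        """Genomic 5'UTR positions in transcript order."""
        if not self.is_coding:
            return []
        cds_lo = self.cds[0][0]
        cds_hi = self.cds[-1][1]
        if self.strand == "+":
            return sorted(p for p in self._exonic if p < cds_lo)
        return sorted((p for p in self._exonic if p >= cds_hi), reverse=True)

    @cached_property
    def utr3_positions(self) -> set[int]:
        if not self.is_coding:
            return set()
        cds_lo = self.cds[0][0]
        cds_hi = self.cds[-1][1]
        if self.strand == "+":
            return {p for p in self._exonic if p >= cds_hi}
        return {p for p in self._exonic if p < cds_lo}

    def transcript_base(self, genome: str, p0: int) -> str:
        """Base at genomic position in transcript orientation."""
        b = genome[p0]
        return b if self.strand == "+" else revcomp(b)


@dataclass(frozen=True)
class EffectRecord:
    variant_key: tuple
    transcript_id: str | None
    category: str

    @property
    def impactful(self) -> bool:
        return self.category in IMPACTFUL_CATEGORIES


def _splice_category(model: GeneModel, p0: int) -> str | None:
    """Splice-site category if p0 lies in the first/last 2 bp of an intron."""
    for (a, b) in model.introns:
        if not a <= p0 < b:
            continue
        at_left = p0 - a < SPLICE_SITE_WIDTH
        at_right = b - p0 <= SPLICE_SITE_WIDTH
        if not (at_left or at_right):
            return "INTRON"
        # donor = intron end adjacent to the upstream exon (5' of the intron)
        if model.strand == "+":
            return "SPLICE_SITE_DONOR" if at_left else "SPLICE_SITE_ACCEPTOR"
        return "SPLICE_SITE_DONOR" if at_right else "SPLICE_SITE_ACCEPTOR"
    return None


def _classify_cds_snp(model: GeneModel, genome: str, p0: int, alt: str) -> str:
    cds_pos = model.cds_positions
    i = model._cds_index[p0]
    codon_idx = i // 3
    codon_pos = [cds_pos[codon_idx * 3 + k] for k in range(3)
                 if codon_idx * 3 + k < len(cds_pos)]
    if len(codon_pos) < 3:           # trailing partial codon: treat as exonic
        return "EXON"
    ref_codon = "".join(model.transcript_base(genome, p) for p in codon_pos)
    alt_tx = alt if model.strand == "+" else revcomp(alt)
    k = codon_pos.index(p0)
    alt_codon = ref_codon[:k] + alt_tx + ref_codon[k + 1:]
    if codon_idx == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return "START_LOST"
    if alt_codon in STOP_CODONS and ref_codon not in STOP_CODONS:
        return "STOP_GAINED"
    if CODON_TABLE[ref_codon] == CODON_TABLE[alt_codon]:
        return "SYNONYMOUS_CODING"
    return "NON_SYNONYMOUS_CODING"


def _classify_cds_indel(ref: str, alt: str) -> str:
    delta = len(alt) - len(ref)
    if delta % 3 != 0:
        return "FRAME_SHIFT"
    if delta < 0:
        return "CODON_CHANGE_PLUS_CODON_DELETION"
    # in-frame insertions have no category of their own here
    log.warning("in-frame CDS insertion tallied as EXON (no dedicated category)")
    return "EXON"


def _start_gained(model: GeneModel, genome: str, p0: int, alt: str) -> bool:
    """Does substituting alt at p0 create a new ATG in the 5'UTR?"""
    utr = model.utr5_positions
    idx = {p: i for i, p in enumerate(utr)}
    if p0 not in idx:
        return False
    seq = "".join(model.transcript_base(genome, p) for p in utr)
    i = idx[p0]
    alt_tx = alt if model.strand == "+" else revcomp(alt)
    new = seq[:i] + alt_tx + seq[i + 1:]
    for s in range(max(0, i - 2), min(len(seq) - 2, i + 1)):
        if new[s:s + 3] == "ATG" and seq[s:s + 3] != "ATG":
            return True
    return False


def annotate(
    variant,
    models: list[GeneModel],
    genome: str | dict[str, str],
    upstream_window: int = 5000,
    downstream_window: int = 5000,
) -> list[EffectRecord]:
    """Classify one variant against every overlapping or nearby transcript.

    ``variant`` needs attributes chrom, pos (1-based), ref_allele,
    alt_allele.  Returns one record per transcript whose body or
    upstream/downstream window contains the variant; a single INTERGENIC
    record if none does.
    """
    if isinstance(genome, str):
        seq_ = genome
        genome = {variant.chrom: seq_, **{m.chrom: seq_ for m in models}}
    ref, alt = variant.ref_allele, variant.alt_allele
    is_snp = len(ref) == 1 and len(alt) == 1
    # region decisions use the first altered base (indels are anchored)
    p0 = variant.pos - 1 if is_snp else variant.pos
    key = (variant.chrom, variant.pos, ref, alt)

    records: list[EffectRecord] = []
    for m in models:
        if m.chrom != variant.chrom:
            continue
        seq = genome[m.chrom]
        cat: str | None = None
        if m.tx_start <= p0 < m.tx_end:
            cat = _splice_category(m, p0)
            if cat is None:  # exonic
                if p0 in m._cds_set:
                    if is_snp:
                        cat = _classify_cds_snp(m, seq, p0, alt)
                    else:
                        cat = _classify_cds_indel(ref, alt)
                elif p0 in {*m.utr5_positions}:
                    if is_snp and _start_gained(m, seq, p0, alt):
                        cat = "START_GAINED"
                    else:
                        cat = "UTR_5_PRIME"
                elif p0 in m.utr3_positions:
                    cat = "UTR_3_PRIME"
                elif p0 in m._exonic:
                    cat = "EXON"
                else:  # pragma: no cover - exhaustive over transcript body
                    cat = "INTRON"
        else:
            before = p0 < m.tx_start
            if m.strand == "+":
                if before and m.tx_start - p0 <= upstream_window:
                    cat = "UPSTREAM"
                elif not before and p0 - m.tx_end < downstream_window:
                    cat = "DOWNSTREAM"
            else:
                if not before and p0 - m.tx_end < upstream_window:
                    cat = "UPSTREAM"
                elif before and m.tx_start - p0 <= downstream_window:
                    cat = "DOWNSTREAM"
        if cat is not None:
            records.append(EffectRecord(key, m.gene_id, cat))
    if not records:
        records.append(EffectRecord(key, None, "INTERGENIC"))
    return records


@dataclass
class EffectTally:
    """Counts per category over a set of effect records."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = {c: int(self.counts.get(c, 0)) for c in CATEGORIES}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        """Percentage of total effect records, two decimals."""
        t = self.total
        return {c: round(100 * n / t, 2) if t else 0.0 for c, n in self.counts.items()}


def tally(effects: list[EffectRecord]) -> EffectTally:
    counts: dict[str, int] = {}
    for e in effects:
        counts[e.category] = counts.get(e.category, 0) + 1
    return EffectTally(counts)


def impactful_count(t: EffectTally) -> int:
    """Number of effects in the eight protein-affecting categories."""
    return sum(n for c, n in t.counts.items() if c in IMPACTFUL_CATEGORIES)
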