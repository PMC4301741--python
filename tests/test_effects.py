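"""Effect annotation against gene models, checked against a brute-force oracle."""

import re
from dataclasses import dataclass

import numpy as np
import pytest
from Bio.Seq import Seq

from gtaudit.dnautil import random_dna, revcomp
from gtaudit.effects import (
    CATEGORIES,
    EffectRecord,
    EffectTally,
    GeneModel,
    annotate,
    impactful_count,
    tally,
)
from gtaudit.simulate import SimParams, _make_gene


@dataclass
class Var:
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str


# ---------------------------------------------------------------- oracle


def oracle_snp_category(model: GeneModel, genome: str, p0: int, alt: str,
                        up_w: int, down_w: int) -> str | None:
    """Independent per-position classifier built from interval sets and
    Biopython translation."""
    minus = model.strand == "-"

    if not (model.tx_start <= p0 < model.tx_end):
        if minus:
            up = model.tx_end <= p0 < model.tx_end + up_w
            down = model.tx_start - down_w <= p0 < model.tx_start
        else:
            up = model.tx_start - up_w <= p0 < model.tx_start
            down = model.tx_end <= p0 < model.tx_end + down_w
        return "UPSTREAM" if up else ("DOWNSTREAM" if down else None)

    for (a, b) in zip([e[1] for e in model.exons[:-1]],
                      [e[0] for e in model.exons[1:]]):
        if a <= p0 < b:  # intron
            five_prime = {b - 1, b - 2} if minus else {a, a + 1}
            three_prime = {a, a + 1} if minus else {b - 1, b - 2}
            if p0 in five_prime:
                return "SPLICE_SITE_DONOR"
            if p0 in three_prime:
                return "SPLICE_SITE_ACCEPTOR"
            return "INTRON"

    cds_pos = sorted(p for (a, b) in model.cds for p in range(a, b))
    if p0 in set(cds_pos):
        i = cds_pos.index(p0)
        ref_cds = "".join(genome[p] for p in cds_pos)
        alt_cds = ref_cds[:i] + alt + ref_cds[i + 1:]
        if minus:
            ref_cds, alt_cds = revcomp(ref_cds), revcomp(alt_cds)
            i = len(cds_pos) - 1 - i
        ref_prot = str(Seq(ref_cds).translate())
        alt_prot = str(Seq(alt_cds).translate())
        codon = i // 3
        if codon == 0 and ref_cds[:3] == "ATG" and alt_cds[:3] != "ATG":
            return "START_LOST"
        if alt_prot[codon] == "*" and ref_prot[codon] != "*":
            return "STOP_GAINED"
        return ("SYNONYMOUS_CODING" if ref_prot[codon] == alt_prot[codon]
                else "NON_SYNONYMOUS_CODING")

    # exonic non-CDS: UTRs for coding genes
    if not model.cds:
        return "EXON"
    lo, hi = model.cds[0][0], model.cds[-1][1]
    utr5_genomic = [p for (a, b) in model.exons for p in range(a, b)
                    if (p >= hi if minus else p < lo)]
    if p0 in set(utr5_genomic):
        seq5 = "".join(genome[p] for p in sorted(utr5_genomic))
        idx = sorted(utr5_genomic).index(p0)
        alt5 = seq5[:idx] + alt + seq5[idx + 1:]
        if minus:
            seq5, alt5 = revcomp(seq5), revcomp(alt5)
            idx = len(seq5) - 1 - idx
        before = {m.start() for m in re.finditer("(?=ATG)", seq5)
                  if m.start() <= idx < m.start() + 3}
        after = {m.start() for m in re.finditer("(?=ATG)", alt5)
                 if m.start() <= idx < m.start() + 3}
        return "START_GAINED" if after - before else "UTR_5_PRIME"
    return "UTR_3_PRIME"


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="module")
def toy_genes():
    rng = np.random.default_rng(42)
    host = list(random_dna(rng, 6000, 0.45))
    models = []
    params_rng = np.random.default_rng(7)
    for g0, strand, gid in ((600, "+", "gplus"), (3400, "-", "gminus")):
        model, seq = _make_gene(params_rng, gid, "chr1", g0, strand)
        host[g0:g0 + len(seq)] = seq
        models.append(model)
    return "".join(host), models


# ---------------------------------------------------------------- tests


def test_codon_change_trp_to_leu(toy_genes):
    """A TGG->TTG codon change is a non-synonymous Trp->Leu substitution."""
    genome = "A" * 10 + "ATG" + "TGG" + "TAA" + "A" * 10
    model = GeneModel("g", "chr1", "+", exons=((10, 19),), cds=((10, 19),))
    var = Var("chr1", 15, "G", "T")  # middle G of TGG
    recs = annotate(var, [model], genome)
    assert [r.category for r in recs] == ["NON_SYNONYMOUS_CODING"]


def test_indel_length_rule():
    genome = "A" * 10 + "ATG" + "CCTGGTCGA" + "TAA" + "A" * 10
    model = GeneModel("g", "chr1", "+", exons=((10, 25),), cds=((10, 25),))
    del1 = Var("chr1", 14, "CC", "C")       # 1 bp CDS deletion
    del3 = Var("chr1", 14, "CCTG", "C")     # 3 bp CDS deletion
    ins2 = Var("chr1", 14, "C", "CAT")      # 2 bp CDS insertion
    assert annotate(del1, [model], genome)[0].category == "FRAME_SHIFT"
    assert annotate(del3, [model], genome)[0].category == \
        "CODON_CHANGE_PLUS_CODON_DELETION"
    assert annotate(ins2, [model], genome)[0].category == "FRAME_SHIFT"


def test_start_and_stop_events():
    genome = "A" * 10 + "ATG" + "TGG" + "TAC" + "TAA" + "A" * 10
    model = GeneModel("g", "chr1", "+", exons=((10, 22),), cds=((10, 22),))
    start_lost = Var("chr1", 11, "A", "C")
    assert annotate(start_lost, [model], genome)[0].category == "START_LOST"
    # TAC -> TAA creates a premature stop
    stop_gained = Var("chr1", 19, "C", "A")
    assert annotate(stop_gained, [model], genome)[0].category == "STOP_GAINED"


@pytest.mark.parametrize("strand_idx", [0, 1])
def test_annotator_matches_brute_force_oracle(toy_genes, strand_idx):
    """Per-position SNP classification equals the independent oracle over
    an entire toy gene and its flanks, on both strands."""
    genome, models = toy_genes
    model = models[strand_idx]
    up_w = down_w = 300
    mismatches = []
    for p0 in range(model.tx_start - 400, model.tx_end + 400):
        ref = genome[p0]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        var = Var("chr1", p0 + 1, ref, alt)
        recs = annotate(var, [model], genome, up_w, down_w)
        got = recs[0].category
        want = oracle_snp_category(model, genome, p0, alt, up_w, down_w)
        if want is None:
            want = "INTERGENIC"
        if got != want:
            mismatches.append((p0, got, want))
    assert not mismatches, mismatches[:10]


def test_strand_symmetry(toy_genes):
    """Reverse-complementing genome, models and variants leaves the
    category tally unchanged."""
    genome, models = toy_genes
    L = len(genome)
    rc_genome = revcomp(genome)

    def flip_model(m: GeneModel) -> GeneModel:
        flip = lambda iv: (L - iv[1], L - iv[0])
        return GeneModel(m.gene_id, m.chrom, "-" if m.strand == "+" else "+",
                         tuple(sorted(flip(e) for e in m.exons)),
                         tuple(sorted(flip(c) for c in m.cds)))

    rng = np.random.default_rng(3)
    variants = []
    for _ in range(300):
        p0 = int(rng.integers(0, L))
        ref = genome[p0]
        alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
        variants.append(Var("chr1", p0 + 1, ref, alt))

    fwd = [r.category for v in variants for r in annotate(v, models, genome)]
    rc_models = [flip_model(m) for m in models]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc_vars = [Var("chr1", L - v.pos + 1, comp[v.ref_allele], comp[v.alt_allele])
               for v in variants]
    rev = [r.category for v in rc_vars for r in annotate(v, rc_models, rc_genome)]
    assert tally([EffectRecord((), None, c) for c in fwd]).counts == \
        tally([EffectRecord((), None, c) for c in rev]).counts


def test_every_variant_annotated_and_categories_closed(toy_genes):
    genome, models = toy_genes
    rng = np.random.default_rng(9)
    for _ in range(200):
        p0 = int(rng.integers(0, len(genome)))
        ref = genome[p0]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        recs = annotate(Var("chr1", p0 + 1, ref, alt), models, genome)
        assert len(recs) >= 1
        assert all(r.category in CATEGORIES for r in recs)


def test_tally_percentages_and_impactful():
    bs998 = {
        "FRAME_SHIFT": 0, "NON_SYNONYMOUS_CODING": 14,
        "CODON_CHANGE_PLUS_CODON_DELETION": 0, "START_GAINED": 2,
        "START_LOST": 2, "STOP_GAINED": 0, "SPLICE_SITE_ACCEPTOR": 1,
        "SPLICE_SITE_DONOR": 0, "SYNONYMOUS_CODING": 5, "EXON": 5,
        "INTRON": 99, "UTR_3_PRIME": 22, "UTR_5_PRIME": 11,
        "UPSTREAM": 395, "DOWNSTREAM": 414, "INTERGENIC": 695,
    }
    t = EffectTally(bs998)
    assert t.total == 1665
    assert t.percentages["NON_SYNONYMOUS_CODING"] == 0.84
    assert impactful_count(t) == 19
    bs121 = EffectTally({
        "FRAME_SHIFT": 6, "NON_SYNONYMOUS_CODING": 37, "START_GAINED": 3,
        "STOP_GAINED": 12, "SPLICE_SITE_ACCEPTOR": 1, "SPLICE_SITE_DONOR": 1})
    assert impactful_count(bs121) == 60
    assert impactful_count(EffectTally({})) == 0
    assert tally([]).total == 0


def test_percentages_sum_to_100(toy_genes):
    genome, models = toy_genes
    rng = np.random.default_rng(4)
    effects = []
    for _ in range(500):
        p0 = int(rng.integers(0, len(genome)))
        ref = genome[p0]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        effects.extend(annotate(Var("chr1", p0 + 1, ref, alt), models, genome))
    t = tally(effects)
    assert abs(sum(t.percentages.values()) - 100) < 0.01 * len(CATEGORIES)
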