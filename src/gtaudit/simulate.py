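"""Synthetic study generator.

Builds every input the audit pipeline consumes, with the statistical
structure the downstream analysis assumes: a diploid host genome carrying
gene models, an integration vector split into T-DNA and backbone, a panel
of foreign (donor-bacterium) replicons, tissue-culture point mutations
induced heterozygous in each regenerated T0 plant, Mendelian selfing
segregation to later generations, per-line variant calls with
depth/quality and callable masks, short reads (optionally containing an
integrated vector), and two-channel tiling-array intensities.

Default parameters mirror the study design being emulated: four lines
(two T2 siblings of one regenerant, one of which carries a homozygous and
the other a heterozygous vector insertion, plus two clean T3 lines),
sequencing depth peaks {8, 4, 6, 10}, 76 b reads, ~500 induced mutations
per regenerant with the published tissue-culture substitution spectrum,
and 25% of induced events being short indels.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np

from .audit import SPECTRUM_CLASSES, CallableMask, VariantCall
from .cgh import ProbeSet
from .dnautil import BASES, random_dna, revcomp
from .effects import GeneModel
from .screen import Read

#: pooled homozygous-SNP substitution spectrum of the four published lines
DEFAULT_SPECTRUM = {
    "AT→GC": 56 / 364,
    "GC→AT": 134 / 364,
    "AT→CG": 19 / 364,
    "AT→TA": 42 / 364,
    "GC→CG": 29 / 364,
    "GC→TA": 84 / 364,
}

#: ref-base requirement and alt base per strand-symmetric class
_CLASS_MOVES = {
    "AT→GC": {"A": "G", "T": "C"},
    "GC→AT": {"G": "A", "C": "T"},
    "AT→CG": {"A": "C", "T": "G"},
    "AT→TA": {"A": "T", "T": "A"},
    "GC→CG": {"G": "C", "C": "G"},
    "GC→TA": {"G": "T", "C": "A"},
}


@dataclass
class SimParams:
    """Knobs of the synthetic study; one seed makes everything deterministic."""

    seed: int = 0
    n_t0_mutations: int = 500
    n_background_polymorphisms: int = 2000
    spectrum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM))
    indel_fraction: float = 0.25
    depth_mean: float = 8.0
    depth_by_line: dict[str, float] = field(
        default_factory=lambda: {"BSR-12-1": 8.0, "BSR-12-2": 4.0,
                                 "BSR-9-9-8": 6.0, "BSR-59-8-5": 10.0})
    quality_per_read: float = 3.0       # phred-like proxy; monotone in support
    quality_cap: float = 60.0
    read_length: int = 76
    error_rate: float = 0.001
    false_positive_rate: float = 0.0    # spurious het calls per base
    background_het_fraction: float = 0.0
    cgh_noise_sigma: float = 0.1        # log-normal sigma (natural log)
    background_fraction: float = 0.02   # CGH additive background b/a
    gc: float = 0.44

    def __post_init__(self) -> None:
        w = self.spectrum_weights
        if any(v < 0 for v in w.values()) or abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("spectrum weights must be nonnegative and sum to 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")

    def line_depth(self, line: str) -> float:
        return self.depth_by_line.get(line, self.depth_mean)


@dataclass
class LinePlan:
    """One sequenced plant line and its breeding history."""

    name: str
    generation: int                   # selfing rounds since T0
    sibling_group: str                # label shared by lines from one T0 plant
    vector_insertion: str = "none"    # none | het | homo
    insertion_site: int | None = None
    gt_zygosity: str = "hom"          # edited-locus genotype for CAPS

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise ValueError("generation must be >= 0")
        if (self.insertion_site is None) != (self.vector_insertion == "none"):
            raise ValueError("insertion_site must be set iff an insertion exists")


def default_line_plans(insertion_site: int = 50_000) -> list[LinePlan]:
    """The emulated four-line design: two T2 siblings with a vector
    insertion (homozygous / heterozygous), two clean T3 lines."""
    return [
        LinePlan("BSR-12-1", 2, "BSR-12", "homo", insertion_site),
        LinePlan("BSR-12-2", 2, "BSR-12", "het", insertion_site),
        LinePlan("BSR-9-9-8", 3, "BSR-9"),
        LinePlan("BSR-59-8-5", 3, "BSR-59"),
    ]


@dataclass
class ReferenceBundle:
    """Host genome, gene models, vector and foreign-sequence panel."""

    chrom: str
    host_sequence: str
    gene_models: list[GeneModel]
    vector_sequence: str
    t_dna_interval: tuple[int, int]
    backbone_interval: tuple[int, int]
    foreign_panel: dict[str, str]
    ploidy: int = 2

    def __post_init__(self) -> None:
        (a, b), (c, d) = sorted([self.t_dna_interval, self.backbone_interval])
        if not (a == 0 and b == c and d == len(self.vector_sequence)):
            raise ValueError("t_dna and backbone must be disjoint and cover the vector")

    @property
    def t_dna(self) -> str:
        a, b = self.t_dna_interval
        return self.vector_sequence[a:b]

    @property
    def backbone(self) -> str:
        a, b = self.backbone_interval
        return self.vector_sequence[a:b]


@dataclass
class TrueVariant:
    chrom: str
    pos: int                    # 1-based
    ref_allele: str
    alt_allele: str
    vtype: str                  # SNP | insertion | deletion
    origin: str                 # background_polymorphism | induced_T0
    t0_group: str | None = None
    zygosity_by_line: dict[str, str] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def is_snp(self) -> bool:
        return self.vtype == "SNP"


@dataclass
class TruthSet:
    variants: list[TrueVariant] = field(default_factory=list)

    def positions(self) -> set[int]:
        return {v.pos for v in self.variants}

    def by_origin(self, origin: str) -> list[TrueVariant]:
        return [v for v in self.variants if v.origin == origin]


# ---------------------------------------------------------------- reference


def _make_gene(rng: np.random.Generator, gene_id: str, chrom: str,
               g0: int, strand: str) -> tuple[GeneModel, str]:
    """One 3-exon coding gene; returns the model and its genomic sequence."""
    utr5_len = int(rng.integers(60, 121))
    utr3_len = int(rng.integers(90, 181))
    cds_codons = [int(rng.integers(40, 90)) for _ in range(3)]
    intron_lens = [int(rng.integers(80, 161)) for _ in range(2)]

    sense_codons = [c for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
                    if c not in {"TAA", "TAG", "TGA"}]
    def codons(n: int) -> str:
        return "".join(sense_codons[i] for i in rng.integers(0, len(sense_codons), n))

    cds_parts = [codons(cds_codons[0]), codons(cds_codons[1]), codons(cds_codons[2])]
    cds_parts[0] = "ATG" + cds_parts[0][3:]
    cds_parts[2] = cds_parts[2][:-3] + "TAA"
    introns = ["GT" + random_dna(rng, n - 4) + "AG" for n in intron_lens]

    elements = [
        ("utr5", random_dna(rng, utr5_len, 0.5)),
        ("cds", cds_parts[0]),
        ("intron", introns[0]),
        ("cds", cds_parts[1]),
        ("intron", introns[1]),
        ("cds", cds_parts[2]),
        ("utr3", random_dna(rng, utr3_len, 0.5)),
    ]
    tx_seq = "".join(s for _, s in elements)
    total = len(tx_seq)

    # transcript-order offsets -> genomic intervals
    offs, cur = [], 0
    for kind, s in elements:
        offs.append((kind, cur, cur + len(s)))
        cur += len(s)

    def to_genomic(a: int, b: int) -> tuple[int, int]:
        if strand == "+":
            return (g0 + a, g0 + b)
        return (g0 + total - b, g0 + total - a)

    exon_ivals, cds_ivals = [], []
    # exons: maximal runs of non-intron elements
    run_start = None
    prev_end = 0
    for kind, a, b in offs + [("intron", total, total)]:
        if kind != "intron":
            if run_start is None:
                run_start = a
            prev_end = b
        else:
            if run_start is not None:
                exon_ivals.append(to_genomic(run_start, prev_end))
                run_start = None
        if kind == "cds":
            cds_ivals.append(to_genomic(a, b))

    genomic_seq = tx_seq if strand == "+" else revcomp(tx_seq)
    model = GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        exons=tuple(sorted(exon_ivals)), cds=tuple(sorted(cds_ivals)),
    )
    return model, genomic_seq


def generate_reference(
    params: SimParams,
    l_host: int = 100_000,
    n_genes: int = 20,
    vector_length: int = 4000,
    t_dna_length: int = 1500,
    chrom: str = "chr1",
) -> ReferenceBundle:
    """Host genome with embedded gene models, vector and foreign panel.

    Gene models are packed left to right with random intergenic gaps;
    packing that cannot fit raises.  The vector is regenerated until it
    shares no 20-mer with the host, which guarantees the read screen has
    host-unique sequence to latch onto.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 101]))
    host = list(random_dna(rng, l_host, params.gc))

    max_gene = 120 + 180 + 3 * 270 + 2 * 160 + 10
    min_gap = 400
    if n_genes * (max_gene + min_gap) + min_gap > l_host:
        raise ValueError(
            f"cannot pack {n_genes} gene models into {l_host} bp "
            f"(need about {n_genes * (max_gene + min_gap) + min_gap})"
        )
    models: list[GeneModel] = []
    slack = l_host - n_genes * (max_gene + min_gap) - min_gap
    cursor = min_gap
    for i in range(n_genes):
        cursor += int(rng.integers(0, max(1, slack // max(n_genes, 1))))
        strand = "+" if rng.random() < 0.5 else "-"
        model, seq = _make_gene(rng, f"gene{i:03d}", chrom, cursor, strand)
        host[cursor:cursor + len(seq)] = seq
        models.append(model)
        cursor += max_gene + min_gap
    host_seq = "".join(host)

    def host_has(kmer_seq: str, k: int = 20) -> bool:
        return any(
            kmer_seq[i:i + k] in host_seq or revcomp(kmer_seq[i:i + k]) in host_seq
            for i in range(0, len(kmer_seq) - k + 1, k)
        )

    while True:
        vector = random_dna(rng, vector_length, 0.55)
        if not host_has(vector):
            break
    foreign = {
        "donor_circular_chromosome": random_dna(rng, 3000, 0.58),
        "donor_linear_chromosome": random_dna(rng, 3000, 0.58),
        "donor_plasmid_at": random_dna(rng, 2000, 0.55),
        "donor_plasmid_ti": random_dna(rng, 2000, 0.55),
    }
    return ReferenceBundle(
        chrom=chrom,
        host_sequence=host_seq,
        gene_models=models,
        vector_sequence=vector,
        t_dna_interval=(0, t_dna_length),
        backbone_interval=(t_dna_length, vector_length),
        foreign_panel=foreign,
    )


# ---------------------------------------------------------------- variants


def _spawn(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def _stable_hash(s: str | None) -> int:
    """Process-independent string hash (unlike builtin hash, which is salted)."""
    return zlib.crc32((s or "").encode()) & 0x7FFFFFFF


def induce_t0_mutations(
    ref: ReferenceBundle,
    n: int,
    spectrum: dict[str, float],
    seed: int,
    indel_fraction: float = 0.25,
    t0_group: str | None = None,
    exclude: set[int] | None = None,
    origin: str = "induced_T0",
) -> TruthSet:
    """Draw ``n`` point mutations, heterozygous in the T0 regenerant.

    SNP classes follow ``spectrum`` (the six strand-symmetric classes);
    ``indel_fraction`` of events are 1-3 bp anchored indels.  Positions
    are unique and avoid ``exclude``.
    """
    if abs(sum(spectrum.values()) - 1.0) > 1e-9 or any(v < 0 for v in spectrum.values()):
        raise ValueError("spectrum weights must be nonnegative and sum to 1")
    rng = _spawn(seed, 211, _stable_hash(t0_group))
    host = ref.host_sequence
    L = len(host)
    if n > L // 4:
        raise ValueError("n exceeds the number of eligible sites")
    used: set[int] = set(exclude or ())
    classes = list(SPECTRUM_CLASSES)
    weights = np.array([spectrum[c] for c in classes])
    weights = weights / weights.sum()
    out: list[TrueVariant] = []

    def fresh_position(want_bases: str | None) -> int:
        # the class is fixed before position sampling so base availability
        # cannot skew the class distribution
        for _ in range(10_000):
            p0 = int(rng.integers(1, L - 5))  # keep room for anchors/indels
            if p0 in used or (p0 + 1) in used:
                continue
            if want_bases is None or host[p0] in want_bases:
                return p0
        raise ValueError("n exceeds the number of eligible sites")

    while len(out) < n:
        if rng.random() < indel_fraction:
            p0 = fresh_position(None)
            length = int(rng.integers(1, 4))
            anchor = host[p0 - 1]
            if rng.random() < 0.5 and p0 + length < L:
                v = TrueVariant(ref.chrom, p0, anchor + host[p0:p0 + length],
                                anchor, "deletion", origin, t0_group)
            else:
                ins = random_dna(rng, length)
                v = TrueVariant(ref.chrom, p0, anchor, anchor + ins,
                                "insertion", origin, t0_group)
            # indel pos records the anchor (1-based p0-1+1 == p0)
        else:
            cls = classes[int(rng.choice(len(classes), p=weights))]
            moves = _CLASS_MOVES[cls]
            p0 = fresh_position("".join(moves))
            base = host[p0]
            v = TrueVariant(ref.chrom, p0 + 1, base, moves[base], "SNP",
                            origin, t0_group)
        used.add(v.pos)
        used.add(p0)
        out.append(v)
    out.sort(key=lambda v: v.pos)
    return TruthSet(out)


def make_background_polymorphisms(
    ref: ReferenceBundle, n: int, spectrum: dict[str, float], seed: int,
    indel_fraction: float = 0.12, exclude: set[int] | None = None,
) -> TruthSet:
    """Divergence between the sequenced stock and the reference assembly,
    present in every line (homozygous by default)."""
    ts = induce_t0_mutations(
        ref, n, spectrum, seed, indel_fraction, t0_group="__background__",
        exclude=exclude, origin="background_polymorphism",
    )
    for v in ts.variants:
        v.t0_group = None
    return ts


def segregate(truth: TruthSet, plans: list[LinePlan], seed: int,
              background_het_fraction: float = 0.0) -> TruthSet:
    """Fill per-line zygosities by simulating selfing segregation.

    Induced variants start heterozygous in the T0 ancestor of their
    sibling group; each selfing round sends het -> hom_alt with p=1/4,
    keeps het with p=1/2, loses it with p=1/4, independently per variant
    and per lineage (sibling lines share the T0 plant, then segregate
    independently).  Background polymorphisms are homozygous-alt in every
    line (optionally a fraction is made uniformly heterozygous).
    """
    for plan in plans:
        if plan.generation < 0:
            raise ValueError("negative generation")
    rng = _spawn(seed, 307)
    for v in truth.variants:
        if v.origin == "background_polymorphism":
            z = "het" if rng.random() < background_het_fraction else "hom_alt"
            v.zygosity_by_line = {p.name: z for p in plans}
            continue
        v.zygosity_by_line = {}
        for plan in plans:
            if plan.sibling_group != v.t0_group:
                v.zygosity_by_line[plan.name] = "hom_ref"
                continue
            state = "het"
            for _ in range(plan.generation):
                if state != "het":
                    break
                u = rng.random()
                state = "hom_alt" if u < 0.25 else ("het" if u < 0.75 else "hom_ref")
            v.zygosity_by_line[plan.name] = state
    return truth


# ---------------------------------------------------------------- calls


@dataclass
class SimulatedCalls:
    """Per-line call sets plus the per-base depth they were drawn from."""

    chrom: str
    callsets: dict[str, list[VariantCall]]
    depth: dict[str, np.ndarray]

    def callable_mask(self, line: str, depth_threshold: int = 1) -> CallableMask:
        return CallableMask({self.chrom: self.depth[line] >= depth_threshold})

    def callable_masks(self, depth_threshold: int = 1) -> dict[str, CallableMask]:
        return {line: self.callable_mask(line, depth_threshold)
                for line in self.depth}


def simulate_variant_calls(
    truth: TruthSet,
    plans: list[LinePlan],
    params: SimParams,
    genome_length: int,
    chrom: str = "chr1",
) -> SimulatedCalls:
    """Emulate mapping+calling: Poisson depth, binomial allele sampling.

    Per line and truth site, depth ~ Poisson(line depth mean).  A
    homozygous-alt site yields a hom_alt call whenever at least one alt
    read and no ref read is seen; a het site yields a het call when both
    alleles are sampled.  Call quality is a monotone proxy of the
    supporting-read count (3 per read, capped at 60).  Sequencing errors
    flip individual reads at ``error_rate``.
    """
    rng = _spawn(params.seed, 401)
    callsets: dict[str, list[VariantCall]] = {}
    depths: dict[str, np.ndarray] = {}
    q = params.quality_per_read
    qcap = params.quality_cap
    e = params.error_rate
    for plan in plans:
        dm = params.line_depth(plan.name)
        depth = rng.poisson(dm, size=genome_length).astype(np.int32)
        calls: list[VariantCall] = []
        for v in truth.variants:
            z = v.zygosity_by_line.get(plan.name, "hom_ref")
            if z == "hom_ref":
                continue
            d = int(depth[v.pos - 1])
            if d == 0:
                continue
            p_alt = (1 - e) if z == "hom_alt" else 0.5
            alt_reads = int(rng.binomial(d, p_alt))
            ref_reads = d - alt_reads
            if alt_reads == 0:
                continue
            zyg = "hom_alt" if ref_reads == 0 else "het"
            calls.append(VariantCall(
                line=plan.name, chrom=v.chrom, pos=v.pos,
                ref_allele=v.ref_allele, alt_allele=v.alt_allele,
                zygosity=zyg, depth=alt_reads,
                quality=min(round(q * alt_reads), qcap),
            ))
        n_fp = rng.poisson(params.false_positive_rate * genome_length)
        taken = truth.positions()
        for _ in range(int(n_fp)):
            pos = int(rng.integers(1, genome_length))
            if pos in taken:
                continue
            d = max(1, int(depth[pos - 1]))
            support = min(1 + int(rng.integers(0, 2)), d)
            fp_ref = "ACGT"[int(rng.integers(0, 4))]
            fp_alt = "ACGT"[("ACGT".index(fp_ref) + int(rng.integers(1, 4))) % 4]
            calls.append(VariantCall(
                line=plan.name, chrom=chrom, pos=pos, ref_allele=fp_ref,
                alt_allele=fp_alt, zygosity="het",
                depth=support, quality=min(round(q * support), qcap),
            ))
        calls.sort(key=lambda c: c.pos)
        callsets[plan.name] = calls
        depths[plan.name] = depth
    return SimulatedCalls(chrom=chrom, callsets=callsets, depth=depths)


# ---------------------------------------------------------------- reads


def simulate_reads(
    genome: str,
    n_reads: int,
    read_length: int,
    error_rate: float,
    seed: int,
    name_prefix: str = "read",
    base_quality: int = 40,
    both_strands: bool = False,
) -> list[Read]:
    """Uniform-start error-prone reads with flat base qualities.

    With ``both_strands`` off (the default sampling model) every
    error-free read is an exact substring of the genome; switching it on
    reverse-complements half the reads.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    rng = _spawn(seed, 503)
    starts = rng.integers(0, len(genome) - read_length + 1, size=n_reads)
    reads: list[Read] = []
    qual = np.full(read_length, base_quality, dtype=np.int16)
    for i, s in enumerate(starts):
        seq = genome[int(s):int(s) + read_length]
        if error_rate > 0:
            errs = np.flatnonzero(rng.random(read_length) < error_rate)
            if errs.size:
                sl = list(seq)
                for j in errs:
                    sl[j] = BASES[(BASES.index(sl[j]) + int(rng.integers(1, 4))) % 4]
                seq = "".join(sl)
        if both_strands and rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(Read(f"{name_prefix}_{i:07d}", seq, qual.copy()))
    return reads


def line_haplotypes(ref: ReferenceBundle, plan: LinePlan) -> tuple[str, str]:
    """The two haploid genome sequences of a line, with any vector insertion."""
    host = ref.host_sequence
    if plan.vector_insertion == "none":
        return host, host
    s = plan.insertion_site
    with_ins = host[:s] + ref.vector_sequence + host[s:]
    if plan.vector_insertion == "homo":
        return with_ins, with_ins
    return with_ins, host


def simulate_line_reads(
    ref: ReferenceBundle,
    plan: LinePlan,
    coverage: float,
    params: SimParams,
    seed_salt: int = 0,
) -> list[Read]:
    """Reads for one line at the given fold coverage, diploid-aware."""
    hap1, hap2 = line_haplotypes(ref, plan)
    n_total = int(round(coverage * len(ref.host_sequence) / params.read_length))
    rng = _spawn(params.seed, 601, seed_salt)
    n1 = int(rng.binomial(n_total, 0.5))
    r1 = simulate_reads(hap1, n1, params.read_length, params.error_rate,
                        int(rng.integers(2**31)), f"{plan.name}_h1")
    r2 = simulate_reads(hap2, n_total - n1, params.read_length, params.error_rate,
                        int(rng.integers(2**31)), f"{plan.name}_h2")
    return r1 + r2


# ---------------------------------------------------------------- CGH


def vector_probe_copies(probes: ProbeSet, insertion: str) -> np.ndarray:
    """Per-probe copy number (per diploid genome) for a test line."""
    per_copy = {"none": 0.0, "het": 1.0, "homo": 2.0}[insertion]
    copies = np.empty(len(probes.probes))
    for i, p in enumerate(probes.probes):
        if p.source == "host_region":
            copies[i] = 2.0
        elif p.source == "control":
            copies[i] = 2.0
        else:
            copies[i] = per_copy
    return copies


def simulate_cgh(
    probes: ProbeSet,
    copies_test: np.ndarray,
    copies_ref: np.ndarray,
    params: SimParams,
    seed_salt: int = 0,
    gain: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw two-channel intensities under a linear signal model.

    intensity = gain * (copies + background_fraction), multiplied by
    independent log-normal noise per probe and channel.  Control probes
    carry their nominal copy number (2) in both channels.
    """
    if params.cgh_noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    rng = _spawn(params.seed, 701, seed_salt)
    b = params.background_fraction
    n = len(probes.probes)
    copies_test = np.asarray(copies_test, dtype=float)
    copies_ref = np.asarray(copies_ref, dtype=float)
    if len(copies_test) != n or len(copies_ref) != n:
        raise ValueError("copy vectors must align with the probe set")

    def channel(copies: np.ndarray) -> np.ndarray:
        signal = gain * (copies + b)
        if params.cgh_noise_sigma > 0:
            signal = signal * rng.lognormal(0.0, params.cgh_noise_sigma, n)
        return signal

    return channel(copies_test), channel(copies_ref)
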