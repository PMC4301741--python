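# Methods

## Scope and design

`gtaudit` is a desk-scale reimplementation of the molecular-characterization
analyses applied to gene-targeted rice lines: exogenous-sequence screening,
copy-number array analysis, CAPS genotyping, somaclonal-variant auditing and
T0 load back-estimation.  Production aligners and callers (BWA, SAMtools,
GATK, snpEff) are deliberately replaced by transparent equivalents that are
exact on the synthetic data the package generates; the package makes no
claim of production variant calling on real sequencing data.

## Selfing-fixation model

Mutations induced in cultured cells are heterozygous in the regenerated T0
plant.  Selfing transmits each such site per generation as het →
{¼ hom-mutant, ½ het, ¼ hom-wild-type}; homozygous states are absorbing.
Closed form after g generations: p_het = 2⁻ᵍ, p_hom = p_lost = (1−2⁻ᵍ)/2.
The estimator divides the observed homozygous line-specific count by the
shared-callable genome fraction f and by p_hom(g).  Assumptions: strict
selfing (no outcrossing), no selection against mutant alleles, a
non-chimeric T0, and independence across sites.  Arithmetic is unrounded
throughout; rounding (nearest, ties away from zero) happens only at
presentation, because totals and sibling averages computed from pre-rounded
class estimates differ visibly from the correct values.

The study-level estimate pools per-line estimates: sibling lines (same T0)
are averaged first, then groups.  Its 95% interval is a parametric
bootstrap (default 200 replicates): each replicate redraws every line's
homozygous count as Binomial(N̂, p_hom(g)·f) and recomputes the pooled
estimate.  A naive resampling of observed calls would omit the segregation
stage's Binomial variance and understate the interval roughly twofold.

## Variant audit

Filters are named DP*d*Q*q*: a call survives with supporting-read depth ≥ d
and quality ≥ q (DP2Q10 and DP4Q20 are predefined).  Background
polymorphisms — divergence between the sequenced stock and the reference
assembly — are identified by sharing: a variant carried by ≥ 2 lines whose
carriers span more than one sibling group cannot be an independent
tissue-culture event and is subtracted.  "Two or more" rather than "more
than two" is used, since with four lines a stricter threshold would make
the sibling-pair exception vacuous; the threshold is configurable.
Subtraction runs before restriction to the shared-callable region by
default (the order is configurable; it matters only for variants callable
in a single line).

Substitutions collapse into six strand-symmetric classes (G→A ≡ C→T, etc.).
Percentages are reported to one decimal, Ti/Tv to two.  The multi-line
Ti/Tv average is the mean of the per-line ratios *after* each is rounded to
two decimals — the convention under which the canonical per-line values
(1.03, 1.10, 1.44, 0.89) average to 1.115 rather than 1.114.

## Effect annotation

Sixteen categories; one record per variant × transcript, with no severity
collapsing, so totals may exceed variant counts.  Rules: CDS SNPs are
translated with the standard code (START_LOST for a destroyed initiator
ATG, STOP_GAINED for a nonsense codon); CDS indels are FRAME_SHIFT when
length mod 3 ≠ 0, in-frame deletions are CODON_CHANGE_PLUS_CODON_DELETION,
and in-frame insertions — which have no category of their own here — are
tallied as EXON with a logged warning.  Splice sites are the first/last
2 bp of an intron (donor at the intron's 5' end).  A 5'UTR substitution
creating an ATG is START_GAINED.  Upstream/downstream windows default to
5 kb, strand-aware.  The eight categories through SPLICE_SITE_DONOR are
flagged protein-affecting.  Positions inside a splice site take the splice
category even when also exonic-adjacent; the annotator is validated
position-by-position against an independent brute-force classifier on toy
genes of both strands.

## Exogenous-sequence screen

Read QC trims bases below quality 20 from both ends, strips configured
adapter prefixes and discards reads shorter than 20 b.  Mapping is
replaced by exact 31-mer lookup: a read supports a foreign reference only
through canonical 31-mers present in that reference and absent from the
host genome, which stands in for a unique-mapping requirement and is
deterministic.  Presence requires ≥ 3 hit reads and ≥ 1% of the reference
covered by matching k-mers.  Gapped alignment and junction resolution are
out of scope.

## Tiling array

Probes are 60-mers: one strand of the host region every 60 bp, both vector
strands every 5 bp, plus 13 control probes.  The signal model is linear in
copy number with a small additive background, intensity = a·(c + b)·ε,
with b = 0.02 relative background and log-normal noise ε (σ = 0.1 by
default); this makes a homozygous insertion's ratio double a heterozygous
one's, the discriminating observable.  Each channel is normalized by its
control-probe median; log2 ratios are smoothed by centered moving averages
(windows 1/5/10/20 probes) whose window shrinks symmetrically at track
ends — this preserves constant tracks and equals the plain centered mean
in the interior, at the cost of exact global mean conservation at the
edges.  Aberrant intervals are maximal same-sign runs scored
|mean|·√n / robust-SD(track) with threshold 4.0, minimum 5 probes, and a
fuzzy-zero floor of 0.3 on |mean| (a published aberration-filter parameter
of "3" is implausible on a log2 scale for one-copy events and is read as
0.3; both are accepted via configuration).  Host-context copy states use
the conventional bands (+0.6 one-copy gain, ≥ +1 two-copy, −1 one-copy
loss, ≤ −2 two-copy) with ±0.2 tolerance; vector-context zygosity compares
a line's mean against a known heterozygous companion (log2 difference
1.0 ± 0.3 → homozygous).

## CAPS genotyping

Virtual PCR requires each primer to match the template exactly once in the
correct orientation; digestion cuts C^AATTG at every MfeI site.  The real
edited-locus sequence is not public, so a synthetic fixture places the two
editable codon contexts (CAATGG → CAATTG via TGG→TTG; CAAGTG → CAATTG via
AGT→ATT) such that the cuts fall 1,751 and 2,050 bp from the forward-primer
end of a 2,287 bp amplicon, reproducing the canonical fragment multiset
{1,751, 299, 237}; which amplicon end the 237 bp fragment abuts is a
fixture convention, not an assertion.

## Ranked partial validation

Candidates are ranked by caller quality (rank 1 best).  With consistent
outcomes (failures forming the bottom of the validated block) the estimate
of truly existing candidates is the number ranked strictly above the
best-ranked failure; no failures keeps all n.  Inconsistent outcomes fall
back to the lowest-ranked confirmation.  This single rule reproduces both
canonical worked cases (39 of 45 validated-from-below; 13 of 121
validated-from-above); it is one consistent reading of a procedure that is
defined only through those two examples.

## Synthetic-data generator

The generator emulates the emulated study's structure, not sequencing
physics.  Defaults: a 100 kb single-chromosome diploid host at GC 0.44
(rice-like) carrying 20 three-exon gene models with canonical GT…AG
introns; a 4 kb vector split into T-DNA and backbone, regenerated until it
shares no 20-mer with the host (guaranteeing screenability); four lines —
two T2 siblings of one regenerant carrying a homozygous / heterozygous
vector insertion and two clean T3 lines; 500 induced mutations per
regenerant drawn from the pooled published tissue-culture substitution
spectrum with 25% short (1–3 bp) anchored indels; 2,000 background
polymorphisms homozygous in all lines; per-line sequencing depth means
{8, 4, 6, 10} (the study's depth-distribution peaks) with Poisson site
depth and binomial allele sampling; 76 b reads with substitution errors at
10⁻³; call quality is the monotone proxy 3 × supporting reads capped at 60
(only the thresholds 10/20 are ever compared against, so any monotone map
serves).  Callable masks are depth thresholds; the pipeline derives each
filter profile's mask at the profile's effective depth
max(min_depth, ⌈min_quality/3⌉), keeping the coverage correction f
consistent with the calls it corrects.  With the default depth means this
yields f ≈ 0.46 at DP2Q10's effective depth.

Not modelled: mapping ambiguity and repeats, indel realignment artefacts,
base-quality miscalibration, structural variants beyond one clean vector
insertion, chimeric regenerants.  Passing tests therefore demonstrate the
statistical correctness of the analysis logic under the stated generative
model, not robustness to real-data artefacts.

## Problem sizes and numerical choices

Tests and examples run genomes of 50–200 kb with hundreds to thousands of
variants — sizes at which every distributional check retains power while
the whole suite stays interactive.  Monte-Carlo assertions use 3–4
standard-error tolerances at stated n; the chi-square spectrum test uses
α = 0.01 at n = 10,000.  All randomness flows from explicit integer seeds
through per-stage `numpy` `SeedSequence` spawns keyed by stable constants
(and a CRC32 of group labels, never Python's salted `hash`), so every
artifact is byte-reproducible.  Ties in rounding are resolved away from
zero; none of the canonical table values sits on an exact .5 under exact
rational arithmetic.

## Known limitations

The DP4Q20 profile is punishing under the synthetic quality proxy
(effective depth 7), so lines simulated at depth mean 4 report near-zero
DP4Q20 counts; this is a property of the proxy, not of the estimator.  The
screen cannot place an insertion breakpoint; the array cannot see
insertions shorter than a probe step; the annotator handles one transcript
per gene and the standard genetic code only.
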