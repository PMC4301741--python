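"""Selfing-fixation model and back-estimation of T0 somaclonal mutation loads.

A mutation arising in a regenerated T0 plant is heterozygous.  Under strict
self-fertilisation each heterozygous site segregates per generation as
het -> {1/4 homozygous-mutant, 1/2 het, 1/4 homozygous wild type}, the
homozygous states being absorbing.  After g selfing rounds

    p_hom(g)  = (1 - 2**-g) / 2
    p_het(g)  = 2**-g
    p_lost(g) = p_hom(g)

so a T3 plant (g=3) retains 43.75% of its T0 mutations as homozygous and
12.5% as heterozygous.  Observed homozygous line-specific variant counts,
corrected for the genome fraction callable in every compared sample, are
divided by p_hom(g) to estimate the original T0 mutation load.

All arithmetic is carried unrounded; rounding (nearest integer, ties away
from zero) is applied only when presenting a value.  Totals and sibling
averages are computed from the unrounded per-class estimates and rounded
last — rounding each class first gives visibly different totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (presentation rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class FixationProfile:
    """Zygosity distribution of an initially heterozygous site after g selfings."""

    generation: int
    p_hom: float
    p_het: float
    p_lost: float


def fixation_probabilities(g: int) -> FixationProfile:
    """Closed-form fixation profile after ``g`` rounds of selfing.

    Parameters
    ----------
    g:
        Number of selfing generations since the regenerated (T0) plant;
        a T3 plant has g=3.
    """
    if g < 0 or int(g) != g:
        raise ValueError(f"generation must be a non-negative integer, got {g!r}")
    g = int(g)
    p_het = 2.0 ** -g
    p_hom = (1.0 - p_het) / 2.0
    return FixationProfile(generation=g, p_hom=p_hom, p_het=p_het, p_lost=p_hom)


@dataclass(frozen=True)
class T0Estimate:
    """Back-estimated T0 mutation count for one variant class."""

    raw_hom: int
    coverage_fraction: float
    generation: int
    corrected: float          # raw / f, unrounded
    t0_count: float           # corrected / p_hom(g), unrounded

    @property
    def corrected_rounded(self) -> int:
        return round_half_away(self.corrected)

    @property
    def t0_rounded(self) -> int:
        return round_half_away(self.t0_count)


def estimate_t0_count(raw_hom: int, coverage_fraction: float, g: int) -> T0Estimate:
    """Estimate the T0 mutation count behind ``raw_hom`` homozygous calls.

    ``raw_hom`` is the number of line-specific homozygous variants found in
    the region callable in all compared samples; ``coverage_fraction`` is
    that region's fraction of the genome; ``g`` the selfing generation.
    """
    if raw_hom < 0:
        raise ValueError("raw_hom must be >= 0")
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in (0, 1]")
    prof = fixation_probabilities(g)
    if prof.p_hom == 0:
        raise ValueError(
            "g=0: no selfing has occurred, every mutation is still heterozygous "
            "and homozygous counts carry no information about the T0 load"
        )
    corrected = raw_hom / coverage_fraction
    return T0Estimate(
        raw_hom=raw_hom,
        coverage_fraction=coverage_fraction,
        generation=int(g),
        corrected=corrected,
        t0_count=corrected / prof.p_hom,
    )


def estimate_t0_total(
    raw_hom_snps: int, raw_hom_indels: int, coverage_fraction: float, g: int
) -> float:
    """Unrounded total T0 estimate over SNPs and indels (round last)."""
    snps = estimate_t0_count(raw_hom_snps, coverage_fraction, g)
    indels = estimate_t0_count(raw_hom_indels, coverage_fraction, g)
    return snps.t0_count + indels.t0_count


def sibling_average(estimates: list[float]) -> float:
    """Arithmetic mean of unrounded T0 estimates for sibling lines.

    Sibling lines descend from the same T0 plant, so their estimates target
    the same quantity and are averaged.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    return sum(estimates) / len(estimates)


def mutation_rate(t0_total: float, genome_size: float) -> float:
    """Per-base somaclonal mutation rate: T0 load / genome size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return t0_total / genome_size


def study_t0_estimate(
    hom_counts: dict[str, int],
    coverage_fraction: float,
    generations: dict[str, int],
    sibling_groups: dict[str, list[str]],
    n_boot: int = 200,
    rng: "np.random.Generator | None" = None,
) -> tuple[float, float, float]:
    """Pooled study-level T0 estimate with a parametric bootstrap interval.

    Per-line estimates are averaged within sibling groups (they share a T0
    plant) and then across groups.  The 95% interval replays the
    generative chain from the point estimate: each replicate redraws every
    line's homozygous count as Binomial(N-hat, p_hom(g) * f), capturing
    both segregation and callable-thinning variance, and recomputes the
    pooled estimate.  Returns ``(point, lo, hi)``.
    """
    import numpy as np

    if rng is None:
        rng = np.random.default_rng(0)

    def pooled(homs: dict[str, int]) -> float:
        ests = {l: estimate_t0_count(homs[l], coverage_fraction,
                                     generations[l]).t0_count for l in homs}
        return float(np.mean([
            np.mean([ests[m] for m in members])
            for members in sibling_groups.values()
        ]))

    point = pooled(hom_counts)
    n_hat = max(1, round_half_away(point))
    boots = []
    for _ in range(n_boot):
        rep = {
            l: int(rng.binomial(
                n_hat,
                fixation_probabilities(generations[l]).p_hom * coverage_fraction))
            for l in hom_counts
        }
        boots.append(pooled(rep))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return point, float(lo), float(hi)


def coverage_from_reads(n_reads: int, read_length: int, genome_size: float) -> float:
    """Fold genome coverage n*len/G, reported to one decimal."""
    if n_reads < 0 or read_length <= 0 or genome_size <= 0:
        raise ValueError("all arguments must be positive (n_reads may be 0)")
    return round(n_reads * read_length / genome_size, 1)
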