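"""Line-specific variant auditing.

Turns per-line variant call sets into candidate induced-mutation sets:
depth/quality filtering, subtraction of shared background polymorphisms
(with a sibling-group exception: a variant shared only by lines descending
from the same T0 plant is still a candidate induced mutation), restriction
to the genome region callable in every compared sample, and substitution
spectrum summaries (six strand-symmetric base-change classes, Ti/Tv).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

PURINES = {"A", "G"}

#: the six strand-symmetric substitution classes, in conventional order
SPECTRUM_CLASSES = ("AT→GC", "GC→AT", "AT→CG", "AT→TA", "GC→CG", "GC→TA")

TRANSITION_CLASSES = frozenset({"AT→GC", "GC→AT"})


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one line."""

    line: str
    chrom: str
    pos: int                 # 1-based
    ref_allele: str
    alt_allele: str
    zygosity: str            # "het" | "hom_alt"
    depth: int               # supporting reads
    quality: float           # phred-like

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.quality < 0:
            raise ValueError("quality must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used for cross-line matching."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


@dataclass(frozen=True)
class FilterProfile:
    """Minimum supporting-read depth and call quality for a variant to survive."""

    name: str
    min_depth: int
    min_quality: float

    @property
    def effective_depth(self) -> int:
        """Depth implied jointly by the depth and quality floors under the
        simulation's quality model (quality = 3 x supporting reads)."""
        return max(self.min_depth, int(np.ceil(self.min_quality / 3)))


DP2Q10 = FilterProfile("DP2Q10", 2, 10)
DP4Q20 = FilterProfile("DP4Q20", 4, 20)


def filter_calls(calls: list[VariantCall], profile: FilterProfile) -> list[VariantCall]:
    """Calls surviving ``profile``: depth >= min_depth and quality >= min_quality."""
    return [
        c for c in calls
        if c.depth >= profile.min_depth and c.quality >= profile.min_quality
    ]


def partition_shared(
    callsets: dict[str, list[VariantCall]],
    sibling_groups: dict[str, list[str]],
    min_shared: int = 2,
) -> tuple[list[tuple], dict[str, list[VariantCall]]]:
    """Split variants into background polymorphisms vs line/group-specific.

    A variant carried by >= ``min_shared`` lines whose carrier set is not
    contained in a single sibling group is treated as a pre-existing
    polymorphism of the source cultivar (it cannot have arisen
    independently in unrelated regenerants); a variant private to one line,
    or shared only within one sibling group, remains a candidate induced
    mutation.  Lines absent from every group count as singleton groups.

    Returns ``(background_keys, line_specific)`` where ``line_specific``
    maps line name to its surviving calls; the union of outputs is a
    partition of the input variants.
    """
    group_of: dict[str, str] = {}
    for gname, members in sibling_groups.items():
        for line in members:
            group_of[line] = gname
    for line in callsets:
        group_of.setdefault(line, f"__singleton__{line}")

    carriers: dict[tuple, set[str]] = defaultdict(set)
    for line, calls in callsets.items():
        for c in calls:
            carriers[c.key].add(line)

    background: set[tuple] = set()
    for key, lines in carriers.items():
        if len(lines) >= min_shared and len({group_of[l] for l in lines}) > 1:
            background.add(key)

    line_specific = {
        line: [c for c in calls if c.key not in background]
        for line, calls in callsets.items()
    }
    return sorted(background), line_specific


@dataclass
class CallableMask:
    """Per-chromosome boolean callability over a genome."""

    chroms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def genome_size(self) -> int:
        return sum(len(a) for a in self.chroms.values())

    @property
    def n_callable(self) -> int:
        return int(sum(a.sum() for a in self.chroms.values()))

    def contains(self, chrom: str, pos: int) -> bool:
        """Is the 1-based position callable?"""
        arr = self.chroms.get(chrom)
        return bool(arr is not None and 0 <= pos - 1 < len(arr) and arr[pos - 1])

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        """Half-open 0-based runs of callable positions (BED convention)."""
        arr = self.chroms[chrom].astype(np.int8)
        if arr.size == 0:
            return []
        edges = np.flatnonzero(np.diff(np.concatenate(([0], arr, [0]))))
        return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def shared_callable(masks: dict[str, CallableMask]) -> tuple[CallableMask, float]:
    """Positionwise intersection of per-line masks and its genome fraction.

    The returned fraction is the coverage-correction denominator f: raw
    variant counts restricted to the intersection underestimate genome-wide
    counts by exactly this factor.
    """
    if not masks:
        raise ValueError("need at least one mask")
    first = next(iter(masks.values()))
    out = CallableMask()
    for chrom, arr in first.chroms.items():
        acc = arr.copy()
        for m in masks.values():
            other = m.chroms.get(chrom)
            if other is None or len(other) != len(arr):
                raise ValueError(f"inconsistent genome for chromosome {chrom!r}")
            acc &= other
        out.chroms[chrom] = acc
    return out, out.n_callable / out.genome_size


def restrict_to_mask(calls: list[VariantCall], mask: CallableMask) -> list[VariantCall]:
    """Calls whose position lies inside the mask."""
    return [c for c in calls if mask.contains(c.chrom, c.pos)]


_SUBSTITUTION_CLASS = {
    ("A", "G"): "AT→GC", ("T", "C"): "AT→GC",
    ("G", "A"): "GC→AT", ("C", "T"): "GC→AT",
    ("A", "C"): "AT→CG", ("T", "G"): "AT→CG",
    ("A", "T"): "AT→TA", ("T", "A"): "AT→TA",
    ("G", "C"): "GC→CG", ("C", "G"): "GC→CG",
    ("G", "T"): "GC→TA", ("C", "A"): "GC→TA",
}


def classify_substitution(ref_base: str, alt_base: str) -> tuple[str, bool]:
    """Strand-symmetric class and transition flag for a single substitution.

    G→A and C→T both map to GC→AT, etc.; a transition keeps the
    purine/pyrimidine character.
    """
    ref, alt = ref_base.upper(), alt_base.upper()
    try:
        cls = _SUBSTITUTION_CLASS[(ref, alt)]
    except KeyError:
        raise ValueError(f"not a substitution: {ref_base}->{alt_base}") from None
    is_ti = (ref in PURINES) == (alt in PURINES)
    return cls, is_ti


@dataclass
class SpectrumTable:
    """Counts of the six substitution classes with Ti/Tv summary."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = {c: int(self.counts.get(c, 0)) for c in SPECTRUM_CLASSES}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        """One-decimal percentages of the total."""
        t = self.total
        return {c: round(100 * n / t, 1) if t else 0.0 for c, n in self.counts.items()}

    @property
    def ti(self) -> int:
        return sum(n for c, n in self.counts.items() if c in TRANSITION_CLASSES)

    @property
    def tv(self) -> int:
        return self.total - self.ti

    @property
    def titv(self) -> float | None:
        """Ti/Tv to two decimals; None when no transversions were seen."""
        if self.tv == 0:
            return None
        return round(self.ti / self.tv, 2)


def spectrum_table(variants: list[VariantCall]) -> SpectrumTable:
    """Substitution-class table over the SNPs in ``variants`` (indels ignored)."""
    counts: dict[str, int] = defaultdict(int)
    for v in variants:
        if not v.is_snp:
            continue
        cls, _ = classify_substitution(v.ref_allele, v.alt_allele)
        counts[cls] += 1
    return SpectrumTable(counts)


def titv_average(tables: list[SpectrumTable]) -> float | None:
    """Mean of the per-line Ti/Tv ratios, three decimals.

    Each per-line ratio is first rounded to two decimals and the rounded
    values averaged — the convention under which the published per-line
    ratios (1.03, 1.1, 1.44, 0.89) average to 1.115; averaging the
    unrounded ratios gives 1.114.
    """
    if not tables:
        raise ValueError("need at least one table")
    ratios = [t.titv for t in tables]
    if any(r is None for r in ratios):
        return None
    return round(sum(ratios) / len(ratios), 3)
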