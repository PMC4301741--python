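"""Screening short reads for exogenous (vector / donor-bacterium) sequences.

Reads are quality-trimmed, then matched against a panel of foreign
references (vector backbone, T-DNA, bacterial replicons) by exact 31-mer
lookup.  Only k-mers absent from the host genome count as evidence, which
plays the role of a unique-mapping requirement: a read supports a
reference only through sequence that cannot have come from the host.
Presence/absence is decided from hit counts and the fraction of the
reference covered by matching k-mers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dnautil import revcomp


@dataclass
class Read:
    name: str
    sequence: str
    qualities: np.ndarray  # phred scores, one per base

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.qualities) != len(self.sequence):
            raise ValueError("quality length != sequence length")


def qc_reads(
    reads: list[Read],
    quality_floor: int = 20,
    min_length: int = 20,
    adapters: tuple[str, ...] = (),
) -> list[Read]:
    """End-trim low-quality bases, strip adapter prefixes, drop short reads.

    Bases below ``quality_floor`` are removed from both ends (never from
    the interior); any configured adapter occurring as a prefix of the
    trimmed read is removed; reads shorter than ``min_length`` afterwards
    are discarded.
    """
    out: list[Read] = []
    for r in reads:
        ok = np.flatnonzero(r.qualities >= quality_floor)
        if ok.size == 0:
            continue
        lo, hi = int(ok[0]), int(ok[-1]) + 1
        seq, qual = r.sequence[lo:hi], r.qualities[lo:hi]
        for ad in adapters:
            if ad and seq.startswith(ad):
                seq, qual = seq[len(ad):], qual[len(ad):]
                break
        if len(seq) >= min_length:
            out.append(Read(r.name, seq, qual))
    return out


@dataclass
class ReferenceHits:
    reference: str
    length: int
    hit_reads: int
    covered_bases: int

    @property
    def covered_fraction(self) -> float:
        return self.covered_bases / self.length if self.length else 0.0


@dataclass
class ScreenReport:
    hits: dict[str, ReferenceHits]
    k: int
    min_hits: int = 3
    min_covered_fraction: float = 0.01
    verdicts: dict[str, str] = field(default_factory=dict)


def _canon(km: str) -> str:
    rc = revcomp(km)
    return km if km <= rc else rc


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    d: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        d.setdefault(_canon(seq[i:i + k]), []).append(i)
    return d


def screen(
    reads: list[Read],
    references: dict[str, str],
    host: str,
    k: int = 31,
) -> ScreenReport:
    """Count reads supporting each foreign reference via host-unique k-mers.

    A read hits a reference when it shares at least one exact k-mer (either
    strand) present in that reference but absent from the host genome.
    Covered bases accumulate over the reference intervals spanned by
    matching k-mers.
    """
    if not references:
        raise ValueError("empty reference panel")
    host_kmers = {_canon(host[i:i + k]) for i in range(len(host) - k + 1)}
    ref_index: dict[str, dict[str, list[int]]] = {}
    for name, seq in references.items():
        pos = _kmer_positions(seq, k)
        ref_index[name] = {km: p for km, p in pos.items() if km not in host_kmers}

    counts = {name: 0 for name in references}
    covered = {name: np.zeros(len(seq), dtype=bool) for name, seq in references.items()}
    for r in reads:
        seen: set[str] = set()
        read_kmers = {_canon(r.sequence[i:i + k]) for i in range(len(r.sequence) - k + 1)}
        for name, index in ref_index.items():
            matched = read_kmers & index.keys()
            if matched:
                if name not in seen:
                    counts[name] += 1
                    seen.add(name)
                cov = covered[name]
                for km in matched:
                    for p in index[km]:
                        cov[p:p + k] = True
    hits = {
        name: ReferenceHits(name, len(seq), counts[name], int(covered[name].sum()))
        for name, seq in references.items()
    }
    return ScreenReport(hits=hits, k=k)


def verdict(
    report: ScreenReport,
    min_hits: int = 3,
    min_covered_fraction: float = 0.01,
) -> dict[str, str]:
    """Present/absent call per reference from hit count and covered fraction."""
    if min_hits < 0 or min_covered_fraction < 0:
        raise ValueError("thresholds must be >= 0")
    report.min_hits = min_hits
    report.min_covered_fraction = min_covered_fraction
    report.verdicts = {
        name: "present"
        if h.hit_reads >= min_hits and h.covered_fraction >= min_covered_fraction
        else "absent"
        for name, h in report.hits.items()
    }
    return report.verdicts
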