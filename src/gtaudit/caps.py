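"""In-silico CAPS genotyping: virtual PCR plus restriction digestion.

The assay: amplify a locus with a primer pair, digest the product with a
restriction enzyme whose recognition site is created by the edit of
interest, and read the genotype off the fragment pattern.  For the
herbicide-tolerance edit modelled here, two codon changes (W548L, TGG→TTG
and S627I, AGT→ATT) each create an MfeI site (CAATTG) inside a 2,287 bp
amplicon, so the edited allele digests into three fragments (1,751, 299
and 237 bp) while the wild-type allele stays uncut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dnautil import random_dna, revcomp

MFEI_SITE = "CAATTG"
MFEI_CUT_OFFSET = 1  # C^AATTG


@dataclass(frozen=True)
class Amplicon:
    sequence: str
    template_start: int          # 0-based on template
    template_end: int            # half-open
    fwd_primer: str
    rev_primer: str

    def __post_init__(self) -> None:
        if not self.sequence.startswith(self.fwd_primer):
            raise ValueError("amplicon must start with the forward primer")
        if not self.sequence.endswith(revcomp(self.rev_primer)):
            raise ValueError("amplicon must end with the reverse primer's complement")


@dataclass(frozen=True)
class DigestResult:
    site: str
    cut_positions: tuple[int, ...]       # 0-based cut points within the sequence
    fragment_lengths: tuple[int, ...]    # descending

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_lengths)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def extract_amplicon(template: str, fwd_primer: str, rev_primer: str) -> Amplicon:
    """Virtual PCR: the inclusive region between uniquely matching primers.

    The forward primer must occur exactly once on the given strand and the
    reverse primer exactly once on the opposite strand (i.e. its reverse
    complement occurs once on the given strand, downstream of the forward
    primer).
    """
    f_hits = _find_all(template, fwd_primer)
    r_hits = _find_all(template, revcomp(rev_primer))
    for name, hits in (("forward", f_hits), ("reverse", r_hits)):
        if len(hits) == 0:
            raise ValueError(f"{name} primer does not match the template")
        if len(hits) > 1:
            raise ValueError(f"{name} primer matches the template {len(hits)} times")
    start = f_hits[0]
    end = r_hits[0] + len(rev_primer)
    if end <= start:
        raise ValueError("reverse primer anneals upstream of the forward primer")
    return Amplicon(template[start:end], start, end, fwd_primer, rev_primer)


def digest(seq: str, site: str = MFEI_SITE, cut_offset: int = MFEI_CUT_OFFSET) -> DigestResult:
    """Cut ``seq`` at every occurrence of ``site`` (palindromic enzyme).

    Fragment lengths always sum to the input length; a sequence without
    the site returns a single full-length fragment.
    """
    cuts = tuple(i + cut_offset for i in _find_all(seq, site))
    bounds = (0, *cuts, len(seq))
    frags = tuple(sorted((b - a for a, b in zip(bounds, bounds[1:])), reverse=True))
    return DigestResult(site=site, cut_positions=cuts, fragment_lengths=frags)


def genotype(allele_digests: tuple[DigestResult, DigestResult]) -> str:
    """Genotype from the digest patterns of the two alleles of a diploid.

    The observable is the union of fragment patterns on a gel: only cut
    fragments -> GT_homo; only the uncut product -> WT; both -> GT_het.
    """
    cut = [d.n_fragments > 1 for d in allele_digests]
    if all(cut):
        return "GT_homo"
    if not any(cut):
        return "WT"
    return "GT_het"


@dataclass(frozen=True)
class CapsLocus:
    """Synthetic edited-locus fixture for the CAPS assay.

    The real locus sequence is not public; this generator places the two
    editable codons so the edited allele's MfeI cuts fall 1,751 and 2,050 bp
    from the forward-primer end of a 2,287 bp amplicon, reproducing the
    published fragment pattern {1,751, 299, 237}.
    """

    wt_template: str
    gt_template: str
    fwd_primer: str
    rev_primer: str


def make_caps_locus(
    seed: int = 0,
    amplicon_length: int = 2287,
    cut_positions: tuple[int, int] = (1751, 2050),
    primer_length: int = 20,
    flank: int = 300,
) -> CapsLocus:
    """Build wild-type and edited templates for the CAPS fixture.

    The W548L codon context CAATGG becomes CAATTG via TGG→TTG and the
    S627I context CAAGTG becomes CAATTG via AGT→ATT; each edit is a single
    substitution placed so the cut point (C^AATTG) lands at the requested
    amplicon coordinate.
    """
    rng = np.random.default_rng(seed)
    while True:
        amp = list(random_dna(rng, amplicon_length, gc=0.45))
        # site start is cut position - cut offset
        for cut, wt_ctx in zip(cut_positions, ("CAATGG", "CAAGTG")):
            s = cut - MFEI_CUT_OFFSET
            amp[s:s + 6] = wt_ctx
        wt_amp = "".join(amp)
        gt_amp = list(wt_amp)
        for cut in cut_positions:
            s = cut - MFEI_CUT_OFFSET
            gt_amp[s:s + 6] = MFEI_SITE
        gt_amp = "".join(gt_amp)
        fwd = wt_amp[:primer_length]
        rev = revcomp(wt_amp[-primer_length:])
        left = random_dna(rng, flank)
        right = random_dna(rng, flank)
        wt_template = left + wt_amp + right
        gt_template = left + gt_amp + right
        ok = (
            len(_find_all(wt_amp, MFEI_SITE)) == 0
            and len(_find_all(gt_amp, MFEI_SITE)) == 2
            and all(
                len(_find_all(t, fwd)) == 1 and len(_find_all(t, revcomp(rev))) == 1
                for t in (wt_template, gt_template)
            )
        )
        if ok:
            return CapsLocus(wt_template, gt_template, fwd, rev)


def genotype_line(locus: CapsLocus, zygosity: str) -> str:
    """Run the full assay for a line with the given edited-allele zygosity."""
    templates = {
        "hom": (locus.gt_template, locus.gt_template),
        "het": (locus.gt_template, locus.wt_template),
        "wt": (locus.wt_template, locus.wt_template),
    }[zygosity]
    digests = tuple(
        digest(extract_amplicon(t, locus.fwd_primer, locus.rev_primer).sequence)
        for t in templates
    )
    return genotype(digests)  # type: ignore[arg-type]
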