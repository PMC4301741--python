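"""In-silico CAPS genotyping of the edited herbicide-tolerance locus.

Virtual PCR amplifies a 2,287 bp product; the two edited codons (W548L,
S627I) each create an MfeI site (CAATTG), so the edited allele digests
into three fragments while the wild type stays uncut.
"""

from gtaudit.caps import digest, extract_amplicon, genotype_line, make_caps_locus

locus = make_caps_locus(seed=0)

for zygosity in ("hom", "het", "wt"):
    print(f"{zygosity:>4}: genotype {genotype_line(locus, zygosity)}")
# a homozygous edit shows only cut fragments, a heterozygote shows both

amp = extract_amplicon(locus.gt_template, locus.fwd_primer, locus.rev_primer)
d = digest(amp.sequence)
print(f"edited-allele amplicon {len(amp.sequence)} bp -> "
      f"fragments {d.fragment_lengths}")
# fragment lengths always sum back to the amplicon length
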