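"""Estimate how many called SNPs truly exist from a partial re-sequencing.

Candidates are ranked by caller quality; re-sequencing a block of them
locates the quality boundary between real and spurious calls.
"""

from gtaudit.validation import RankedValidation, consistency_ratio, estimate_true_count

# 45 homozygous candidates; the 12 lowest-quality re-sequenced:
# the bottom 6 were absent, the 6 above confirmed
homo = RankedValidation(45, {rank: (rank <= 39) for rank in range(34, 46)})
n_homo = estimate_true_count(homo)
print(f"homozygous: {n_homo} of 45 candidates estimated real")

# 121 heterozygous candidates; the 48 highest-quality re-sequenced:
# only the top 13 confirmed
het = RankedValidation(121, {rank: (rank <= 13) for rank in range(1, 49)})
n_het = estimate_true_count(het)
print(f"heterozygous: {n_het} of 121 candidates estimated real")

observed, expected = consistency_ratio(n_homo, n_het, g=3)
print(f"hom/het ratio {observed:.1f} vs selfing expectation {expected:.1f}")
# agreement supports the homozygous calls being largely genuine
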