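"""Back-estimate T0 mutation loads from homozygous variant counts.

A mutation arising in tissue culture is heterozygous in the regenerated
T0 plant; each selfing round fixes a quarter of the remaining heterozygous
sites.  Dividing the observed homozygous count by the callable-genome
fraction f and by p_hom(g) recovers the original load.
"""

from gtaudit import (
    estimate_t0_count,
    estimate_t0_total,
    fixation_probabilities,
    mutation_rate,
    sibling_average,
)
from gtaudit.mendel import round_half_away

prof = fixation_probabilities(3)
print(f"after 3 selfings: hom {prof.p_hom:.2%}, het {prof.p_het:.2%}")
# -> 43.75% of T0 mutations are homozygous in a T3 plant, 12.5% still het

est = estimate_t0_count(raw_hom=45, coverage_fraction=0.46, g=3)
print(f"45 hom SNPs at f=0.46, g=3  ->  T0 SNP load {est.t0_rounded}")
total = estimate_t0_total(45, 15, 0.46, 3)
print(f"with 15 hom indels          ->  T0 total {round_half_away(total)}")
# totals are computed unrounded and rounded once (224 + 75 would give 299)

avg = sibling_average([465.0, 537.0])
print(f"sibling lines 465 and 537   ->  shared-T0 average {round_half_away(avg)}")
rate = mutation_rate(round_half_away(total), 3.9e8)
print(f"per-base somaclonal rate     ->  {rate:.2e}")
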