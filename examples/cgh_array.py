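"""Tiling-CGH detection of an integrated vector and its copy number.

Two-channel intensities over dense 60-mer vector probes are normalized by
control-probe medians; a homozygous insertion doubles the Cy5/Cy3 ratio of
a heterozygous one (log2 difference of 1).
"""

import numpy as np

from gtaudit.cgh import (
    call_aberrations,
    copy_state,
    design_probes,
    moving_average,
    normalize_and_ratio,
)
from gtaudit.dnautil import random_dna
from gtaudit.simulate import SimParams, simulate_cgh, vector_probe_copies

rng = np.random.default_rng(0)
probes = design_probes(host_region=random_dna(rng, 6000),
                       vector=random_dna(rng, 2000))
params = SimParams(seed=0, cgh_noise_sigma=0.1)
ref_copies = vector_probe_copies(probes, "none")

means = {}
for i, insertion in enumerate(("none", "het", "homo")):
    test = vector_probe_copies(probes, insertion)
    t_raw, r_raw = simulate_cgh(probes, test, ref_copies, params, seed_salt=i)
    res = normalize_and_ratio(probes, t_raw, r_raw)
    _, track = res.track("vector_forward")
    smooth = moving_average(track, 20)
    calls = call_aberrations(smooth)
    means[insertion] = float(smooth.mean())
    print(f"{insertion:>4}: mean log2 ratio {means[insertion]:6.2f}, "
          f"aberrant intervals {len(calls)}")

state = copy_state(means["homo"], "vector", companion_mean=means["het"])
print(f"homo vs het log2 difference {means['homo'] - means['het']:.2f} "
      f"-> copy state {state!r}")
# ~1.0 difference = doubled ratio = homozygous insertion
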