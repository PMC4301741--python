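"""Screen whole-genome reads for vector backbone and donor-bacterium DNA.

A line carrying the integration vector yields reads whose 31-mers occur in
the vector but nowhere in the host genome; a clean line yields none.
"""

from gtaudit.screen import qc_reads, screen, verdict
from gtaudit.simulate import LinePlan, SimParams, generate_reference, simulate_line_reads

params = SimParams(seed=0, error_rate=0.001)
ref = generate_reference(params, l_host=30_000, n_genes=4)
panel = {"vector_backbone": ref.backbone, "vector_t_dna": ref.t_dna,
         **ref.foreign_panel}

for plan in (LinePlan("clean_T3", 3, "G1"),
             LinePlan("insertion_T2", 2, "G2", "het", 15_000)):
    reads = qc_reads(simulate_line_reads(ref, plan, coverage=10.0, params=params))
    report = screen(reads, panel, ref.host_sequence)
    v = verdict(report)
    print(f"{plan.name}: {len(reads)} reads after QC")
    for name, h in report.hits.items():
        print(f"  {name:28s} hits {h.hit_reads:5d}  "
              f"covered {h.covered_fraction:5.1%}  -> {v[name]}")
# only the insertion line shows vector hits; donor replicons stay absent
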