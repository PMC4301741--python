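"""Synthetic-data generator: references, mutations, segregation, calls, reads."""

import numpy as np
import pytest
from scipy import stats

from gtaudit.audit import DP2Q10, DP4Q20, SPECTRUM_CLASSES, classify_substitution
from gtaudit.dnautil import gc_fraction, kmer_set
from gtaudit.simulate import (
    DEFAULT_SPECTRUM,
    LinePlan,
    SimParams,
    TruthSet,
    default_line_plans,
    generate_reference,
    induce_t0_mutations,
    make_background_polymorphisms,
    segregate,
    simulate_reads,
    simulate_variant_calls,
)

BS59_SPECTRUM = {"AT→GC": 0.154, "GC→AT": 0.316, "AT→CG": 0.043,
                 "AT→TA": 0.085, "GC→CG": 0.060, "GC→TA": 0.342}


class TestReference:
    def test_sizes_and_counts(self, small_reference):
        assert len(small_reference.host_sequence) == 60_000
        assert len(small_reference.gene_models) == 8
        assert small_reference.ploidy == 2
        assert small_reference.t_dna + small_reference.backbone == \
            small_reference.vector_sequence

    def test_determinism(self, params, small_reference):
        again = generate_reference(params, l_host=60_000, n_genes=8)
        assert again.host_sequence == small_reference.host_sequence
        assert again.vector_sequence == small_reference.vector_sequence
        assert again.gene_models == small_reference.gene_models

    def test_gc_content_within_binomial_interval(self, small_reference):
        gc = gc_fraction(small_reference.host_sequence)
        n = len(small_reference.host_sequence)
        lo, hi = stats.binom.interval(0.99, n, 0.44)
        # gene models perturb base composition slightly; allow their span
        assert lo / n - 0.02 < gc < hi / n + 0.02

    def test_vector_has_host_unique_kmers(self, small_reference):
        host = small_reference.host_sequence
        host_k = kmer_set(host, 20)
        vec_k = kmer_set(small_reference.vector_sequence, 20)
        assert vec_k - host_k  # at least one screenable 20-mer

    def test_infeasible_packing_rejected(self, params):
        with pytest.raises(ValueError, match="pack"):
            generate_reference(params, l_host=12_000, n_genes=50)


class TestInduction:
    def test_count_and_origin(self, small_reference):
        ts = induce_t0_mutations(small_reference, 500, DEFAULT_SPECTRUM, seed=1,
                                 t0_group="G")
        assert len(ts.variants) == 500
        assert all(v.origin == "induced_T0" for v in ts.variants)
        assert len({v.pos for v in ts.variants}) == 500

    def test_degenerate_spectrum_forces_class(self, small_reference):
        spectrum = {c: 0.0 for c in SPECTRUM_CLASSES}
        spectrum["GC→AT"] = 1.0
        ts = induce_t0_mutations(small_reference, 200, spectrum, seed=2,
                                 indel_fraction=0.0, t0_group="G")
        for v in ts.variants:
            assert (v.ref_allele, v.alt_allele) in {("G", "A"), ("C", "T")}

    def test_bad_spectrum_rejected(self, small_reference):
        with pytest.raises(ValueError, match="sum to 1"):
            induce_t0_mutations(small_reference, 10,
                                {c: 0.5 for c in SPECTRUM_CLASSES}, seed=1)

    def test_spectrum_goodness_of_fit(self, small_reference):
        """10,000 draws from a published line's spectrum pass a chi-square
        goodness-of-fit test at alpha = 0.01."""
        w = {c: v / sum(BS59_SPECTRUM.values()) for c, v in BS59_SPECTRUM.items()}
        ts = induce_t0_mutations(small_reference, 10_000, w, seed=3,
                                 indel_fraction=0.0, t0_group="G")
        counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
        for v in ts.variants:
            cls, _ = classify_substitution(v.ref_allele, v.alt_allele)
            counts[cls] += 1
        observed = [counts[c] for c in SPECTRUM_CLASSES]
        expected = [10_000 * w[c] for c in SPECTRUM_CLASSES]
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01


class TestSegregation:
    def _truth(self, ref, n, seed=4):
        return induce_t0_mutations(ref, n, DEFAULT_SPECTRUM, seed, t0_group="G")

    def test_generation_zero_all_het(self, small_reference):
        ts = self._truth(small_reference, 200)
        segregate(ts, [LinePlan("L", 0, "G")], seed=5)
        assert all(v.zygosity_by_line["L"] == "het" for v in ts.variants)

    def test_hom_fraction_at_t3(self, small_reference):
        """After 3 selfings the homozygous-mutant fraction is 43.75%."""
        n = 5000
        ts = self._truth(small_reference, n)
        segregate(ts, [LinePlan("L", 3, "G")], seed=6)
        hom = sum(v.zygosity_by_line["L"] == "hom_alt" for v in ts.variants)
        p = 0.4375
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hom / n - p) < 3 * se

    def test_het_vanishes_at_g20(self, small_reference):
        ts = self._truth(small_reference, 2000)
        segregate(ts, [LinePlan("L", 20, "G")], seed=7)
        het = sum(v.zygosity_by_line["L"] == "het" for v in ts.variants)
        assert het == 0  # expectation 2000 * 2^-20 ~ 0.002

    def test_conservation_and_symmetry(self, small_reference):
        n = 5000
        ts = self._truth(small_reference, n)
        segregate(ts, [LinePlan("L", 2, "G")], seed=8)
        states = [v.zygosity_by_line["L"] for v in ts.variants]
        hom = states.count("hom_alt") / n
        het = states.count("het") / n
        lost = states.count("hom_ref") / n
        assert hom + het + lost == pytest.approx(1.0)
        se = np.sqrt(0.375 * 0.625 / n)
        assert abs(hom - lost) < 4 * se  # fixation and loss are symmetric

    def test_monte_carlo_matches_closed_form(self, small_reference):
        """Empirical fixation fractions track the closed-form profile."""
        from gtaudit.mendel import fixation_probabilities
        n = 100_000
        ts = TruthSet([v for v in self._truth(small_reference, 5000).variants])
        # replicate the 5000 variants across 20 virtual lineages via plans
        plans = [LinePlan(f"L{i}", 3, "G") for i in range(20)]
        segregate(ts, plans, seed=9)
        prof = fixation_probabilities(3)
        hom = sum(v.zygosity_by_line[p.name] == "hom_alt"
                  for v in ts.variants for p in plans)
        se = np.sqrt(prof.p_hom * (1 - prof.p_hom) / n)
        assert abs(hom / n - prof.p_hom) < 3 * se

    def test_background_hom_everywhere(self, small_reference, plans):
        bg = make_background_polymorphisms(small_reference, 300,
                                           DEFAULT_SPECTRUM, seed=10)
        segregate(bg, plans, seed=11)
        for v in bg.variants:
            assert set(v.zygosity_by_line.values()) == {"hom_alt"}

    def test_negative_generation_rejected(self, small_reference):
        ts = self._truth(small_reference, 10)
        with pytest.raises(ValueError):
            LinePlan("L", -1, "G")


class TestCalls:
    def test_noise_free_limit_recovers_truth(self, small_reference):
        """With no errors and deep coverage, calls inside the callable mask
        equal the truth zygosities exactly."""
        params = SimParams(seed=12, error_rate=0.0, depth_mean=60.0,
                           depth_by_line={})
        ts = induce_t0_mutations(small_reference, 300, DEFAULT_SPECTRUM,
                                 seed=13, t0_group="G")
        plan = LinePlan("L", 3, "G")
        segregate(ts, [plan], seed=14)
        calls = simulate_variant_calls(ts, [plan], params, 60_000)
        got = {c.key: c.zygosity for c in calls.callsets["L"]}
        mask = calls.callable_mask("L", 1)
        want = {v.key: v.zygosity_by_line["L"] for v in ts.variants
                if v.zygosity_by_line["L"] != "hom_ref"
                and mask.contains(v.chrom, v.pos)}
        assert got == want

    def test_callable_fraction_poisson(self, small_reference):
        params = SimParams(seed=15, depth_mean=6.0, depth_by_line={})
        ts = TruthSet()
        plan = LinePlan("L", 3, "G")
        calls = simulate_variant_calls(ts, [plan], params, 60_000)
        frac = calls.callable_mask("L", 1).n_callable / 60_000
        expected = 1 - np.exp(-6.0)
        se = np.sqrt(expected * (1 - expected) / 60_000)
        assert abs(frac - expected) < 4 * se

    def test_quality_proxy_and_filters(self):
        from gtaudit.audit import VariantCall, filter_calls
        c = VariantCall("L", "chr1", 10, "G", "A", "hom_alt", depth=2, quality=6)
        assert filter_calls([c], DP2Q10) == []   # Q6 < 10
        c4 = VariantCall("L", "chr1", 10, "G", "A", "hom_alt", depth=4, quality=12)
        assert filter_calls([c4], DP2Q10) == [c4]
        assert filter_calls([c4], DP4Q20) == []

    def test_determinism(self, small_reference, plans, params):
        ts = induce_t0_mutations(small_reference, 100, DEFAULT_SPECTRUM,
                                 seed=16, t0_group="BSR-12")
        segregate(ts, plans, seed=17)
        a = simulate_variant_calls(ts, plans, params, 60_000)
        b = simulate_variant_calls(ts, plans, params, 60_000)
        assert a.callsets == b.callsets


class TestReads:
    def test_total_bases(self):
        reads = simulate_reads("ACGT" * 500, 1000, 76, 0.0, seed=18)
        assert sum(len(r.sequence) for r in reads) == 76_000

    def test_error_free_reads_are_substrings(self):
        genome = "".join(np.random.default_rng(19).choice(list("ACGT"), 5000))
        for r in simulate_reads(genome, 200, 76, 0.0, seed=20):
            assert r.sequence in genome

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads("A" * 100, -1, 10, 0.0, seed=0)

    def test_mean_depth_matches_coverage_formula(self):
        """n * len / L reads give the nominal fold coverage."""
        rng = np.random.default_rng(21)
        L, n, rl = 390_000, 55_634, 76
        genome = "".join(rng.choice(list("ACGT"), L))
        reads = simulate_reads(genome, n, rl, 0.0, seed=22)
        mean_depth = sum(len(r.sequence) for r in reads) / L
        assert mean_depth == pytest.approx(10.84, abs=0.01)
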