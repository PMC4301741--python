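"""End-to-end audit pipeline over a synthetic study.

Stages: simulate -> caps -> screen -> cgh -> audit -> annotate -> estimate
-> report.  Everything is driven by one config (YAML or dict) whose single
seed determines every random draw, so a rerun reproduces the report
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import audit as audit_mod
from . import caps as caps_mod
from . import cgh as cgh_mod
from . import effects as effects_mod
from . import io as io_mod
from . import mendel, screen as screen_mod, simulate as sim
from .audit import DP2Q10, DP4Q20, FilterProfile
from .validation import RankedValidation, estimate_true_count

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    seed: int = 0
    l_host: int = 100_000
    n_genes: int = 20
    n_t0_mutations: int = 500
    n_background_polymorphisms: int = 2000
    screen_coverage: float = 10.0
    cgh_host_region: tuple[int, int] = (40_000, 46_000)
    n_validate_homo: int = 12
    subtract_before_mask: bool = True     # polymorphism subtraction order
    profiles: tuple[str, ...] = ("DP2Q10", "DP4Q20")
    params: sim.SimParams = field(default_factory=sim.SimParams)
    write_artifacts: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        if self.l_host < 10_000:
            raise ConfigError("l_host must be >= 10000")
        for p in self.profiles:
            if p not in _PROFILES:
                raise ConfigError(f"unknown filter profile {p!r}")
        self.params.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        params = sim.SimParams(**raw.pop("params", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "cgh_host_region" in raw:
            raw["cgh_host_region"] = tuple(raw["cgh_host_region"])
        if "profiles" in raw:
            raw["profiles"] = tuple(raw["profiles"])
        return cls(params=params, **raw)


_PROFILES: dict[str, FilterProfile] = {"DP2Q10": DP2Q10, "DP4Q20": DP4Q20}


@dataclass
class LineAudit:
    """Everything the audit concludes about one line."""

    name: str
    generation: int
    sibling_group: str
    caps_genotype: str = ""
    screen_verdicts: dict[str, str] = field(default_factory=dict)
    cgh_verdict: str = ""
    cgh_copy_state: str = ""
    cgh_vector_mean_log2: float = float("nan")
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    spectrum: dict[str, int] = field(default_factory=dict)
    titv: float | None = None
    effect_counts: dict[str, int] = field(default_factory=dict)
    impactful: int = 0
    t0_estimates: dict[str, dict[str, float]] = field(default_factory=dict)
    mutation_rate: dict[str, float] = field(default_factory=dict)


@dataclass
class AuditReport:
    config: PipelineConfig
    lines: dict[str, LineAudit]
    coverage_fraction: dict[str, float]
    sibling_averages: dict[str, dict[str, float]]
    validation_estimate: int | None = None
    titv_average: float | None = None

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"unserializable {type(o)}")
        payload = {
            "lines": {k: dataclasses.asdict(v) for k, v in self.lines.items()},
            "coverage_fraction": self.coverage_fraction,
            "sibling_averages": self.sibling_averages,
            "validation_estimate": self.validation_estimate,
            "titv_average": self.titv_average,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=default)


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except (ConfigError,):
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("simulate")
def _simulate(cfg: PipelineConfig):
    params = cfg.params
    ref = sim.generate_reference(params, cfg.l_host, cfg.n_genes)
    plans = sim.default_line_plans(insertion_site=cfg.l_host // 2)
    truth = sim.TruthSet()
    taken: set[int] = set()
    bg = sim.make_background_polymorphisms(
        ref, cfg.n_background_polymorphisms, params.spectrum_weights,
        params.seed, exclude=taken)
    taken |= bg.positions()
    truth.variants.extend(bg.variants)
    for group in sorted({p.sibling_group for p in plans}):
        ts = sim.induce_t0_mutations(
            ref, cfg.n_t0_mutations, params.spectrum_weights, params.seed,
            params.indel_fraction, t0_group=group, exclude=taken)
        taken |= ts.positions()
        truth.variants.extend(ts.variants)
    truth.variants.sort(key=lambda v: v.pos)
    sim.segregate(truth, plans, params.seed, params.background_het_fraction)
    calls = sim.simulate_variant_calls(truth, plans, params, cfg.l_host, ref.chrom)
    return ref, plans, truth, calls


@_stage("caps")
def _caps(cfg: PipelineConfig, plans) -> dict[str, str]:
    locus = caps_mod.make_caps_locus(seed=cfg.seed)
    return {p.name: caps_mod.genotype_line(locus, p.gt_zygosity) for p in plans}


@_stage("screen")
def _screen(cfg: PipelineConfig, ref, plans, outdir: Path | None):
    references = {
        "vector_backbone": ref.backbone,
        "vector_t_dna": ref.t_dna,
        **ref.foreign_panel,
    }
    verdicts: dict[str, dict[str, str]] = {}
    for i, plan in enumerate(plans):
        reads = sim.simulate_line_reads(ref, plan, cfg.screen_coverage,
                                        cfg.params, seed_salt=i)
        reads = screen_mod.qc_reads(reads)
        rep = screen_mod.screen(reads, references, ref.host_sequence)
        verdicts[plan.name] = screen_mod.verdict(rep)
        if outdir is not None:
            rows = [
                {"reference": n, "hits": h.hit_reads, "covered_bases": h.covered_bases,
                 "fraction": round(h.covered_fraction, 4),
                 "verdict": verdicts[plan.name][n]}
                for n, h in rep.hits.items()
            ]
            pd.DataFrame(rows).to_csv(outdir / f"screen_{plan.name}.tsv",
                                      sep="\t", index=False)
    return verdicts


@_stage("cgh")
def _cgh(cfg: PipelineConfig, ref, plans):
    a, b = cfg.cgh_host_region
    probes = cgh_mod.design_probes(ref.host_sequence[a:b], ref.vector_sequence)
    copies_ref = sim.vector_probe_copies(probes, "none")

    def vector_mean(insertion: str, salt: int) -> float:
        test = sim.vector_probe_copies(probes, insertion)
        t_raw, r_raw = sim.simulate_cgh(probes, test, copies_ref, cfg.params,
                                        seed_salt=salt)
        res = cgh_mod.normalize_and_ratio(probes, t_raw, r_raw)
        _, track = res.track("vector_forward")
        sm = cgh_mod.moving_average(track, 20)
        calls = cgh_mod.call_aberrations(sm)
        mean = float(sm.mean())
        return mean if calls else float("nan")

    # positive-control mixture: one vector copy per diploid genome
    companion = vector_mean("het", salt=999)
    out: dict[str, tuple[str, str, float]] = {}
    for i, plan in enumerate(plans):
        m = vector_mean(plan.vector_insertion, salt=i)
        if np.isnan(m):
            out[plan.name] = ("absent", "none", m)
        else:
            state = cgh_mod.copy_state(m, "vector", companion_mean=companion)
            out[plan.name] = ("present", state, m)
    return out


@_stage("audit")
def _audit(cfg: PipelineConfig, plans, calls):
    sibling_groups: dict[str, list[str]] = {}
    for p in plans:
        sibling_groups.setdefault(p.sibling_group, []).append(p.name)
    results = {}
    coverage = {}
    for pname in cfg.profiles:
        profile = _PROFILES[pname]
        filtered = {line: audit_mod.filter_calls(cs, profile)
                    for line, cs in calls.callsets.items()}
        masks = calls.callable_masks(profile.effective_depth)
        shared, f = audit_mod.shared_callable(masks)
        coverage[pname] = f
        if cfg.subtract_before_mask:
            _, specific = audit_mod.partition_shared(filtered, sibling_groups)
            specific = {line: audit_mod.restrict_to_mask(cs, shared)
                        for line, cs in specific.items()}
        else:
            restricted = {line: audit_mod.restrict_to_mask(cs, shared)
                          for line, cs in filtered.items()}
            _, specific = audit_mod.partition_shared(restricted, sibling_groups)
        results[pname] = specific
    return results, coverage, sibling_groups


def _count_classes(calls_list) -> dict[str, int]:
    out = {"hom_snps": 0, "het_snps": 0, "hom_indels": 0, "het_indels": 0}
    for c in calls_list:
        kind = "snps" if c.is_snp else "indels"
        zyg = "hom" if c.zygosity == "hom_alt" else "het"
        out[f"{zyg}_{kind}"] += 1
    return out


@_stage("estimate")
def _validation_estimate(cfg: PipelineConfig, specific_dp2, truth, line: str):
    """Partial re-sequencing emulation: the lowest-quality homozygous SNP
    candidates are checked against the simulation truth."""
    cands = sorted(
        (c for c in specific_dp2.get(line, ())
         if c.is_snp and c.zygosity == "hom_alt"),
        key=lambda c: -c.quality)
    if not cands:
        return None
    true_hom = {v.key for v in truth.variants
                if v.zygosity_by_line.get(line) == "hom_alt"}
    n = len(cands)
    k = min(cfg.n_validate_homo, n)
    outcomes = {rank: cands[rank - 1].key in true_hom
                for rank in range(n - k + 1, n + 1)}
    return estimate_true_count(RankedValidation(n, outcomes))


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> AuditReport:
    """Run every stage and assemble the audit report.

    With ``outdir`` set (and ``cfg.write_artifacts``), intermediate files
    (FASTA/GFF3/VCF/BED/TSV and the report itself) are written there.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    ref, plans, truth, calls = _simulate(cfg)
    log.info("simulated %d truth variants over %d bp", len(truth.variants), cfg.l_host)

    caps_genotypes = _caps(cfg, plans)
    screen_verdicts = _screen(cfg, ref, plans, out if cfg.write_artifacts else None)
    cgh_results = _cgh(cfg, ref, plans)
    specific_by_profile, coverage, sibling_groups = _audit(cfg, plans, calls)

    lines: dict[str, LineAudit] = {}
    genome_size = len(ref.host_sequence)
    for plan in plans:
        la = LineAudit(plan.name, plan.generation, plan.sibling_group)
        la.caps_genotype = caps_genotypes[plan.name]
        la.screen_verdicts = screen_verdicts[plan.name]
        la.cgh_verdict, la.cgh_copy_state, la.cgh_vector_mean_log2 = \
            cgh_results[plan.name]
        for pname in cfg.profiles:
            specific = specific_by_profile[pname][plan.name]
            counts = _count_classes(specific)
            la.counts[pname] = counts
            f = coverage[pname]
            est_snp = mendel.estimate_t0_count(counts["hom_snps"], f, plan.generation)
            est_ind = mendel.estimate_t0_count(counts["hom_indels"], f, plan.generation)
            total = est_snp.t0_count + est_ind.t0_count
            la.t0_estimates[pname] = {
                "snps": est_snp.t0_count, "indels": est_ind.t0_count,
                "total": total, "total_rounded": mendel.round_half_away(total),
            }
            la.mutation_rate[pname] = mendel.mutation_rate(total, genome_size)
        dp2 = specific_by_profile[cfg.profiles[0]][plan.name]
        spec = audit_mod.spectrum_table(
            [c for c in dp2 if c.zygosity == "hom_alt"])
        la.spectrum = spec.counts
        la.titv = spec.titv
        effects = []
        for c in dp2:
            effects.extend(effects_mod.annotate(c, ref.gene_models,
                                                {ref.chrom: ref.host_sequence}))
        t = effects_mod.tally(effects)
        la.effect_counts = t.counts
        la.impactful = effects_mod.impactful_count(t)
        lines[plan.name] = la

    sib_avgs: dict[str, dict[str, float]] = {}
    for pname in cfg.profiles:
        sib_avgs[pname] = {}
        for group, members in sorted(sibling_groups.items()):
            ests = [lines[m].t0_estimates[pname]["total"] for m in members]
            sib_avgs[pname][group] = mendel.sibling_average(ests)

    tables = [
        audit_mod.SpectrumTable(lines[p.name].spectrum) for p in plans
    ]
    report = AuditReport(
        config=cfg, lines=lines, coverage_fraction=coverage,
        sibling_averages=sib_avgs,
        validation_estimate=_validation_estimate(
            cfg, specific_by_profile[cfg.profiles[0]], truth, plans[-1].name),
        titv_average=audit_mod.titv_average(tables),
    )

    if out is not None and cfg.write_artifacts:
        _write_artifacts(out, cfg, ref, plans, calls, report)
    return report


def _write_artifacts(out: Path, cfg, ref, plans, calls, report: AuditReport) -> None:
    io_mod.write_fasta(out / "reference.fa", {ref.chrom: ref.host_sequence})
    io_mod.write_fasta(out / "vector.fa", {
        "vector": ref.vector_sequence, "t_dna": ref.t_dna, "backbone": ref.backbone})
    io_mod.write_fasta(out / "foreign_panel.fa", ref.foreign_panel)
    io_mod.write_gff3(out / "genes.gff3", ref.gene_models)
    contigs = {ref.chrom: len(ref.host_sequence)}
    for line, cs in calls.callsets.items():
        io_mod.write_vcf(out / f"calls_{line}.vcf", cs, line, contigs)
    for pname in cfg.profiles:
        prof = _PROFILES[pname]
        for line in calls.depth:
            io_mod.write_bed(out / f"callable_{line}_{pname}.bed",
                             calls.callable_mask(line, prof.effective_depth))
    rows = []
    for name, la in report.lines.items():
        for pname, est in la.t0_estimates.items():
            c = la.counts[pname]
            rows.append({
                "line": name, "generation": la.generation, "profile": pname,
                **c, "coverage_fraction": round(report.coverage_fraction[pname], 4),
                "t0_snps": mendel.round_half_away(est["snps"]),
                "t0_indels": mendel.round_half_away(est["indels"]),
                "t0_total": est["total_rounded"],
                "sibling_average": mendel.round_half_away(
                    report.sibling_averages[pname][la.sibling_group]),
            })
    pd.DataFrame(rows).to_csv(out / "table1_t0_estimates.tsv", sep="\t", index=False)
    spec_rows = [{"line": n, **la.spectrum, "TiTv": la.titv}
                 for n, la in report.lines.items()]
    pd.DataFrame(spec_rows).to_csv(out / "table2_spectrum.tsv", sep="\t", index=False)
    eff_rows = [{"line": n, **la.effect_counts, "impactful": la.impactful}
                for n, la in report.lines.items()]
    pd.DataFrame(eff_rows).to_csv(out / "table3_effects.tsv", sep="\t", index=False)
    (out / "report.json").write_text(report.to_json())
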