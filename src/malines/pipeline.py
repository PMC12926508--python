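"""End-to-end orchestration: mask -> filters -> ancestral inference -> de
novo calls -> rates and spectra -> LOH -> population comparison.

Each stage failure is re-raised with the stage name so a broken run names
its cause.  With the same seed and inputs the summary is identical across
runs; every number in the summary is reproducible by re-invoking the
corresponding module operation on the persisted intermediates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import calls as calls_mod
from . import loh as loh_mod
from . import rates as rates_mod
from . import study
from .filters import FilterConfig, apply_site_filters
from .loh import HmmParams
from .popgen import snm_overlap
from .variants import HET, build_callable_mask


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    mask: object = None
    filtered: object = None
    filter_report: object = None
    ancestral: object = None
    calls: list = field(default_factory=list)
    snm_rates: object = None
    indel_rates: object = None
    spectrum: object = None
    compartments: object = None
    compartment_tests: dict = field(default_factory=dict)
    chrom_uniformity: tuple = None
    loh_tracts: list = field(default_factory=list)
    loh_table: object = None
    loh_rate: float = None
    gbgc: tuple = None
    overlap: object = None
    summary: dict = field(default_factory=dict)


def analyze_experiment(exp, filter_config: FilterConfig | None = None,
                       hmm_params: HmmParams | None = None,
                       min_consensus: int | None = None,
                       run_loh: bool = True,
                       run_popgen: bool = True,
                       outdir=None) -> PipelineResult:
    """Run the full calling and analysis pipeline on a simulated (or loaded)
    experiment bundle with fields ``sites``, ``depth``, ``ref``, and
    ``config`` (for generations)."""
    res = PipelineResult()
    generations = exp.config.generations
    cfg = filter_config or FilterConfig()

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - stage name is the contract
            raise StageError(name, exc) from exc

    res.mask = stage("mask", lambda: build_callable_mask(
        exp.depth, cfg.min_depth, cfg.max_depth))
    res.filtered, res.filter_report = stage("filter", lambda: apply_site_filters(
        exp.sites, res.mask, cfg))
    res.ancestral = stage("ancestral", lambda: calls_mod.infer_ancestral(
        res.filtered, min_consensus))
    res.calls = stage("call", lambda: calls_mod.group_mnms(
        calls_mod.call_mutations(res.filtered, res.ancestral, res.mask, exp.ref,
                                 indel_window=cfg.indel_proximity_window)))
    res.snm_rates = stage("rates", lambda: rates_mod.rate_table(
        res.calls, res.mask, generations, ("SNM",)))
    res.indel_rates = stage("rates", lambda: rates_mod.rate_table(
        res.calls, res.mask, generations, ("insertion", "deletion")))
    res.spectrum = stage("spectrum", lambda: rates_mod.six_type_spectrum(
        res.calls, res.mask, exp.ref, generations))
    res.compartments, res.compartment_tests = stage(
        "spectrum", lambda: rates_mod.compartment_rates(
            res.calls, res.mask, exp.ref, generations))
    if len(exp.ref.chrom_names) >= 2:
        res.chrom_uniformity = stage("spectrum", lambda: rates_mod.
                                     chromosome_uniformity(res.calls, res.mask))

    if run_loh:
        params = hmm_params or HmmParams()
        chrom_lengths = {c: exp.ref.chrom_length(c) for c in exp.ref.chrom_names}
        res.loh_tracts = stage("loh", lambda: loh_mod.classify_all(
            loh_mod.detect_loh_tracts(res.filtered, res.ancestral, params,
                                      chrom_lengths),
            exp.depth, res.mask))
        n_het = _ancestral_het_counts(res)
        res.loh_table, res.loh_rate = stage("loh", lambda: loh_mod.
                                            experiment_loh_rate(
                                                res.loh_tracts, generations, n_het))
        conv = [t for t in res.loh_tracts if t.mechanism == "conversion"]
        if conv:
            try:
                res.gbgc = loh_mod.gc_conversion_bias(conv)
            except ValueError:
                res.gbgc = None

    if run_popgen and getattr(exp, "pop_freqs", None) is not None:
        res.overlap = stage("compare", lambda: snm_overlap(
            res.calls, exp.pop_freqs))

    res.summary = _summarize(res, generations)
    if outdir is not None:
        _write_outputs(res, exp, Path(outdir))
    return res


@dataclass
class _GenerationsOnly:
    generations: dict


@dataclass
class LoadedExperiment:
    """An experiment read back from files (FASTA/GFF3/VCF/TSV)."""

    ref: object
    sites: object
    depth: object
    config: _GenerationsOnly
    pop_freqs: object = None


def load_experiment(indir, generations: dict[str, float] | list | None = None
                    ) -> LoadedExperiment:
    """Load a persisted experiment directory (as written by
    :func:`malines.simulate.write_experiment`).

    ``generations`` may be a mapping line -> generation count or a list in
    VCF sample order; defaults to the study's per-line counts when the
    sample count matches, else an error.
    """
    from .popgen import PopulationFrequencies
    from .reference import read_reference
    from .variants import DepthTracks, read_variants
    indir = Path(indir)
    ref = read_reference(indir / "reference.fa", indir / "annotation.gff3")
    sites = read_variants(indir / "variants.vcf")
    depth_path = indir / "depth.tsv"
    if not depth_path.exists():
        raise StageError("mask", FileNotFoundError(f"missing {depth_path}"))
    depth = DepthTracks.read_tsv(depth_path)
    if generations is None:
        vals = list(study.GENERATIONS.values())
        if len(sites.samples) != len(vals):
            raise ValueError("generations must be supplied when the line "
                             "count differs from the eight-line design")
        generations = vals
    if not isinstance(generations, dict):
        generations = dict(zip(sites.samples, generations))
    pop = None
    pop_path = indir / "population_frequencies.tsv"
    if pop_path.exists():
        pop = PopulationFrequencies.read_tsv(pop_path)
    return LoadedExperiment(ref=ref, sites=sites, depth=depth,
                            config=_GenerationsOnly(generations=generations),
                            pop_freqs=pop)


def _ancestral_het_counts(res) -> dict[str, int]:
    """Ancestral heterozygous-site count, per line (same consensus set)."""
    n = int((res.ancestral.genotype == HET).sum())
    return {s: n for s in res.filtered.samples}


def _summarize(res, generations) -> dict:
    s = {}
    s["n_snm"] = int(sum(1 for c in res.calls if c.event_class == "SNM"))
    s["n_indel"] = int(sum(1 for c in res.calls
                           if c.event_class in ("insertion", "deletion")))
    s["snm_rate"] = {"mean": res.snm_rates.pooled_mean,
                     "ci_low": res.snm_rates.ci_low,
                     "ci_high": res.snm_rates.ci_high,
                     "per_line": res.snm_rates.per_line.to_dict("records")}
    s["indel_rate"] = {"mean": res.indel_rates.pooled_mean,
                       "ci_low": res.indel_rates.ci_low,
                       "ci_high": res.indel_rates.ci_high}
    spec = res.spectrum
    s["spectrum"] = {"counts": spec.counts, "rates": spec.rates,
                     "ts_tv": spec.ts_tv, "u": spec.u, "v": spec.v,
                     "gc_equilibrium": spec.gc_equilibrium}
    mnm_groups, mnm_members = calls_mod.count_mnm(res.calls)
    s["mnm"] = {"groups": mnm_groups, "members": mnm_members}
    if res.chrom_uniformity:
        chi2, df, p = res.chrom_uniformity
        s["chromosome_uniformity"] = {"chi2": chi2, "df": df, "p": p}
    if res.compartments is not None:
        s["compartments"] = res.compartments.to_dict("records")
    if res.loh_table is not None:
        s["loh"] = {"n_events": int(res.loh_table["events"].sum()),
                    "rate": res.loh_rate,
                    "n_deletion": int(sum(1 for t in res.loh_tracts
                                          if t.mechanism == "deletion")),
                    "n_conversion": int(sum(1 for t in res.loh_tracts
                                            if t.mechanism == "conversion"))}
        if res.gbgc:
            s["loh"]["gc_fraction"], s["loh"]["gbgc_p"] = res.gbgc
    if res.overlap is not None:
        s["snm_overlap"] = res.overlap.to_dict("records")
    return s


def _write_outputs(res, exp, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res.filter_report.to_frame().to_csv(outdir / "filter_report.tsv",
                                        sep="\t", index=False)
    calls_mod.calls_to_frame(res.calls).to_csv(outdir / "calls.tsv",
                                               sep="\t", index=False)
    res.snm_rates.per_line.to_csv(outdir / "snm_rates.tsv", sep="\t", index=False)
    res.indel_rates.per_line.to_csv(outdir / "indel_rates.tsv", sep="\t",
                                    index=False)
    if res.spectrum.context_counts is not None:
        res.spectrum.context_counts.rename("count").to_csv(
            outdir / "context_spectrum.tsv", sep="\t")
    if res.compartments is not None:
        res.compartments.to_csv(outdir / "compartments.tsv", sep="\t", index=False)
    if res.loh_tracts:
        loh_mod.tracts_to_frame(res.loh_tracts).to_csv(
            outdir / "loh_tracts.tsv", sep="\t", index=False)
        loh_mod.write_bed(res.loh_tracts, outdir / "loh_tracts.bed")
    if res.loh_table is not None:
        res.loh_table.to_csv(outdir / "loh_rates.tsv", sep="\t", index=False)
    if res.overlap is not None:
        res.overlap.to_csv(outdir / "snm_overlap.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(res.summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def desk_statistics() -> dict:
    """Headline statistics recomputed from the published per-line tables
    (no sequencing data required)."""
    snm_rates = [study.SNM_RATES[l] for l in study.LINES]
    indel_rates = [study.INDEL_RATES[l] for l in study.LINES]
    # plain-z intervals: the published bounds derive from mean +/- 1.96 SE
    snm_mean, snm_lo, snm_hi = rates_mod.pooled_rate_ci(snm_rates,
                                                        method="normal")
    ind_mean, ind_lo, ind_hi = rates_mod.pooled_rate_ci(indel_rates,
                                                        method="normal")
    spec = rates_mod.SpectrumTable.from_counts_and_rates(
        study.SIX_TYPE_COUNTS, study.SIX_TYPE_RATES)
    snm_corrected = rates_mod.corrected_rate(
        snm_mean, study.NONSYN_GENOME_FRACTION, study.NONSYN_DEFICIT)
    indel_corrected = rates_mod.corrected_rate(
        ind_mean, study.EXON_GENOME_FRACTION, study.INDEL_EXON_DEFICIT)
    ne = {pop: rates_mod.effective_population_size(pi, snm_corrected)
          for pop, pi in study.PI_S.items()}
    return {
        "snm_total": sum(study.SNM_COUNTS.values()),
        "indel_total": sum(study.INDEL_COUNTS.values()),
        "snm_rate": {"mean": snm_mean, "ci_low": snm_lo, "ci_high": snm_hi},
        "indel_rate": {"mean": ind_mean, "ci_low": ind_lo, "ci_high": ind_hi},
        "snm_rate_corrected": snm_corrected,
        "indel_rate_corrected": indel_corrected,
        "ts_tv": spec.ts_tv,
        "rate_ratio_max_min": max(spec.rates.values()) / min(spec.rates.values()),
        "gc_equilibrium": spec.gc_equilibrium,
        "effective_population_size": ne,
        "loh_total_events": sum(study.LOH_EVENTS.values()),
        "loh_rate_mean_of_lines": float(np.mean(list(study.LOH_RATES.values()))),
    }
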