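"""End-to-end orchestration: simulate/load -> call sites -> quantify -> test.

A run is driven by one :class:`RunConfig` (YAML-loadable) whose defaults
are the method constants of the underlying protocol: >=10-read site
support, 50-nt site spacing, 5-nt bins, 3-read peak floor, 60-nt merge
gap, 1,000-nt 3'-UTR extension, p<0.001 cutoff, expression floor of 5
reads, WIG scaling to 10 million mapped reads.  Every stage's outputs are
written to the run directory; the machine-readable ``summary.json``
contains only numbers re-derivable from those artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import apa_stats, cs_discovery, peak_quant, synthetic_data
from .errors import ConfigError, InputError
from .io_utils import (
    GenomeAccessor,
    read_bed6,
    read_gene_list,
    read_models_tsv,
    read_reads_sam,
    write_peaks_bed,
    write_sites_bed,
    write_sites_tsv,
)
logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All paths and thresholds for one pipeline run."""

    outdir: str = "apa3seq_run"
    seed: int = 0
    conditions: tuple = ("proliferating", "arrested")
    # method constants (defaults are the protocol values)
    min_support: int = 10
    min_spacing: int = 50
    bin_size: int = 5
    min_peak: int = 3
    merge_gap: int = 60
    alpha: float = 0.001
    utr_extension: int = 1000
    expr_floor: float = 5.0
    wig_target: float = 1e7
    pui_pseudocount: float = 1.0
    quantify_mode: str = "cleavage"  # or "start"
    write_wig: bool = False
    # inputs; when genome/models/sam paths are absent, data is simulated
    genome_fasta: str | None = None
    models_tsv: str | None = None
    sam_by_sample: dict = field(default_factory=dict)
    known_sites_bed: str | None = None
    cell_cycle_genes: str | None = None
    processing_genes: str | None = None
    simulate: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("min_support", "min_spacing", "bin_size", "min_peak",
                     "merge_gap", "utr_extension"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0,1)")
        if self.quantify_mode not in ("cleavage", "start"):
            raise ConfigError("quantify_mode must be 'cleavage' or 'start'")
        if len(self.conditions) < 2:
            raise ConfigError("need at least two conditions")

    @property
    def simulated(self) -> bool:
        return not (self.genome_fasta and self.models_tsv and self.sam_by_sample)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "conditions" in data:
            data["conditions"] = tuple(data["conditions"])
        return cls(**data)

    def simulation_config(self) -> synthetic_data.SimulationConfig:
        overrides = dict(self.simulate)
        overrides.setdefault("seed", self.seed)
        overrides.setdefault("conditions", tuple(self.conditions))
        for key in ("conditions", "proximal_weight_shifted", "intronic_weight"):
            if key in overrides and isinstance(overrides[key], list):
                overrides[key] = tuple(overrides[key])
        return synthetic_data.SimulationConfig(**overrides)


def validate_inputs(config: RunConfig) -> list[str]:
    """Consistency report for file-based inputs; empty when clean."""
    violations: list[str] = []
    if config.simulated:
        return violations
    try:
        genome = GenomeAccessor.from_fasta(config.genome_fasta)
    except Exception as exc:
        return [f"genome FASTA unreadable: {exc}"]
    chroms = set(genome.chroms())
    try:
        models = read_models_tsv(config.models_tsv)
        for m in models:
            if m.chrom not in chroms:
                violations.append(f"model {m.transcript_id}: chrom {m.chrom} not in FASTA")
            elif m.end > genome.length(m.chrom):
                violations.append(f"model {m.transcript_id}: exceeds {m.chrom} length")
    except Exception as exc:
        violations.append(f"models TSV unreadable: {exc}")
    for sample, path in config.sam_by_sample.items():
        try:
            for r in read_reads_sam(path, sample):
                if r.chrom not in chroms:
                    violations.append(f"SAM {sample}: read {r.read_id} on unknown chrom {r.chrom}")
                elif r.end > genome.length(r.chrom):
                    violations.append(f"SAM {sample}: read {r.read_id} out of bounds")
        except Exception as exc:
            violations.append(f"SAM {sample} unreadable: {exc}")
    if config.known_sites_bed:
        try:
            for chrom, start, end, *_ in read_bed6(config.known_sites_bed):
                if end <= start:
                    violations.append(f"BED record {chrom}:{start}-{end}: end <= start")
        except InputError as exc:
            violations.append(str(exc))
    return violations


def _positions_from_read_starts(reads_by_sample) -> peak_quant.PositionMap:
    """Transcript-sense 5' alignment starts, the alternative binning mode."""
    out: dict = {}
    for sample, reads in reads_by_sample.items():
        per_key: dict = {}
        for r in reads:
            pos = r.start if r.strand == "+" else r.end - 1
            per_key.setdefault((r.chrom, r.strand), []).append(pos)
        out[sample] = per_key
    return out


def _build_usage_tables(peaks, samples):
    """Per-transcript ordered 3'-UTR peak level tables (rows=ordinal j)."""
    by_tx: dict[str, list] = {}
    for p in peaks:
        if p.transcript_id and p.ordinal_j:
            by_tx.setdefault(p.transcript_id, []).append(p)
    tables = []
    for tid in sorted(by_tx):
        plist = sorted(by_tx[tid], key=lambda p: p.ordinal_j)
        if len(plist) < 2:
            continue
        counts = np.array([[p.levels.get(s, 0) for s in samples] for p in plist], float)
        tables.append(apa_stats.UsageTable(tid, list(samples), counts))
    return tables


def _build_region_tables(peaks, samples):
    """Per-transcript (intronic, 3'UTR) summed levels per condition."""
    intronic: dict[str, np.ndarray] = {}
    utr3: dict[str, np.ndarray] = {}
    for p in peaks:
        lv = np.array([p.levels.get(s, 0) for s in samples], float)
        for site in p.sites:
            if not site.transcript_id:
                continue
            store = intronic if site.region == "intron" else (
                utr3 if site.region == "utr3" else None
            )
            if store is not None:
                store[site.transcript_id] = store.get(
                    site.transcript_id, np.zeros(len(samples))
                ) + lv
                break
    tables = []
    for tid in sorted(set(intronic) & set(utr3)):
        tables.append((tid, intronic[tid], utr3[tid]))
    return tables


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setLevel(logging.INFO)
    root = logging.getLogger("apa3seq")
    root.addHandler(handler)
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)
    t0 = time.time()
    stage = "setup"
    try:
        logger.info(
            "thresholds: min_support=%d min_spacing=%d bin=%d min_peak=%d "
            "merge_gap=%d alpha=%g utr_extension=%d expr_floor=%g wig_target=%g",
            config.min_support, config.min_spacing, config.bin_size,
            config.min_peak, config.merge_gap, config.alpha,
            config.utr_extension, config.expr_floor, config.wig_target,
        )
        samples = list(config.conditions)

        stage = "inputs"
        gene_sets = {}
        if config.simulated:
            sim_cfg = config.simulation_config()
            ds = synthetic_data.simulate_dataset(sim_cfg)
            synthetic_data.write_dataset(ds, outdir / "simulated")
            genome = ds.accessor
            models = ds.models
            reads_by_sample = ds.reads_by_sample
            samples = ds.samples
            gene_sets = ds.gene_sets
            logger.info("simulated %d transcripts, %d reads",
                        len(models), len(ds.meta))
        else:
            violations = validate_inputs(config)
            if violations:
                raise InputError("; ".join(violations))
            genome = GenomeAccessor.from_fasta(config.genome_fasta)
            models = read_models_tsv(config.models_tsv)
            reads_by_sample = {
                s: read_reads_sam(p, s) for s, p in config.sam_by_sample.items()
            }
        if config.cell_cycle_genes:
            gene_sets["cell_cycle"] = read_gene_list(config.cell_cycle_genes)
        if config.processing_genes:
            gene_sets["processing"] = read_gene_list(config.processing_genes)

        stage = "tail detection"
        evidence = []
        for s in samples:
            ev = cs_discovery.detect_tails(reads_by_sample[s], genome)
            logger.info("%s: %d/%d reads carry untemplated tails",
                        s, len(ev), len(reads_by_sample[s]))
            evidence.extend(ev)

        stage = "site calling"
        profiles = cs_discovery.build_profiles(evidence)
        sites = cs_discovery.call_sites(
            profiles, min_support=config.min_support, min_spacing=config.min_spacing
        )
        cs_discovery.annotate_sites(sites, models, utr_extension=config.utr_extension)
        write_sites_bed(sites, outdir / "sites.bed")
        write_sites_tsv(sites, samples, outdir / "sites.tsv")
        region_counts = {}
        for s in sites:
            region_counts[s.region] = region_counts.get(s.region, 0) + 1
        logger.info("called %d sites: %s", len(sites), region_counts)

        known_overlap = None
        if config.known_sites_bed:
            known = read_bed6(config.known_sites_bed)
            over, novel, p = cs_discovery.compare_site_strength(sites, known)
            known_overlap = {
                "n_overlapping": len(over), "n_novel": len(novel),
                "rank_sum_p": p,
            }

        stage = "peak quantification"
        if config.quantify_mode == "cleavage":
            positions = peak_quant.positions_from_evidence(evidence)
        else:
            positions = _positions_from_read_starts(reads_by_sample)
        tracks = peak_quant.bin_reads(positions, bin_size=config.bin_size)
        peaks = peak_quant.call_all_peaks(
            tracks, min_peak=config.min_peak, merge_gap=config.merge_gap
        )
        unassigned = peak_quant.quantify_peaks(peaks, positions, samples)
        orphans = peak_quant.link_peaks_to_sites(
            peaks, sites, models, utr_extension=config.utr_extension
        )
        write_peaks_bed(peaks, samples, outdir / "peaks.bed")
        logger.info("%d peaks; %d unlinked sites; unassigned positions %s",
                    len(peaks), len(orphans), unassigned)

        stage = "differential usage"
        to_cond, from_cond = samples[0], samples[1]
        tables = _build_usage_tables(peaks, samples)
        results, untestable = apa_stats.analyze_usage_tables(
            tables, from_cond=from_cond, to_cond=to_cond, alpha=config.alpha
        )
        tally = apa_stats.direction_tally(results)
        pui = apa_stats.pui_tables(tables, pseudocount=config.pui_pseudocount)
        pui_medians = {
            c: apa_stats.proximal_pui_median(pui, c) if pui else float("nan")
            for c in samples
        }
        _write_results_tsv(results, samples, outdir / "transcript_results.tsv")

        stage = "intronic shifts"
        region_tables = _build_region_tables(peaks, samples)
        intronic = apa_stats.intronic_shift_test(region_tables, alpha=config.alpha)

        stage = "expression"
        expr = peak_quant.quantify_expression(
            positions, models, samples=samples,
            floor=config.expr_floor, utr_extension=config.utr_extension,
        )
        expr.to_csv(outdir / "expression.tsv", sep="\t")
        prolif = {}
        if gene_sets.get("cell_cycle"):
            for c in samples:
                prolif[c] = apa_stats.proliferation_index(
                    expr, gene_sets["cell_cycle"], c
                )
        geneset_p = None
        if gene_sets.get("processing"):
            fc = apa_stats.log2_fold_change(expr, samples[0], samples[1])
            geneset_p = apa_stats.geneset_shift_test(fc, gene_sets["processing"]).p_wilcoxon

        if config.write_wig:
            stage = "wig export"
            for s in samples:
                total = len(reads_by_sample[s])
                wig = cs_discovery.export_wig(reads_by_sample[s], total, sample=s)
                (outdir / f"{s}.wig").write_text(wig)

        stage = "summary"
        summary = {
            "config": {
                "seed": config.seed,
                "conditions": samples,
                "min_support": config.min_support,
                "min_spacing": config.min_spacing,
                "bin_size": config.bin_size,
                "min_peak": config.min_peak,
                "merge_gap": config.merge_gap,
                "alpha": config.alpha,
                "utr_extension": config.utr_extension,
            },
            "sites_by_region": {
                "total": len(sites), **{k: region_counts[k] for k in sorted(region_counts)}
            },
            "proximal_pui_median": pui_medians,
            "apa_shift": {
                "n_multi_cs_transcripts": len(tables),
                "n_untestable": len(untestable),
                "n_significant": tally.n,
                "k_shortened": tally.k,
                "binomial_p": tally.p_binomial,
                "log10_binomial_p": tally.log10_p,
            },
            "intronic_shift": {
                "n_tested": intronic.n_tested,
                "n_significant": intronic.n_significant,
                "k_toward_intronic": intronic.k_toward_intronic,
                "binomial_p": (
                    intronic.direction_test.p_binomial
                    if intronic.direction_test else None
                ),
            },
            "proliferation_index": prolif,
            "geneset_shift": {"processing_vs_background_p": geneset_p},
        }
        if known_overlap is not None:
            summary["known_site_overlap"] = known_overlap
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=True)
            fh.write("\n")
        logger.info("pipeline finished in %.1f s", time.time() - t0)
        return summary
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _write_results_tsv(results, samples, path) -> None:
    import pandas as pd

    rows = []
    for r in results:
        row = {
            "transcript_id": r.transcript_id,
            "chi2": r.chi2, "df": r.df, "p": r.p, "direction": r.direction,
        }
        for s in samples:
            row[f"cs_index_{s}"] = r.cs_index.get(s)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
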