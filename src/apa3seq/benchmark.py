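"""Ground-truth scoring of a full pipeline pass over simulated data.

Runs every stage on a freshly simulated dataset and scores it against the
generator's truth records: cleavage-site recovery, internal-priming
rejection, differential-usage sensitivity and specificity, plus the global
shortening statistics.  Used by the validation suite and the reproduction
script.
"""

from __future__ import annotations

import numpy as np

from . import apa_stats, cs_discovery, peak_quant
from .pipeline import _build_usage_tables
from .synthetic_data import SimulationConfig, simulate_dataset

RECOVERY_WINDOW = 5  # nt tolerance when matching called sites to truth loci
MIN_TRUTH_READS = 10  # truth loci below this pooled read count are not scored


def evaluate_recovery(config: SimulationConfig, alpha: float = 0.001) -> dict:
    """Simulate under ``config``, run the pipeline stages, score vs truth."""
    ds = simulate_dataset(config)
    reads = ds.all_reads()
    evidence = cs_discovery.detect_tails(reads, ds.accessor)
    ev_ids = {e.read_id for e in evidence}

    # internal-priming rejection: artifact reads that slipped through
    ip_ids = set(ds.meta[ds.meta.category == "ip"].read_id)
    n_ip_accepted = len(ip_ids & ev_ids)
    rejection = 1.0 - n_ip_accepted / len(ip_ids) if ip_ids else float("nan")

    # cleavage-site recovery within RECOVERY_WINDOW nt
    sites = cs_discovery.call_sites(cs_discovery.build_profiles(evidence))
    cs_discovery.annotate_sites(sites, ds.models)
    model_by = {m.transcript_id: m for m in ds.models}
    tails = ds.meta[ds.meta.category == "tail"]
    reads_per_locus = tails.groupby(["transcript_id", "cs_index"]).size()
    site_pos: dict[tuple, list[int]] = {}
    for s in sites:
        site_pos.setdefault((s.chrom, s.strand), []).append(s.position)
    n_eligible = n_recovered = 0
    for t in ds.truth:
        m = model_by[t.transcript_id]
        for i, pos in enumerate(t.cs_positions):
            if reads_per_locus.get((t.transcript_id, i), 0) < MIN_TRUTH_READS:
                continue
            n_eligible += 1
            near = site_pos.get((m.chrom, m.strand), [])
            if any(abs(p - pos) <= RECOVERY_WINDOW for p in near):
                n_recovered += 1
    recovery = n_recovered / n_eligible if n_eligible else float("nan")

    # differential usage on 3'-UTR peaks
    samples = ds.samples
    positions = peak_quant.positions_from_evidence(evidence)
    tracks = peak_quant.bin_reads(positions)
    peaks = peak_quant.call_all_peaks(tracks)
    peak_quant.quantify_peaks(peaks, positions, samples)
    peak_quant.link_peaks_to_sites(peaks, sites, ds.models)
    tables = _build_usage_tables(peaks, samples)
    results, _ = apa_stats.analyze_usage_tables(
        tables, from_cond=samples[1], to_cond=samples[0], alpha=alpha
    )
    shifted = ds.gene_sets["shifted_transcripts"]
    by_id = {r.transcript_id: r for r in results}
    n_shifted = len(shifted)
    n_hit = sum(
        1
        for tid in shifted
        if tid in by_id
        and by_id[tid].p < alpha
        and by_id[tid].direction == "shortened"
    )
    null_tested = [r for r in results if r.transcript_id not in shifted]
    n_false = sum(1 for r in null_tested if r.p < alpha)
    sensitivity = n_hit / n_shifted if n_shifted else float("nan")
    fpr = n_false / len(null_tested) if null_tested else float("nan")

    tally = apa_stats.direction_tally(results)
    pui = apa_stats.pui_tables(tables)
    pui_medians = {c: apa_stats.proximal_pui_median(pui, c) for c in samples}

    return {
        "n_reads": len(reads),
        "n_sites": len(sites),
        "n_truth_loci_scored": n_eligible,
        "cs_recovery": recovery,
        "n_internal_priming_reads": len(ip_ids),
        "internal_priming_rejection": rejection,
        "n_transcripts_tested": len(results),
        "n_shifted_truth": n_shifted,
        "shift_sensitivity": sensitivity,
        "n_null_tested": len(null_tested),
        "null_false_positive_rate": fpr,
        "n_significant": tally.n,
        "k_shortened": tally.k,
        "direction_binomial_p": tally.p_binomial,
        "proximal_pui_median": pui_medians,
    }


def proximal_pui_medians(config: SimulationConfig) -> dict:
    """Per-condition median proximal usage index from one simulated run."""
    ds = simulate_dataset(config)
    evidence = cs_discovery.detect_tails(ds.all_reads(), ds.accessor)
    sites = cs_discovery.call_sites(cs_discovery.build_profiles(evidence))
    cs_discovery.annotate_sites(sites, ds.models)
    positions = peak_quant.positions_from_evidence(evidence)
    peaks = peak_quant.call_all_peaks(peak_quant.bin_reads(positions))
    peak_quant.quantify_peaks(peaks, positions, ds.samples)
    peak_quant.link_peaks_to_sites(peaks, sites, ds.models)
    tables = _build_usage_tables(peaks, ds.samples)
    pui = apa_stats.pui_tables(tables)
    return {c: apa_stats.proximal_pui_median(pui, c) for c in ds.samples}
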