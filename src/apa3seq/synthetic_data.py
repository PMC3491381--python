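"""Synthetic 3'-Seq data with known ground truth.

The generator emulates the features of a 3'-end sequencing library that the
downstream pipeline must handle: multi-poly(A)-site transcripts whose
proximal/distal usage weights differ between cellular conditions, reads
ending in untemplated poly(A) stretches with positional jitter around the
true cleavage site, internal-priming artifact reads whose terminal A-run is
genomically templated, intronic cleavage sites, transcript-body reads
without tails, and per-base substitution errors.

Every transcript lives in its own fixed-size genomic slot with a uniform
local layout (exon1 - intron - exon2, the 3' UTR at the 3' end of exon2),
placed on either strand.  A fraction of transcripts additionally carry an
internal 12-A tract (internal-priming bait), an intronic cleavage locus,
or a distal cleavage locus 300 nt past the annotated 3' end (exercising
the 1,000-nt 3'-UTR extension used downstream).

Random A/T homopolymer runs in the background sequence are capped at 6 nt
so that the only templated tails long enough to mimic a poly(A) tail are
the deliberately planted baits; this keeps artifact-rejection and
site-recovery metrics exact.

All randomness flows from ``SimulationConfig.seed``; identical config gives
byte-identical outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .io_utils import (
    GenomeAccessor,
    write_fasta,
    write_models_bed12,
    write_models_tsv,
    write_reads_sam,
    write_reads_tsv,
    write_truth_tsv,
)
from .types import AlignedRead, TranscriptModel, TruthRecord, revcomp

# Transcript-local layout (transcript-sense coordinates, nt)
TX_LEN = 3000
SLOT = 6000  # genomic pitch per transcript, leaves >=1.5 kb flanks
FLANK = 1500  # local coordinate 0 sits FLANK nt into the slot
EXON1 = (0, 600)
INTRON = (600, 1400)
EXON2 = (1400, TX_LEN)
CDS_LOCAL = (100, 1900)
UTR3_LOCAL = (1900, TX_LEN)
INTRONIC_CS_LOCAL = 1000
BAIT_LOCAL = (1600, 1612)  # 12-A internal-priming tract, inside the CDS
FIRST_UTR3_CS = 2050
CS_PITCH = 400
EXTENSION_CS_LOCAL = TX_LEN + 300  # past the annotated 3' end
CHROM_MARGIN = 500
MIN_TEMPLATED = 15


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulated 3'-Seq experiment.

    ``conditions[0]`` plays the proliferative condition: cell-cycle and
    3'-end-processing gene sets get their expression boost there, and
    shifted transcripts use ``proximal_weight_shifted[0]`` there.
    """

    n_transcripts: int = 300
    n_cs_per_transcript: int | dict = 2  # constant, or {count: probability}
    depth_per_transcript: int = 200  # reads per transcript per condition
    read_length: int = 50
    tail_length_min: int = 8
    tail_length_poisson_mean: float = 4.0
    jitter_sd: float = 2.0
    internal_priming_rate: float = 0.1
    internal_priming_bait_fraction: float = 0.3
    body_read_fraction: float = 0.2
    error_rate: float = 0.005
    seed: int = 0
    conditions: tuple = ("proliferating", "arrested")
    shifted_fraction: float = 1.0 / 3.0
    proximal_weight_shifted: tuple = (0.7, 0.3)  # per condition
    proximal_weight_null: float = 0.5
    intronic_fraction: float = 0.15
    intronic_weight: tuple = (0.25, 0.10)  # per condition, for intronic-CS transcripts
    extension_fraction: float = 0.1
    minus_strand_fraction: float = 0.5
    cell_cycle_fraction: float = 0.10
    cell_cycle_boost: float = 4.0
    processing_fraction: float = 0.05
    processing_boost: float = 2.0
    transcripts_per_chrom: int = 50

    def validate(self) -> None:
        rates = (
            "internal_priming_rate", "internal_priming_bait_fraction",
            "body_read_fraction", "error_rate", "shifted_fraction",
            "proximal_weight_null", "intronic_fraction", "extension_fraction",
            "minus_strand_fraction", "cell_cycle_fraction", "processing_fraction",
        )
        for name in rates:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.n_transcripts < 1:
            raise ConfigError(f"n_transcripts must be >= 1, got {self.n_transcripts}")
        if self.depth_per_transcript < 1:
            raise ConfigError("depth_per_transcript must be >= 1")
        if self.tail_length_min < 8:
            raise ConfigError(
                f"tail_length_min must be >= 8 (detection floor), got {self.tail_length_min}"
            )
        if self.read_length < MIN_TEMPLATED + self.tail_length_min:
            raise ConfigError("read_length too short for tail plus anchor")
        if self.jitter_sd < 0:
            raise ConfigError("jitter_sd must be >= 0")
        if len(self.conditions) < 1:
            raise ConfigError("conditions must be non-empty")
        if len(self.proximal_weight_shifted) != len(self.conditions):
            raise ConfigError("proximal_weight_shifted must have one entry per condition")
        if len(self.intronic_weight) != len(self.conditions):
            raise ConfigError("intronic_weight must have one entry per condition")
        for w in tuple(self.proximal_weight_shifted) + tuple(self.intronic_weight):
            if not (0.0 <= w <= 1.0):
                raise ConfigError("usage weights must be in [0,1]")
        if self.internal_priming_rate + self.body_read_fraction >= 1.0:
            raise ConfigError(
                "internal_priming_rate + body_read_fraction must be < 1"
            )
        for k in self._cs_count_space():
            if not 1 <= k <= 3:
                raise ConfigError(
                    f"n_cs_per_transcript supports 1..3 sites per transcript, got {k}"
                )

    def _cs_count_space(self) -> list[int]:
        if isinstance(self.n_cs_per_transcript, dict):
            return [int(k) for k in self.n_cs_per_transcript]
        return [int(self.n_cs_per_transcript)]


@dataclass(frozen=True)
class _TranscriptPlan:
    index: int
    transcript_id: str
    gene_id: str
    chrom: str
    slot0: int
    strand: str
    n_cs: int
    has_intronic: bool
    has_bait: bool
    has_extension: bool
    shifted: bool
    cell_cycle: bool
    processing: bool

    def cs_local(self) -> list[int]:
        """Cleavage loci in transcript-local coordinates, 5'->3'."""
        utr = [FIRST_UTR3_CS + CS_PITCH * i for i in range(self.n_cs)]
        if self.has_extension:
            utr[-1] = EXTENSION_CS_LOCAL
        return ([INTRONIC_CS_LOCAL] if self.has_intronic else []) + utr

    def cs_regions(self) -> list[str]:
        return (["intron"] if self.has_intronic else []) + ["utr3"] * self.n_cs


def _pick(rng: np.random.Generator, pool: np.ndarray, fraction: float) -> set:
    k = int(round(fraction * len(pool)))
    if k == 0:
        return set()
    return set(rng.choice(pool, size=min(k, len(pool)), replace=False).tolist())


def _plan(config: SimulationConfig) -> list[_TranscriptPlan]:
    config.validate()
    rng = np.random.default_rng([config.seed % (2**31), 11])
    n = config.n_transcripts
    idx = np.arange(n)
    if isinstance(config.n_cs_per_transcript, dict):
        ks = sorted(config.n_cs_per_transcript)
        ps = np.array([config.n_cs_per_transcript[k] for k in ks], float)
        ps = ps / ps.sum()
        n_cs = rng.choice(np.array(ks, int), size=n, p=ps)
    else:
        n_cs = np.full(n, int(config.n_cs_per_transcript))
    minus = _pick(rng, idx, config.minus_strand_fraction)
    multi = idx[n_cs >= 2]
    shifted = _pick(rng, multi, config.shifted_fraction * n / max(len(multi), 1))
    intronic = _pick(rng, idx, config.intronic_fraction)
    bait = _pick(rng, idx, config.internal_priming_bait_fraction)
    extension = _pick(rng, idx, config.extension_fraction)
    cc = _pick(rng, idx, config.cell_cycle_fraction)
    remaining = np.array(sorted(set(idx.tolist()) - cc), int)
    proc = _pick(rng, remaining, config.processing_fraction * n / max(len(remaining), 1))
    plans = []
    for i in range(n):
        chrom_i = i // config.transcripts_per_chrom
        slot_i = i % config.transcripts_per_chrom
        plans.append(
            _TranscriptPlan(
                index=i,
                transcript_id=f"tx{i:04d}",
                gene_id=f"gene{i:04d}",
                chrom=f"chr{chrom_i + 1}",
                slot0=CHROM_MARGIN + slot_i * SLOT,
                strand="-" if i in minus else "+",
                n_cs=int(n_cs[i]),
                has_intronic=i in intronic,
                has_bait=i in bait,
                has_extension=i in extension,
                shifted=i in shifted,
                cell_cycle=i in cc,
                processing=i in proc,
            )
        )
    return plans


# ---------------------------------------------------------------------------
# Coordinate mapping between transcript-local and genomic frames

def local_to_genomic(plan_or_model, local: int) -> int:
    """Map a transcript-local coordinate to its genomic position."""
    if isinstance(plan_or_model, TranscriptModel):
        start, strand = plan_or_model.start, plan_or_model.strand
        slot0 = start - FLANK
    else:
        slot0, strand = plan_or_model.slot0, plan_or_model.strand
    if strand == "+":
        return slot0 + FLANK + local
    return slot0 + FLANK + TX_LEN - 1 - local + (SLOT - 2 * FLANK - TX_LEN)


def genomic_to_local(model: TranscriptModel, g: int) -> int:
    slot0 = model.start - FLANK
    if model.strand == "+":
        return g - slot0 - FLANK
    return slot0 + FLANK + TX_LEN - 1 + (SLOT - 2 * FLANK - TX_LEN) - g


def _local_interval_to_genomic(plan, a: int, b: int) -> tuple[int, int]:
    if plan.strand == "+":
        return (local_to_genomic(plan, a), local_to_genomic(plan, b - 1) + 1)
    return (local_to_genomic(plan, b - 1), local_to_genomic(plan, a) + 1)


# ---------------------------------------------------------------------------
# Reference construction

_A_RUN = re.compile(r"A{7,}")
_T_RUN = re.compile(r"T{7,}")


def _cap_runs(seq: np.ndarray) -> None:
    """Break every A- or T-homopolymer longer than 6 nt in place."""
    s = "".join(seq)
    for pat, repl in ((_A_RUN, "C"), (_T_RUN, "G")):
        for m in pat.finditer(s):
            for p in range(m.start() + 6, m.end(), 7):
                seq[p] = repl


def _model_from_plan(plan: _TranscriptPlan) -> TranscriptModel:
    exons = [
        _local_interval_to_genomic(plan, *EXON1),
        _local_interval_to_genomic(plan, *EXON2),
    ]
    exons.sort()
    return TranscriptModel(
        transcript_id=plan.transcript_id,
        gene_id=plan.gene_id,
        chrom=plan.chrom,
        strand=plan.strand,
        exons=tuple(exons),
        utr3=_local_interval_to_genomic(plan, *UTR3_LOCAL),
        cds=_local_interval_to_genomic(plan, *CDS_LOCAL),
    )


def build_reference(config: SimulationConfig):
    """Build the reference genome and transcript models.

    Returns ``(genome, models)`` where ``genome`` maps chromosome name to
    sequence.  Deterministic under ``config.seed``.
    """
    plans = _plan(config)
    rng = np.random.default_rng([config.seed % (2**31), 13])
    bases = np.array(list("ACGT"))
    safe = np.array(list("CGT"))
    chrom_slots: dict[str, list[str]] = {}
    for plan in plans:
        slot = rng.choice(bases, size=SLOT)
        _cap_runs(slot)
        for c in plan.cs_local():
            lo, hi = FLANK + c - 8, FLANK + c + 16
            slot[lo:hi] = rng.choice(safe, size=hi - lo)
        if plan.has_bait:
            slot[FLANK + BAIT_LOCAL[0] : FLANK + BAIT_LOCAL[1]] = "A"
        text = "".join(slot)
        if plan.strand == "-":
            text = revcomp(text)
        chrom_slots.setdefault(plan.chrom, []).append(text)
    genome = {}
    for chrom in sorted(chrom_slots, key=lambda c: int(c[3:])):
        margin_l = "".join(rng.choice(safe, size=CHROM_MARGIN))
        margin_r = "".join(rng.choice(safe, size=CHROM_MARGIN))
        genome[chrom] = margin_l + "".join(chrom_slots[chrom]) + margin_r
    models = [_model_from_plan(p) for p in plans]
    return genome, models


def make_truth(config: SimulationConfig) -> list[TruthRecord]:
    """Ground-truth cleavage loci and per-condition usage weights."""
    truth = []
    for plan in _plan(config):
        locals_ = plan.cs_local()
        regions = plan.cs_regions()
        positions = [local_to_genomic(plan, c) for c in locals_]
        weights = {}
        for ci, cond in enumerate(config.conditions):
            v = config.intronic_weight[ci] if plan.has_intronic else 0.0
            m = plan.n_cs
            if m == 1:
                utr = [1.0]
            else:
                w = (
                    config.proximal_weight_shifted[ci]
                    if plan.shifted
                    else config.proximal_weight_null
                )
                utr = [w] + [(1.0 - w) / (m - 1)] * (m - 1)
            full = ([v] if plan.has_intronic else []) + [u * (1.0 - v) for u in utr]
            weights[cond] = tuple(full)
        truth.append(
            TruthRecord(plan.transcript_id, tuple(positions), tuple(regions), weights)
        )
    return truth


def gene_sets(config: SimulationConfig) -> dict[str, set[str]]:
    """Gene identifiers of the planted cell-cycle and 3'-end-processing sets."""
    plans = _plan(config)
    return {
        "cell_cycle": {p.gene_id for p in plans if p.cell_cycle},
        "processing": {p.gene_id for p in plans if p.processing},
        "shifted_transcripts": {p.transcript_id for p in plans if p.shifted},
    }


# ---------------------------------------------------------------------------
# Read simulation

def _tx_fetch(genome: GenomeAccessor, model: TranscriptModel, a: int, b: int) -> str:
    """Transcript-sense genomic sequence over local interval [a, b)."""
    if model.strand == "+":
        g0 = local_to_genomic(model, a)
        return genome.fetch(model.chrom, g0, g0 + (b - a))
    g0 = local_to_genomic(model, b - 1)
    return revcomp(genome.fetch(model.chrom, g0, g0 + (b - a)))


def _apply_errors(rng, seq: list, n_templated: int, error_rate: float) -> None:
    if error_rate <= 0 or n_templated == 0:
        return
    k = rng.binomial(n_templated, error_rate)
    if k == 0:
        return
    positions = rng.choice(n_templated, size=k, replace=False)
    for p in positions:
        alt = [b for b in "ACGT" if b != seq[p]]
        seq[p] = alt[rng.integers(0, 3)]


def simulate_reads(genome, models, truth, config: SimulationConfig):
    """Sample aligned 3'-Seq reads for every condition.

    Returns ``(reads_by_sample, meta)``: one list of :class:`AlignedRead`
    per condition sample, plus a per-read metadata table (category,
    originating cleavage locus, emitted jittered cleavage position) used
    for recovery scoring.
    """
    config.validate()
    if not isinstance(genome, GenomeAccessor):
        genome = GenomeAccessor(genome)
    model_by_id = {m.transcript_id: m for m in models}
    for t in truth:
        if t.transcript_id not in model_by_id:
            raise InputError(f"truth references unknown transcript {t.transcript_id!r}")
    plans = {p.transcript_id: p for p in _plan(config)}
    rng = np.random.default_rng([config.seed % (2**31), 17])
    jitter_cap = int(np.ceil(3 * config.jitter_sd))
    max_tail = config.read_length - MIN_TEMPLATED

    reads_by_sample: dict[str, list[AlignedRead]] = {c: [] for c in config.conditions}
    meta_rows = []
    truth_sorted = sorted(truth, key=lambda t: t.transcript_id)

    for ci, cond in enumerate(config.conditions):
        for rec in truth_sorted:
            model = model_by_id[rec.transcript_id]
            plan = plans.get(rec.transcript_id)
            # bait presence read off the genome, not the plan
            has_bait = _tx_fetch(genome, model, *BAIT_LOCAL) == "A" * (
                BAIT_LOCAL[1] - BAIT_LOCAL[0]
            )
            boost = 1.0
            if ci == 0 and plan is not None:
                if plan.cell_cycle:
                    boost *= config.cell_cycle_boost
                if plan.processing:
                    boost *= config.processing_boost
            depth = int(round(config.depth_per_transcript * boost))
            p_ip = config.internal_priming_rate if has_bait else 0.0
            p_body = config.body_read_fraction
            n_tail, n_body, n_ip = rng.multinomial(
                depth, [1.0 - p_ip - p_body, p_body, p_ip]
            )
            weights = np.asarray(rec.usage_weights[cond], float)
            per_cs = rng.multinomial(n_tail, weights / weights.sum())
            serial = 0

            def emit(seq_list, local_start, templated, category, cs_i, cs_g, emit_g):
                nonlocal serial
                rid = f"{rec.transcript_id}|{cond}|{serial}"
                serial += 1
                a, b = local_start, local_start + templated
                if model.strand == "+":
                    gs, ge = local_to_genomic(model, a), local_to_genomic(model, b - 1) + 1
                else:
                    gs, ge = local_to_genomic(model, b - 1), local_to_genomic(model, a) + 1
                reads_by_sample[cond].append(
                    AlignedRead(rid, cond, model.chrom, model.strand, gs, ge, "".join(seq_list))
                )
                meta_rows.append(
                    (rid, cond, rec.transcript_id, category, cs_i, cs_g, emit_g)
                )
            # tailed reads
            for cs_i, count in enumerate(per_cs):
                c_local = genomic_to_local(model, rec.cs_positions[cs_i])
                for _ in range(count):
                    d = 0
                    if config.jitter_sd > 0:
                        d = int(
                            np.clip(
                                round(rng.normal(0.0, config.jitter_sd)),
                                -jitter_cap,
                                jitter_cap,
                            )
                        )
                    c_j = c_local + d
                    tail = min(
                        config.tail_length_min + rng.poisson(config.tail_length_poisson_mean),
                        max_tail,
                    )
                    m_len = config.read_length - tail
                    body = list(_tx_fetch(genome, model, c_j - m_len, c_j))
                    _apply_errors(rng, body, m_len, config.error_rate)
                    seq = body + ["A"] * tail
                    emit(
                        seq, c_j - m_len, m_len, "tail", cs_i,
                        rec.cs_positions[cs_i], local_to_genomic(model, c_j),
                    )
            # body reads (no tail); avoid 3'-ends inside the bait tract
            rl = config.read_length
            windows = [
                (EXON1[0], EXON1[1] - rl),
                (EXON2[0], EXON2[1] - rl),
            ]
            for _ in range(n_body):
                for _try in range(30):
                    w = windows[rng.integers(0, len(windows))]
                    b = int(rng.integers(w[0], w[1] + 1))
                    read_end = b + rl
                    if has_bait and BAIT_LOCAL[0] < read_end <= BAIT_LOCAL[1] + 1:
                        continue
                    break
                seq = list(_tx_fetch(genome, model, b, b + rl))
                _apply_errors(rng, seq, rl, config.error_rate)
                emit(seq, b, rl, "body", -1, -1, -1)
            # internal-priming reads: terminal run templated from the bait
            for _ in range(n_ip):
                end = int(rng.integers(BAIT_LOCAL[0] + 8, BAIT_LOCAL[1] + 1))
                seq = list(_tx_fetch(genome, model, end - rl, end))
                _apply_errors(rng, seq, rl, config.error_rate)
                emit(seq, end - rl, rl, "ip", -1, -1, -1)

    meta = pd.DataFrame(
        meta_rows,
        columns=[
            "read_id", "sample", "transcript_id", "category",
            "cs_index", "cs_genomic", "cleavage_genomic",
        ],
    )
    return reads_by_sample, meta


# ---------------------------------------------------------------------------
# One-call dataset assembly and on-disk export

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict
    models: list
    truth: list
    reads_by_sample: dict
    meta: pd.DataFrame
    gene_sets: dict = field(default_factory=dict)

    @property
    def accessor(self) -> GenomeAccessor:
        return GenomeAccessor(self.genome)

    @property
    def samples(self) -> list[str]:
        return list(self.config.conditions)

    def all_reads(self) -> list[AlignedRead]:
        return [r for s in self.samples for r in self.reads_by_sample[s]]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    genome, models = build_reference(config)
    truth = make_truth(config)
    reads, meta = simulate_reads(genome, models, truth, config)
    return SimulatedDataset(
        config=config,
        genome=genome,
        models=models,
        truth=truth,
        reads_by_sample=reads,
        meta=meta,
        gene_sets=gene_sets(config),
    )


def write_dataset(ds: SimulatedDataset, outdir) -> dict:
    """Write every artifact (FASTA, BED12/TSV models, per-sample SAM, read
    and truth TSVs, gene lists); returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "models_tsv": outdir / "models.tsv",
        "models_bed": outdir / "models.bed12",
        "reads_tsv": outdir / "reads.tsv",
        "truth": outdir / "truth.tsv",
        "meta": outdir / "read_meta.tsv",
        "cell_cycle": outdir / "cell_cycle_genes.txt",
        "processing": outdir / "processing_genes.txt",
    }
    write_fasta(ds.genome, paths["genome"])
    write_models_tsv(ds.models, paths["models_tsv"])
    write_models_bed12(ds.models, paths["models_bed"])
    write_truth_tsv(ds.truth, paths["truth"])
    write_reads_tsv(ds.all_reads(), paths["reads_tsv"])
    ds.meta.to_csv(paths["meta"], sep="\t", index=False)
    chrom_lengths = {c: len(s) for c, s in ds.genome.items()}
    for sample in ds.samples:
        p = outdir / f"reads_{sample}.sam"
        write_reads_sam(ds.reads_by_sample[sample], chrom_lengths, p)
        paths[f"sam_{sample}"] = p
    for key in ("cell_cycle", "processing"):
        with open(paths[key], "w") as fh:
            for g in sorted(ds.gene_sets.get(key, ())):
                fh.write(g + "\n")
    return paths
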