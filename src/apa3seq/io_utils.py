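"""Readers and writers for the standard formats the pipeline touches.

FASTA is read back through pyfaidx, SAM through pysam; everything the
package writes (FASTA, SAM, BED, TSV, WIG) is plain text.  File formats use
their native coordinate conventions (SAM/WIG 1-based, BED 0-based
half-open); all in-memory structures stay 0-based half-open.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
import pysam
from pyfaidx import Fasta

from .errors import BoundsError, InputError
from .types import AlignedRead, CleavageSite, Peak, TranscriptModel, TruthRecord, revcomp


class GenomeAccessor:
    """Uniform random access to reference sequence, from memory or FASTA."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: str(s).upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "GenomeAccessor":
        fa = Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        try:
            return len(self._seqs[chrom])
        except KeyError:
            raise InputError(f"unknown chromosome {chrom!r}")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs.get(chrom)
        if seq is None:
            raise InputError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(seq):
            raise BoundsError(
                f"{chrom}:{start}-{end} outside sequence of length {len(seq)}"
            )
        return seq[start:end]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Transcript models (TSV twin + BED12)

_MODEL_COLS = [
    "transcript_id", "gene_id", "chrom", "strand",
    "exon_starts", "exon_ends", "utr3_start", "utr3_end",
    "cds_start", "cds_end",
]


def write_models_tsv(models: Iterable[TranscriptModel], path) -> None:
    rows = []
    for m in models:
        rows.append({
            "transcript_id": m.transcript_id,
            "gene_id": m.gene_id,
            "chrom": m.chrom,
            "strand": m.strand,
            "exon_starts": ",".join(str(s) for s, _ in m.exons),
            "exon_ends": ",".join(str(e) for _, e in m.exons),
            "utr3_start": m.utr3[0],
            "utr3_end": m.utr3[1],
            "cds_start": m.cds[0] if m.cds else "",
            "cds_end": m.cds[1] if m.cds else "",
        })
    pd.DataFrame(rows, columns=_MODEL_COLS).to_csv(path, sep="\t", index=False)


def read_models_tsv(path) -> list[TranscriptModel]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    models = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in row.exon_starts.split(",")]
        ends = [int(x) for x in row.exon_ends.split(",")]
        cds = (int(row.cds_start), int(row.cds_end)) if row.cds_start != "" else None
        models.append(
            TranscriptModel(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                exons=tuple(zip(starts, ends)),
                utr3=(int(row.utr3_start), int(row.utr3_end)),
                cds=cds,
            )
        )
    return models


def write_models_bed12(models: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            block_sizes = ",".join(str(e - s) for s, e in m.exons)
            block_starts = ",".join(str(s - m.start) for s, _ in m.exons)
            thick = m.cds or (m.start, m.start)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        m.chrom, m.start, m.end, m.transcript_id, 0, m.strand,
                        thick[0], thick[1], "0,0,0", len(m.exons),
                        block_sizes, block_starts,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Truth table

def write_truth_tsv(truth: Iterable[TruthRecord], path) -> None:
    rows = []
    for t in truth:
        for cond, weights in t.usage_weights.items():
            for pos, region, w in zip(t.cs_positions, t.cs_region, weights):
                rows.append(
                    {
                        "transcript_id": t.transcript_id,
                        "position": pos,
                        "region": region,
                        "condition": cond,
                        "weight": w,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    truth = []
    for tid, sub in df.groupby("transcript_id", sort=True):
        conds = {}
        first = sub[sub.condition == sub.condition.iloc[0]].sort_values("position")
        positions = tuple(first.position)
        regions = tuple(first.region)
        for cond, csub in sub.groupby("condition"):
            csub = csub.sort_values("position")
            conds[cond] = tuple(csub.weight)
        truth.append(TruthRecord(str(tid), positions, regions, conds))
    return truth


# ---------------------------------------------------------------------------
# Reads: SAM (one file per sample) and TSV twin

def write_reads_sam(reads: Iterable[AlignedRead], chrom_lengths: Mapping[str, int], path) -> None:
    """Minimal SAM: FLAG carries strand, CIGAR is <m>M with a soft-clip for
    any untemplated tail, SEQ in genome-forward orientation."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for r in reads:
            m = r.end - r.start
            tail = len(r.seq) - m
            if r.strand == "+":
                flag = 0
                cigar = f"{m}M{tail}S" if tail else f"{m}M"
                seq_out = r.seq
            else:
                flag = 16
                cigar = f"{tail}S{m}M" if tail else f"{m}M"
                seq_out = revcomp(r.seq)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.read_id, flag, r.chrom, r.start + 1, 255, cigar,
                        "*", 0, 0, seq_out, "*",
                    )
                )
                + "\n"
            )


def read_reads_sam(path, sample: str) -> list[AlignedRead]:
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            seq = aln.query_sequence or ""
            if strand == "-":
                seq = revcomp(seq)
            reads.append(
                AlignedRead(
                    read_id=aln.query_name,
                    sample=sample,
                    chrom=aln.reference_name,
                    strand=strand,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    seq=seq,
                )
            )
    return reads


_READ_COLS = ["read_id", "sample", "chrom", "strand", "start", "end", "seq"]


def write_reads_tsv(reads: Iterable[AlignedRead], path) -> None:
    rows = [[r.read_id, r.sample, r.chrom, r.strand, r.start, r.end, r.seq] for r in reads]
    pd.DataFrame(rows, columns=_READ_COLS).to_csv(path, sep="\t", index=False)


def read_reads_tsv(path) -> list[AlignedRead]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "read_id": str, "sample": str})
    return [
        AlignedRead(r.read_id, r.sample, r.chrom, r.strand, int(r.start), int(r.end), r.seq)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Cleavage sites and peaks

def write_sites_bed(sites: Iterable[CleavageSite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            name = s.transcript_id or "."
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t{name}\t{s.total_support}\t{s.strand}\n"
            )


def write_sites_tsv(sites: list[CleavageSite], samples: list[str], path) -> None:
    rows = []
    for s in sites:
        row = {
            "chrom": s.chrom,
            "strand": s.strand,
            "position": s.position,
            "region": s.region,
            "transcript_id": s.transcript_id or "",
            "total_support": s.total_support,
        }
        for smp in samples:
            row[f"support_{smp}"] = s.support.get(smp, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> list[CleavageSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    support_cols = [c for c in df.columns if c.startswith("support_")]
    sites = []
    for row in df.itertuples(index=False):
        support = {c[len("support_"):]: int(getattr(row, c)) for c in support_cols}
        sites.append(
            CleavageSite(
                chrom=row.chrom,
                strand=row.strand,
                position=int(row.position),
                support=support,
                region=row.region,
                transcript_id=row.transcript_id or None,
            )
        )
    return sites


def read_bed6(path) -> list[tuple[str, int, int, str, float, str]]:
    """BED6 records (chrom, start, end, name, score, strand); short rows padded."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"malformed BED line: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            out.append((chrom, start, end, name, score, strand))
    return out


def write_peaks_bed(peaks: list[Peak], samples: list[str], path) -> None:
    """BED6+ with per-sample levels, ordinal and transcript as extra columns."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tname\tscore\tstrand\t"
            + "\t".join(f"level_{s}" for s in samples)
            + "\tordinal_j\ttranscript_id\n"
        )
        for i, p in enumerate(peaks):
            levels = [str(p.levels.get(s, 0)) for s in samples]
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{sum(p.levels.values())}\t{p.strand}\t"
                + "\t".join(levels)
                + f"\t{p.ordinal_j if p.ordinal_j else '.'}\t{p.transcript_id or '.'}\n"
            )


def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
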