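"""Peak construction over 5-nt bins and usage/expression quantification.

Chromosomes are divided into fixed 5-nt bins anchored at coordinate 0.
Per-sample counts of inferred cleavage positions are reduced to the
per-bin maximum over samples so that peak boundaries are shared by all
samples of a dataset; runs of non-empty bins whose maximum reaches 3
reads become peaks, and peaks separated by less than 60 nt are merged
(transitively).  Peak levels E_j — the per-sample count of cleavage
positions inside the peak — are the quantities entering the usage
statistics.
"""

from __future__ import annotations

import bisect
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .types import CleavageSite, Peak, TailEvidence, TranscriptModel

logger = logging.getLogger(__name__)

BIN_SIZE = 5
MIN_PEAK = 3
MERGE_GAP = 60
SITE_LINK_WINDOW = 30
EXPRESSION_FLOOR = 5.0
UTR_EXTENSION = 1000

PositionMap = dict[str, dict[tuple, list[int]]]  # sample -> (chrom,strand) -> positions


def positions_from_evidence(evidence: Iterable[TailEvidence]) -> PositionMap:
    """Group inferred cleavage positions by sample and (chrom, strand)."""
    out: PositionMap = defaultdict(lambda: defaultdict(list))
    for ev in evidence:
        out[ev.sample][(ev.chrom, ev.strand)].append(ev.cleavage_pos)
    return {s: dict(v) for s, v in out.items()}


@dataclass
class BinTrack:
    """Per-(chrom, strand) binned counts, per sample plus the across-sample max."""

    chrom: str
    strand: str
    bin_size: int = BIN_SIZE
    counts: dict = field(default_factory=dict)  # sample -> Counter(bin_index)
    max_counts: Counter = field(default_factory=Counter)


def bin_reads(positions: PositionMap, bin_size: int = BIN_SIZE) -> dict[tuple, BinTrack]:
    """Bin per-sample positions; ``max_counts`` is the per-bin maximum over samples."""
    tracks: dict[tuple, BinTrack] = {}
    for sample in sorted(positions):
        for key, pos_list in positions[sample].items():
            track = tracks.get(key)
            if track is None:
                track = tracks[key] = BinTrack(chrom=key[0], strand=key[1], bin_size=bin_size)
            c = Counter()
            for p in pos_list:
                if p < 0:
                    raise InputError(f"negative position {p} on {key}")
                c[p // bin_size] += 1
            track.counts[sample] = c
            for b, n in c.items():
                if n > track.max_counts[b]:
                    track.max_counts[b] = n
    return tracks


def call_peaks(
    track: BinTrack, min_peak: int = MIN_PEAK, merge_gap: int = MERGE_GAP
) -> list[Peak]:
    """Peaks from one bin track: maximal runs of non-empty bins kept when the
    run's maximum bin count >= ``min_peak``; kept peaks closer than
    ``merge_gap`` nt are merged transitively."""
    bins = sorted(b for b, n in track.max_counts.items() if n > 0)
    if not bins:
        return []
    bs = track.bin_size
    runs: list[tuple[int, int]] = []
    run_start = prev = bins[0]
    for b in bins[1:]:
        if b == prev + 1:
            prev = b
            continue
        runs.append((run_start, prev))
        run_start = prev = b
    runs.append((run_start, prev))
    kept = [
        (b0 * bs, (b1 + 1) * bs)
        for b0, b1 in runs
        if max(track.max_counts[b] for b in range(b0, b1 + 1)) >= min_peak
    ]
    merged: list[list[int]] = []
    for s, e in kept:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [Peak(chrom=track.chrom, strand=track.strand, start=s, end=e) for s, e in merged]


def call_all_peaks(
    tracks: dict[tuple, BinTrack], min_peak: int = MIN_PEAK, merge_gap: int = MERGE_GAP
) -> list[Peak]:
    peaks = []
    for key in sorted(tracks):
        peaks.extend(call_peaks(tracks[key], min_peak=min_peak, merge_gap=merge_gap))
    return peaks


def quantify_peaks(
    peaks: Sequence[Peak], positions: PositionMap, samples: Sequence[str] | None = None
) -> dict[str, int]:
    """Fill per-sample peak levels; returns per-sample counts of cleavage
    positions falling outside every peak (unassigned)."""
    if samples is None:
        samples = sorted(positions)
    by_key: dict[tuple, list[Peak]] = defaultdict(list)
    for p in peaks:
        p.levels = {s: 0 for s in samples}
        by_key[(p.chrom, p.strand)].append(p)
    for v in by_key.values():
        v.sort(key=lambda p: p.start)
    unassigned = {s: 0 for s in samples}
    for sample in samples:
        for key, pos_list in positions.get(sample, {}).items():
            plist = by_key.get(key, [])
            starts = [p.start for p in plist]
            for pos in pos_list:
                i = bisect.bisect_right(starts, pos) - 1
                if i >= 0 and plist[i].contains(pos):
                    plist[i].levels[sample] += 1
                else:
                    unassigned[sample] += 1
    return unassigned


def link_peaks_to_sites(
    peaks: Sequence[Peak],
    sites: Sequence[CleavageSite],
    models: Sequence[TranscriptModel],
    link_window: int = SITE_LINK_WINDOW,
    utr_extension: int = UTR_EXTENSION,
) -> list[CleavageSite]:
    """Attach called sites to peaks and assign 3'-UTR peak ordinals.

    Each site maps to the peak containing it, else the nearest peak within
    ``link_window`` nt; unassignable sites are returned (and logged).
    Peaks holding a 3'-UTR site of a transcript get ``ordinal_j`` 1..N in
    5'->3' transcript orientation.
    """
    by_key: dict[tuple, list[Peak]] = defaultdict(list)
    for p in peaks:
        by_key[(p.chrom, p.strand)].append(p)
    for v in by_key.values():
        v.sort(key=lambda p: p.start)
    orphans: list[CleavageSite] = []
    for site in sites:
        plist = by_key.get((site.chrom, site.strand), [])
        best, bestd = None, None
        for p in plist:
            d = p.distance(site.position)
            if bestd is None or d < bestd:
                best, bestd = p, d
        if best is None or bestd > link_window:
            logger.info(
                "site %s:%d(%s) has no peak within %d nt; excluded",
                site.chrom, site.position, site.strand, link_window,
            )
            orphans.append(site)
            continue
        best.sites.append(site)
    # ordinals per transcript over 3'-UTR peaks
    tx_peaks: dict[str, list[Peak]] = defaultdict(list)
    strand_of = {m.transcript_id: m.strand for m in models}
    for p in peaks:
        utr_sites = [s for s in p.sites if s.region == "utr3" and s.transcript_id]
        if not utr_sites:
            continue
        primary = max(utr_sites, key=lambda s: s.total_support)
        p.transcript_id = primary.transcript_id
        tx_peaks[p.transcript_id].append(p)
    for tid, plist in tx_peaks.items():
        plist.sort(key=lambda p: p.start, reverse=strand_of.get(tid) == "-")
        for j, p in enumerate(plist, start=1):
            p.ordinal_j = j
    return orphans


def quantify_expression(
    positions: PositionMap,
    models: Sequence[TranscriptModel],
    samples: Sequence[str] | None = None,
    floor: float = EXPRESSION_FLOOR,
    utr_extension: int = UTR_EXTENSION,
    normalize: bool = True,
) -> pd.DataFrame:
    """Gene x sample expression: cleavage positions in each gene's extended
    3' UTR, quantile-normalized across samples, then floored at ``floor``."""
    if not models:
        raise InputError("no transcript models supplied")
    if samples is None:
        samples = sorted(positions)
    genes = sorted({m.gene_id for m in models})
    mat = pd.DataFrame(0.0, index=genes, columns=list(samples))
    by_key: dict[tuple, list[tuple[int, int, str]]] = defaultdict(list)
    for m in models:
        s, e = m.extended_utr3(utr_extension)
        by_key[(m.chrom, m.strand)].append((s, e, m.gene_id))
    for sample in samples:
        for key, pos_list in positions.get(sample, {}).items():
            feats = by_key.get(key, [])
            for pos in pos_list:
                for s, e, gid in feats:
                    if s <= pos < e:
                        mat.loc[gid, sample] += 1
                        break
    if normalize:
        mat = quantile_normalize(mat)
    return mat.clip(lower=floor)


def quantile_normalize(df: pd.DataFrame, ties: str = "average") -> pd.DataFrame:
    """Force identical marginal distributions across columns.

    Each column's values are replaced by the mean-of-sorted-values profile
    at their within-column rank.  ``ties='average'`` interpolates tied
    ranks (tied entries share one value); ``ties='first'`` breaks ties by
    row order, which makes the sorted columns exactly identical.
    """
    if ties not in ("average", "first"):
        raise InputError(f"ties must be 'average' or 'first', got {ties!r}")
    values = df.to_numpy(dtype=float)
    profile = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = pd.Series(values[:, j])
        ranks = col.rank(method=ties).to_numpy()
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = (profile[lo] + profile[hi]) / 2.0
    return pd.DataFrame(out, index=df.index, columns=df.columns)
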