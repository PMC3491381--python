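"""Poly(A) cleavage-site discovery from aligned 3'-Seq reads.

A read supports a cleavage call when its transcript-sense 3' terminus
carries a maximal A-run of at least 8 nt of which at least 5 of the first
8 mismatch the reference — the internal-priming filter: artifact reads
primed at genomically A-rich tracts have templated (matching) A-runs and
are rejected.  Per-position tallies of such evidence form cleavage-site
profiles; sites are the profile local maxima, subject to a minimum spacing
of 50 nt (the stronger of two close candidates wins) and a minimum pooled
support of 10 reads.
"""

from __future__ import annotations

import bisect
import logging
from collections import Counter, defaultdict
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .errors import InputError
from .io_utils import GenomeAccessor
from .types import (
    AlignedRead,
    CleavageSite,
    TailEvidence,
    TranscriptModel,
    revcomp,
)

logger = logging.getLogger(__name__)

MIN_TAIL_RUN = 8
MIN_MISMATCHES = 5
CHECK_WINDOW = 8
MIN_SUPPORT = 10
MIN_SPACING = 50
UTR_EXTENSION = 1000


# ---------------------------------------------------------------------------
# Tail detection

def detect_tail(
    read: AlignedRead,
    reference: GenomeAccessor,
    min_run: int = MIN_TAIL_RUN,
    min_mismatches: int = MIN_MISMATCHES,
) -> TailEvidence | None:
    """Detect an untemplated poly(A) tail at the read's 3' terminus.

    Returns evidence iff the maximal terminal A-run has length >= ``min_run``
    and at least ``min_mismatches`` of its first 8 bases mismatch the
    reference at the corresponding transcript-sense genomic positions
    (reference N counts as a mismatch).  The cleavage position is the
    genomic coordinate of the run's first base.
    """
    seq = read.seq
    n = len(seq)
    run = 0
    while run < n and seq[n - 1 - run] == "A":
        run += 1
    if run < min_run:
        return None
    idx = n - run  # index of run start within the transcript-sense read
    # genomic position of read base i: the read 5' end anchors at the
    # aligned span's 5' edge in transcript orientation
    if read.strand == "+":
        first = read.start + idx
        ref = reference.fetch(read.chrom, first, first + CHECK_WINDOW)
    else:
        anchor = read.end - 1
        first = anchor - idx
        ref = revcomp(reference.fetch(read.chrom, first - CHECK_WINDOW + 1, first + 1))
    mismatches = sum(1 for b in ref[:CHECK_WINDOW] if b != "A")
    if mismatches < min_mismatches:
        return None
    cleavage = read.start + idx if read.strand == "+" else read.end - 1 - idx
    return TailEvidence(
        read_id=read.read_id,
        sample=read.sample,
        chrom=read.chrom,
        strand=read.strand,
        cleavage_pos=cleavage,
        stretch_len=run,
        mismatches_in_first8=mismatches,
    )


def detect_tails(
    reads: Iterable[AlignedRead], reference: GenomeAccessor, **kwargs
) -> list[TailEvidence]:
    out = []
    for read in reads:
        ev = detect_tail(read, reference, **kwargs)
        if ev is not None:
            out.append(ev)
    return out


# ---------------------------------------------------------------------------
# Profiles

def build_profiles(evidence: Iterable[TailEvidence]) -> dict:
    """Per (chrom, strand, sample) cleavage-site profile: position -> read count."""
    profiles: dict[tuple, Counter] = defaultdict(Counter)
    for ev in evidence:
        profiles[(ev.chrom, ev.strand, ev.sample)][ev.cleavage_pos] += 1
    return dict(profiles)


def _local_maxima(counts: Counter, window: int, strand: str) -> list[int]:
    """Positions whose count >= every neighbour within +-window; among ties
    within a window only the 5'-most (strand-aware) survives."""
    positions = sorted(counts)
    maxima = []
    for i, p in enumerate(positions):
        c = counts[p]
        keep = True
        # scan neighbours within the window on both sides
        j = i - 1
        while j >= 0 and p - positions[j] <= window:
            q = positions[j]
            cq = counts[q]
            if cq > c or (cq == c and (q < p if strand == "+" else q > p)):
                keep = False
                break
            j -= 1
        if keep:
            j = i + 1
            while j < len(positions) and positions[j] - p <= window:
                q = positions[j]
                cq = counts[q]
                if cq > c or (cq == c and (q < p if strand == "+" else q > p)):
                    keep = False
                    break
                j += 1
        if keep:
            maxima.append(p)
    return maxima


def call_sites(
    profiles: dict,
    min_support: int = MIN_SUPPORT,
    min_spacing: int = MIN_SPACING,
    assign_window: int | None = None,
) -> list[CleavageSite]:
    """Call cleavage sites from per-sample profiles pooled over samples.

    Candidates are local maxima of the pooled profile; candidates closer
    than ``min_spacing`` are resolved greedily in favour of the stronger;
    each evidence count is then assigned to the nearest surviving candidate
    within ``assign_window`` (default half the spacing) and candidates with
    pooled support below ``min_support`` are dropped.
    """
    if assign_window is None:
        assign_window = min_spacing // 2
    pooled: dict[tuple, Counter] = defaultdict(Counter)
    by_sample: dict[tuple, dict[str, Counter]] = defaultdict(dict)
    for (chrom, strand, sample), counts in profiles.items():
        pooled[(chrom, strand)].update(counts)
        by_sample[(chrom, strand)][sample] = counts

    sites: list[CleavageSite] = []
    for key in sorted(pooled):
        chrom, strand = key
        counts = pooled[key]
        candidates = _local_maxima(counts, min_spacing, strand)
        # greedy spacing resolution, strongest first; ties 5'-most first
        order = sorted(
            candidates,
            key=lambda p: (-counts[p], p if strand == "+" else -p),
        )
        accepted: list[int] = []
        for p in order:
            if all(abs(p - q) >= min_spacing for q in accepted):
                accepted.append(p)
        accepted.sort()
        if not accepted:
            continue
        # assign every evidence position to the nearest accepted candidate
        support: dict[int, Counter] = {p: Counter() for p in accepted}
        for sample, sc in by_sample[key].items():
            for pos, cnt in sc.items():
                best, bestd = None, None
                for p in accepted:  # accepted lists are short per locus
                    d = abs(pos - p)
                    if bestd is None or d < bestd or (
                        d == bestd and ((p < best) == (strand == "+"))
                    ):
                        best, bestd = p, d
                if bestd is not None and bestd <= assign_window:
                    support[best][sample] += cnt
        for p in accepted:
            total = sum(support[p].values())
            if total >= min_support:
                sites.append(
                    CleavageSite(
                        chrom=chrom, strand=strand, position=p,
                        support=dict(support[p]),
                    )
                )
    sites.sort(key=lambda s: (s.chrom, s.strand, s.position))
    return sites


# ---------------------------------------------------------------------------
# Region annotation

_REGION_PRIORITY = {"utr3": 0, "intron": 1, "cds": 2}


def annotate_sites(
    sites: Sequence[CleavageSite],
    models: Sequence[TranscriptModel],
    utr_extension: int = UTR_EXTENSION,
) -> list[CleavageSite]:
    """Label each site utr3 / intron / cds / intergenic (strand-aware).

    The annotated 3' UTR is extended ``utr_extension`` nt downstream in
    transcript orientation before containment is tested.  When overlapping
    transcripts disagree the highest-priority region wins
    (utr3 > intron > cds > intergenic).
    """
    trees: dict[tuple, IntervalTree] = defaultdict(IntervalTree)
    for m in models:
        for s, e in ((m.extended_utr3(utr_extension)),):
            if e > s:
                trees[(m.chrom, m.strand)].addi(s, e, ("utr3", m.transcript_id))
        for s, e in m.introns():
            trees[(m.chrom, m.strand)].addi(s, e, ("intron", m.transcript_id))
        if m.cds is not None:
            s, e = m.cds
            if e <= s:
                raise InputError(f"{m.transcript_id}: malformed CDS interval [{s},{e})")
            trees[(m.chrom, m.strand)].addi(s, e, ("cds", m.transcript_id))
    for site in sites:
        hits = trees.get((site.chrom, site.strand), IntervalTree())[site.position]
        if not hits:
            site.region, site.transcript_id = "intergenic", None
            continue
        best = min(
            (iv.data for iv in hits),
            key=lambda d: (_REGION_PRIORITY[d[0]], d[1]),
        )
        site.region, site.transcript_id = best
    return list(sites)


# ---------------------------------------------------------------------------
# Comparison against known poly(A) sites

def compare_site_strength(
    sites: Sequence[CleavageSite],
    known: Sequence[tuple],
    window: int = 50,
):
    """Split sites by overlap (+- ``window``) with known poly(A) records and
    compare the two support distributions by rank-sum test.

    ``known`` holds BED6-like tuples; strand is honoured when present.
    Returns ``(overlapping_supports, novel_supports, p_value)`` with
    ``p_value`` None when either class is empty.
    """
    from .apa_stats import rank_sum_test

    if window < 0:
        raise InputError("window must be >= 0")
    by_key: dict[tuple, list[int]] = defaultdict(list)
    for chrom, start, end, _name, _score, strand in known:
        for st in ("+", "-") if strand not in "+-" else (strand,):
            by_key[(chrom, st)].append((start + end - 1) // 2)
    for v in by_key.values():
        v.sort()
    overlapping, novel = [], []
    for s in sites:
        positions = by_key.get((s.chrom, s.strand), [])
        i = bisect.bisect_left(positions, s.position - window)
        hit = i < len(positions) and positions[i] <= s.position + window
        (overlapping if hit else novel).append(s.total_support)
    p = rank_sum_test(overlapping, novel) if overlapping and novel else None
    return overlapping, novel, p


# ---------------------------------------------------------------------------
# WIG export

def export_wig(
    reads: Iterable[AlignedRead],
    total_mapped: int,
    sample: str = "sample",
) -> str:
    """Per-base read coverage as variableStep WIG text (1-based), scaled to
    10 million mapped reads (factor 1e7 / ``total_mapped``)."""
    if total_mapped <= 0:
        raise InputError("total_mapped must be > 0")
    scale = 1e7 / total_mapped
    cover: dict[str, Counter] = defaultdict(Counter)
    for r in reads:
        c = cover[r.chrom]
        for pos in range(r.start, r.end):
            c[pos] += 1
    lines = [f'track type=wiggle_0 name="{sample}"']
    for chrom in sorted(cover):
        lines.append(f"variableStep chrom={chrom}")
        for pos in sorted(cover[chrom]):
            lines.append(f"{pos + 1}\t{cover[chrom][pos] * scale:g}")
    return "\n".join(lines) + "\n"
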