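"""Tail detection, profile building, site calling, annotation, WIG export."""

import numpy as np
import pytest

from apa3seq import cs_discovery
from apa3seq.cs_discovery import (
    annotate_sites,
    build_profiles,
    call_sites,
    compare_site_strength,
    detect_tail,
    export_wig,
)
from apa3seq.errors import BoundsError, InputError
from apa3seq.io_utils import GenomeAccessor
from apa3seq.types import AlignedRead, CleavageSite, TailEvidence, TranscriptModel, revcomp


def _read(seq, start, end, strand="+", chrom="c", sample="s1", rid="r1"):
    return AlignedRead(rid, sample, chrom, strand, start, end, seq)


def _ev(pos, n=1, sample="s1", chrom="c", strand="+"):
    return [
        TailEvidence(f"e{pos}_{i}_{sample}", sample, chrom, strand, pos, 10, 8)
        for i in range(n)
    ]


class TestDetectTail:
    def test_fully_untemplated_tail_detected(self):
        genome = GenomeAccessor({"c": "GGATCCGTAC" + "GCGTCGGTCC"})
        read = _read("GGATCCGTAC" + "A" * 10, 0, 10)
        ev = detect_tail(read, genome)
        assert ev is not None
        assert ev.mismatches_in_first8 == 8
        assert ev.stretch_len == 10
        assert ev.cleavage_pos == 10

    def test_templated_a_tract_is_internal_priming(self):
        genome = GenomeAccessor({"c": "GGATCCGTAC" + "A" * 10})
        read = _read("GGATCCGTAC" + "A" * 10, 0, 20)
        assert detect_tail(read, genome) is None

    def test_seven_a_run_below_floor(self):
        genome = GenomeAccessor({"c": "GGATCCGTAC" + "GCGTCGG"})
        read = _read("GGATCCGTAC" + "A" * 7, 0, 10)
        assert detect_tail(read, genome) is None

    def test_four_of_eight_mismatches_rejected(self):
        # reference under the first 8 run bases is AAAACGTC: 4 matches only
        genome = GenomeAccessor({"c": "CCGTCCGTTG" + "AAAACGTCGG"})
        read = _read("CCGTCCGTTG" + "A" * 8, 0, 10)
        assert detect_tail(read, genome) is None

    def test_five_of_eight_mismatches_accepted(self):
        genome = GenomeAccessor({"c": "CCGTCCGTTG" + "AAACCGTCGG"})
        read = _read("CCGTCCGTTG" + "A" * 8, 0, 10)
        ev = detect_tail(read, genome)
        assert ev is not None and ev.mismatches_in_first8 == 5

    def test_minus_strand_cleavage_position(self):
        # transcript-sense templated part GGATCCGTAC lies at genomic [10,20)
        # reverse-complemented; the tail continues genomically leftward.
        templated = "GGATCCGTAC"
        genome = GenomeAccessor({"c": "GCGTCGGTCC"[::-1] + revcomp(templated)})
        read = _read(templated + "A" * 10, 10, 20, strand="-")
        ev = detect_tail(read, genome)
        assert ev is not None
        assert ev.cleavage_pos == 9  # first untemplated base, transcript-sense

    def test_reference_too_short_raises(self):
        genome = GenomeAccessor({"c": "GGATCCGTAC" + "GC"})
        read = _read("GGATCCGTAC" + "A" * 10, 0, 10)
        with pytest.raises(BoundsError):
            detect_tail(read, genome)


class TestProfilesAndSites:
    def test_profile_counts_multiplicity(self):
        profiles = build_profiles(_ev(100, 3))
        assert profiles[("c", "+", "s1")][100] == 3
        assert build_profiles([]) == {}
        profiles = build_profiles(_ev(100, 2) + _ev(130, 5))
        counts = profiles[("c", "+", "s1")]
        assert counts[100] == 2 and counts[130] == 5 and sum(counts.values()) == 7

    def test_close_candidates_keep_the_stronger(self):
        sites = call_sites(build_profiles(_ev(100, 50) + _ev(130, 20)))
        assert [s.position for s in sites] == [100]
        assert sites[0].total_support == 50

    def test_nine_reads_below_support_floor(self):
        assert call_sites(build_profiles(_ev(100, 9))) == []

    def test_spacing_sixty_keeps_both(self):
        sites = call_sites(build_profiles(_ev(100, 15) + _ev(160, 12)))
        assert [s.position for s in sites] == [100, 160]

    def test_nearby_evidence_pools_into_site_support(self):
        # scattered evidence within the assignment window counts as support
        evidence = _ev(100, 6) + _ev(98, 3) + _ev(103, 2)
        sites = call_sites(build_profiles(evidence))
        assert len(sites) == 1
        assert sites[0].position == 100
        assert sites[0].total_support == 11

    def test_per_sample_support_recorded(self):
        evidence = _ev(100, 8, sample="a") + _ev(100, 5, sample="b")
        sites = call_sites(build_profiles(evidence))
        assert sites[0].support == {"a": 8, "b": 5}

    def test_spacing_and_support_invariants_random(self):
        rng = np.random.default_rng(0)
        evidence = []
        for i, pos in enumerate(rng.integers(0, 2000, size=800)):
            evidence.extend(_ev(int(pos), 1))
        sites = call_sites(build_profiles(evidence), min_support=2)
        positions = sorted(s.position for s in sites)
        assert all(b - a >= 50 for a, b in zip(positions, positions[1:]))
        assert sum(s.total_support for s in sites) <= len(evidence)


def _toy_model(strand="+", chrom="c"):
    if strand == "+":
        return TranscriptModel(
            "t1", "g1", chrom, "+",
            exons=((0, 600), (1400, 3000)),
            utr3=(1900, 3000), cds=(100, 1900),
        )
    return TranscriptModel(
        "t1", "g1", chrom, "-",
        exons=((7000, 8600), (9400, 10000)),
        utr3=(7000, 8100), cds=(8100, 9900),
    )


class TestAnnotation:
    def test_downstream_extension_is_utr3(self):
        sites = [CleavageSite("c", "+", 3400, {"s": 20})]
        annotate_sites(sites, [_toy_model()])
        assert sites[0].region == "utr3" and sites[0].transcript_id == "t1"

    def test_intron_and_cds_and_intergenic(self):
        sites = [
            CleavageSite("c", "+", 1000, {"s": 20}),
            CleavageSite("c", "+", 500, {"s": 20}),
            CleavageSite("c", "+", 9000, {"s": 20}),
        ]
        annotate_sites(sites, [_toy_model()])
        assert [s.region for s in sites] == ["intron", "cds", "intergenic"]

    def test_minus_strand_extension_extends_leftward(self):
        sites = [
            CleavageSite("c", "-", 6500, {"s": 20}),  # 500 nt past the 3' end
            CleavageSite("c", "+", 6500, {"s": 20}),  # wrong strand
        ]
        annotate_sites(sites, [_toy_model("-")])
        assert sites[0].region == "utr3"
        assert sites[1].region == "intergenic"


class TestKnownSiteComparison:
    def _sites(self, supports, start=0, spacing=100):
        return [
            CleavageSite("c", "+", start + i * spacing, {"s": int(v)})
            for i, v in enumerate(supports)
        ]

    def test_empty_known_bed_all_novel(self):
        over, novel, p = compare_site_strength(self._sites([10, 20, 30]), [])
        assert over == [] and len(novel) == 3 and p is None

    def test_identical_distributions_p_one(self):
        sites = self._sites([10, 10, 10, 10, 10, 10])
        known = [("c", s.position, s.position + 1, ".", 0, "+") for s in sites[:3]]
        over, novel, p = compare_site_strength(sites, known, window=10)
        assert len(over) == 3 and len(novel) == 3
        assert p == 1.0

    def test_exact_rank_sum_enumeration(self):
        sites = self._sites([100, 90, 80, 10, 12, 11])
        known = [("c", s.position, s.position + 1, ".", 0, "+") for s in sites[:3]]
        _, _, p = compare_site_strength(sites, known, window=10)
        assert p == pytest.approx(2 / 20)  # complete separation, C(6,3)=20


class TestWig:
    def test_unit_scale(self):
        reads = [_read("A" * 30, 100, 130)]
        wig = export_wig(reads, int(1e7))
        values = [float(l.split("\t")[1]) for l in wig.splitlines() if "\t" in l]
        assert len(values) == 30 and all(v == 1.0 for v in values)
        assert "variableStep chrom=c" in wig

    def test_linear_scaling(self):
        reads = [_read("A" * 30, 100, 130)]
        wig = export_wig(reads, int(5e6))
        values = [float(l.split("\t")[1]) for l in wig.splitlines() if "\t" in l]
        assert all(v == 2.0 for v in values)

    def test_empty_sample_header_only(self):
        wig = export_wig([], int(1e7), sample="empty")
        assert wig.startswith("track")
        assert "variableStep" not in wig

    def test_zero_total_rejected(self):
        with pytest.raises(InputError):
            export_wig([], 0)


class TestOnSimulatedData:
    def test_all_internal_priming_reads_rejected(self, small_dataset, small_evidence):
        ip_ids = set(small_dataset.meta[small_dataset.meta.category == "ip"].read_id)
        assert len(ip_ids) > 0
        assert not ip_ids & {e.read_id for e in small_evidence}

    def test_no_evidence_from_body_reads(self, small_dataset, small_evidence):
        body = set(small_dataset.meta[small_dataset.meta.category == "body"].read_id)
        assert not body & {e.read_id for e in small_evidence}

    def test_jitter_free_sites_equal_truth_exactly(self):
        from apa3seq import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_transcripts=10, depth_per_transcript=80, seed=4,
            jitter_sd=0.0, error_rate=0.0, internal_priming_rate=0.0,
            body_read_fraction=0.0, extension_fraction=0.0,
        )
        ds = simulate_dataset(cfg)
        evidence = cs_discovery.detect_tails(ds.all_reads(), ds.accessor)
        sites = call_sites(build_profiles(evidence))
        called = {(s.chrom, s.strand, s.position) for s in sites}
        model_by = {m.transcript_id: m for m in ds.models}
        truth = {
            (model_by[t.transcript_id].chrom, model_by[t.transcript_id].strand, p)
            for t in ds.truth
            for p in t.cs_positions
        }
        assert called <= truth
        # every decently-used truth site is recovered exactly
        assert len(called) >= 0.95 * len(truth)

    def test_called_sites_near_truth_with_jitter(self, small_dataset, small_evidence):
        sites = call_sites(build_profiles(small_evidence))
        model_by = {m.transcript_id: m for m in small_dataset.models}
        truth_pos = [
            (model_by[t.transcript_id].chrom, model_by[t.transcript_id].strand, p)
            for t in small_dataset.truth
            for p in t.cs_positions
        ]
        for s in sites:
            assert any(
                c == s.chrom and st == s.strand and abs(p - s.position) <= 5
                for c, st, p in truth_pos
            )
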