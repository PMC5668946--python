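"""Read taxonomy: junction change-point search, anchored and paired IRRs."""

import numpy as np
import pytest

from strcall.catalog import AlignedRead, ModelParams, RepeatSpec
from strcall.classify import (
    EvidenceKind,
    classify_spanning_or_flanking,
    find_anchored_irrs,
    find_paired_irrs,
    pair_reads,
)
from strcall.purity import weighted_purity


@pytest.mark.parametrize(
    "build,expected_kind,expected_m",
    [
        # 20 bp left flank + 5 units + 20 bp right flank: exact spanning count
        (lambda fl: fl.left[-20:] + "GGCCCC" * 5 + fl.right[:20], EvidenceKind.SPANNING, 5),
        # repeat runs off the read end: flanking, complete units only
        (lambda fl: "GGCCCC" * 10 + fl.right[:40], EvidenceKind.FLANKING, 10),
        (lambda fl: fl.left[-40:] + "GGCCCC" * 10, EvidenceKind.FLANKING, 10),
        # no repeat at all
        (lambda fl: fl.left[-100:], None, None),
        (lambda fl: fl.right[:100], None, None),
        # read fully inside the repeat (any phase): not junction evidence
        (lambda fl: ("GGCCCC" * 30)[4:154], None, None),
    ],
)
def test_junction_taxonomy(random_flanks, ggcccc_spec, read_factory, build, expected_kind, expected_m):
    bases = build(random_flanks)
    read = read_factory("r", bases, pos=ggcccc_spec.start - 40)
    ev = classify_spanning_or_flanking(read, ggcccc_spec, random_flanks)
    if expected_kind is None:
        assert ev is None
    else:
        assert ev.kind is expected_kind
        assert ev.units_m == expected_m
        assert ev.wp_score >= 0.9


def test_zero_unit_allele_spanning(random_flanks, read_factory):
    """A deleted repeat still yields a spanning read across the bare junction."""
    start = len(random_flanks.left)
    spec = RepeatSpec("zero", "chrT", start, start + 1, "GGCCCC")
    read = read_factory("r", random_flanks.left[-70:] + random_flanks.right[:80])
    ev = classify_spanning_or_flanking(read, spec, random_flanks)
    assert ev.kind is EvidenceKind.SPANNING
    assert ev.units_m == 0


def test_tiny_repeat_tail_is_not_flanking(random_flanks, ggcccc_spec, read_factory):
    """Less than one unit beyond the junction cannot anchor a flank call."""
    read = read_factory("r", random_flanks.left[-97:] + "GGC")
    assert classify_spanning_or_flanking(read, ggcccc_spec, random_flanks) is None


def test_flank_margin_blocks_motif_like_flanks(ggcccc_spec, read_factory):
    """If the 'flank' is itself repeat sequence, the junction is unresolvable."""
    from strcall.classify import ReferenceFlanks

    repeat_flanks = ReferenceFlanks(left="GGCCCC" * 300, right="GGCCCC" * 300)
    read = read_factory("r", "GGCCCC" * 25)
    assert classify_spanning_or_flanking(read, ggcccc_spec, repeat_flanks) is None


def _irr_read(name, read_factory, **kw):
    return read_factory(name, "GGCCCC" * 25, **kw)


def _flank_read(name, random_flanks, read_factory, **kw):
    return read_factory(name, random_flanks.left[-150:], **kw)


class TestAnchoredIrrs:
    def test_mate_anchors_within_window(self, random_flanks, ggcccc_spec, read_factory):
        pairs = [
            (
                _irr_read("p1", read_factory, mapq=0, pos=ggcccc_spec.start),
                _flank_read("p1", random_flanks, read_factory, mapq=60, pos=ggcccc_spec.start - 500),
            )
        ]
        (ev,) = find_anchored_irrs(pairs, ggcccc_spec)
        assert ev.kind is EvidenceKind.IRR_ANCHORED
        assert ev.units_m == 25  # floor(150 / 6)

    @pytest.mark.parametrize("mapq,offset", [(0, -500), (60, -5000)])
    def test_weak_or_distant_mates_do_not_anchor(
        self, random_flanks, ggcccc_spec, read_factory, mapq, offset
    ):
        pairs = [
            (
                _irr_read("p1", read_factory, mapq=0, pos=ggcccc_spec.start),
                _flank_read("p1", random_flanks, read_factory, mapq=mapq, pos=ggcccc_spec.start + offset),
            )
        ]
        assert find_anchored_irrs(pairs, ggcccc_spec) == []

    def test_irr_mate_cannot_anchor(self, ggcccc_spec, read_factory):
        """A pure-repeat mate is never a unique anchor, whatever its MAPQ."""
        pairs = [
            (
                _irr_read("p1", read_factory, mapq=0, pos=ggcccc_spec.start),
                _irr_read("p1", read_factory, mapq=60, pos=ggcccc_spec.start),
            )
        ]
        assert find_anchored_irrs(pairs, ggcccc_spec) == []


class TestPairedIrrs:
    def test_both_unaligned(self, ggcccc_spec, read_factory):
        pairs = [
            (
                _irr_read("p1", read_factory, chrom=None, pos=None, mapq=0),
                _irr_read("p1", read_factory, chrom=None, pos=None, mapq=0),
            )
        ]
        evs = find_paired_irrs(pairs, ggcccc_spec)
        assert len(evs) == 2
        assert all(e.kind is EvidenceKind.IRR_PAIRED for e in evs)

    def test_mapq0_in_offtarget_region(self, read_factory):
        spec = RepeatSpec(
            "x", "chrT", 1500, 1518, "GGCCCC", offtarget_regions=(("chr2", 1000, 2000),)
        )
        pairs = [
            (
                _irr_read("p1", read_factory, chrom="chr2", pos=1200, mapq=0),
                _irr_read("p1", read_factory, chrom="chr2", pos=1400, mapq=0),
            )
        ]
        assert len(find_paired_irrs(pairs, spec)) == 2

    def test_aligned_elsewhere_ignored_without_offtargets(self, ggcccc_spec, read_factory):
        pairs = [
            (
                _irr_read("p1", read_factory, chrom="chr5", pos=999_000, mapq=0),
                _irr_read("p1", read_factory, chrom="chr5", pos=999_200, mapq=0),
            )
        ]
        assert find_paired_irrs(pairs, ggcccc_spec) == []

    def test_non_irr_pairs_excluded(self, random_flanks, ggcccc_spec, read_factory):
        pairs = [
            (
                _flank_read("p1", random_flanks, read_factory, chrom=None, pos=None),
                _irr_read("p1", read_factory, chrom=None, pos=None),
            )
        ]
        assert find_paired_irrs(pairs, ggcccc_spec) == []


def test_pair_reads_groups_by_name(read_factory):
    reads = [
        read_factory("a", "ACGT"),
        read_factory("a", "TTTT"),
        read_factory("orphan", "GGGG"),
        read_factory("dup", "CCCC", is_duplicate=True),
    ]
    pairs = pair_reads(reads)
    names = sorted(p[0].name for p in pairs)
    assert names == ["a", "orphan"]
    complete = [p for p in pairs if p[1] is not None]
    assert len(complete) == 1 and complete[0][0].name == "a"


def test_simulated_reads_classify_to_their_true_category(random_flanks):
    """Zero-error simulation: every unambiguous read lands in its true class.

    Reads whose junction leaves fewer than 10 flank bases or less than one
    motif unit in the read are geometrically ambiguous and not asserted.
    """
    from strcall.classify import ReferenceFlanks
    from strcall.purity import weighted_purity_bulk
    from strcall.simulate import SimConfig, simulate_sample

    for alleles in [(4, 4), (120, 120)]:  # far below / far above read length
        cfg = SimConfig(
            alleles=alleles,
            mean_depth=30,
            base_error_rate=0.0,
            flank_length=1200,
            seed=3,
        )
        sample = simulate_sample(cfg, mode="oracle")
        aligned = {(r.name, r.is_read1): r for r in sample.reads}
        model = ModelParams()
        n_checked = 0
        for sr in sample.sim_reads:
            read = aligned[(sr.name, sr.is_read1)]
            ev = classify_spanning_or_flanking(read, sample.spec, sample.flanks, model)
            if sr.category == "in_repeat":
                assert ev is None
                assert weighted_purity(read.bases, read.quals, "GGCCCC") == 1.0
                n_checked += 1
            elif sr.category == "flank_only":
                assert ev is None
                n_checked += 1
            elif sr.category == "spanning":
                if min(sr.left_flank_bp, sr.right_flank_bp) < 10:
                    continue
                assert ev is not None and ev.kind is EvidenceKind.SPANNING
                assert ev.units_m == alleles[sr.hap]
                n_checked += 1
            elif sr.category == "flanking":
                if sr.repeat_bp < 6 or max(sr.left_flank_bp, sr.right_flank_bp) < 10:
                    continue
                assert ev is not None and ev.kind is EvidenceKind.FLANKING
                assert ev.units_m == sr.repeat_bp // 6
                n_checked += 1
        assert n_checked > 100
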