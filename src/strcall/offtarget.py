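"""Cohort-level discovery of off-target regions for a repeat motif.

Read pairs from a long expansion in which both mates are in-repeat carry no
reliable mapping information: aligners either leave them unaligned or drop
them, with MAPQ 0, at a handful of reproducible decoy loci elsewhere in the
genome.  Scanning a cohort for such pairs, merging nearby mapping positions,
and keeping clusters seen in enough samples yields the off-target region
list that a repeat catalog entry can then use to reclaim those reads.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .catalog import AlignedRead, ModelParams, RepeatSpec
from .classify import pair_reads
from .purity import weighted_purity_bulk

#: Reserved key for read pairs in which both mates are unaligned.
UNALIGNED = "unaligned"


@dataclass(frozen=True)
class OfftargetRegion:
    chrom: str
    start: int
    end: int
    n_samples: int
    max_irr_pairs: int


@dataclass
class OfftargetReport:
    """Merged off-target regions supported by at least ``min_samples`` samples."""

    regions: list[OfftargetRegion]
    merge_distance: int
    min_samples: int
    n_samples_scanned: int = 0
    unaligned_pair_counts: dict[int, int] = field(default_factory=dict)

    def to_bed(self) -> str:
        lines = [
            f"{r.chrom}\t{r.start}\t{r.end}\toff_target_{i + 1}\t{r.max_irr_pairs}"
            for i, r in enumerate(self.regions)
        ]
        return "\n".join(lines) + ("\n" if lines else "")

    def to_tsv(self) -> str:
        header = "chrom\tstart\tend\tn_samples\tmax_irr_pairs"
        lines = [
            f"{r.chrom}\t{r.start}\t{r.end}\t{r.n_samples}\t{r.max_irr_pairs}"
            for r in self.regions
        ]
        footer = (
            f"# samples_scanned={self.n_samples_scanned} "
            f"merge_distance={self.merge_distance} min_samples={self.min_samples}"
        )
        return "\n".join([header, *lines, footer]) + "\n"

    def as_offtarget_regions(self) -> tuple[tuple[str, int, int], ...]:
        """The regions in the shape RepeatSpec.offtarget_regions expects."""
        return tuple((r.chrom, r.start, r.end) for r in self.regions)


def scan_sample_for_misaligned_irr_pairs(
    reads: Iterable[AlignedRead],
    motif: str,
    model: ModelParams = ModelParams(),
) -> list[tuple[str, int]]:
    """Positions of read pairs where both mates are IRRs and poorly mapped.

    A mate qualifies if it is unaligned or mapped with MAPQ 0 (anywhere in
    the genome — this is the discovery scan, before any off-target list
    exists).  Each qualifying pair contributes its leftmost mapping
    coordinate, or the reserved ``"unaligned"`` key if neither mate maps.
    """
    pairs = [p for p in pair_reads(reads) if p[1] is not None]
    if not pairs:
        return []
    flat = [r for p in pairs for r in p]
    wp = weighted_purity_bulk(flat, motif, model)
    wp_of = {id(r): w for r, w in zip(flat, wp)}
    positions: list[tuple[str, int]] = []
    for first, second in pairs:
        if any(r.is_aligned and r.mapq != 0 for r in (first, second)):
            continue
        if min(wp_of[id(first)], wp_of[id(second)]) < model.wp_threshold:
            continue
        aligned = [r for r in (first, second) if r.is_aligned]
        if not aligned:
            positions.append((UNALIGNED, 0))
        else:
            best = min(aligned, key=lambda r: (r.chrom, r.pos))
            positions.append((best.chrom, best.pos))
    return positions


def _merge_positions(
    positions: Sequence[tuple[str, int]], merge_distance: int
) -> dict[str, list[tuple[int, int, int]]]:
    """Per-chromosome intervals (start, end, n_pairs) from nearby positions."""
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for chrom, pos in positions:
        by_chrom[chrom].append(pos)
    merged: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, pos_list in by_chrom.items():
        pos_list.sort()
        intervals = []
        start = prev = pos_list[0]
        count = 1
        for pos in pos_list[1:]:
            if pos - prev <= merge_distance:
                prev = pos
                count += 1
            else:
                intervals.append((start, prev + 1, count))
                start = prev = pos
                count = 1
        intervals.append((start, prev + 1, count))
        merged[chrom] = intervals
    return merged


def merge_and_filter(
    per_sample_positions: Sequence[Sequence[tuple[str, int]]],
    merge_distance: int = 500,
    min_samples: int = 5,
) -> OfftargetReport:
    """Cluster per-sample pair positions and keep recurrent regions.

    Positions are first merged within each sample, the per-sample intervals
    are then clustered across the cohort (again within ``merge_distance``),
    and clusters supported by at least ``min_samples`` distinct samples are
    reported.  With ``min_samples=1`` this is the plain union.
    """
    if not per_sample_positions:
        raise ValueError("at least one scanned sample is required")
    unaligned_counts: dict[int, int] = {}
    all_intervals: list[tuple[str, int, int, int, int]] = []  # chrom,start,end,sample,n
    for sample_idx, positions in enumerate(per_sample_positions):
        genomic = [(c, p) for c, p in positions if c != UNALIGNED]
        n_unaligned = len(positions) - len(genomic)
        if n_unaligned:
            unaligned_counts[sample_idx] = n_unaligned
        if not genomic:
            continue
        for chrom, intervals in _merge_positions(genomic, merge_distance).items():
            for start, end, count in intervals:
                all_intervals.append((chrom, start, end, sample_idx, count))

    all_intervals.sort(key=lambda t: (t[0], t[1], t[2]))
    regions: list[OfftargetRegion] = []
    cluster: list[tuple[str, int, int, int, int]] = []

    def flush() -> None:
        if not cluster:
            return
        samples = {t[3] for t in cluster}
        if len(samples) >= min_samples:
            per_sample_total: dict[int, int] = defaultdict(int)
            for t in cluster:
                per_sample_total[t[3]] += t[4]
            regions.append(
                OfftargetRegion(
                    chrom=cluster[0][0],
                    start=min(t[1] for t in cluster),
                    end=max(t[2] for t in cluster),
                    n_samples=len(samples),
                    max_irr_pairs=max(per_sample_total.values()),
                )
            )

    for interval in all_intervals:
        if cluster and (
            interval[0] != cluster[-1][0]
            or interval[1] > max(t[2] for t in cluster) + merge_distance
        ):
            flush()
            cluster = []
        cluster.append(interval)
    flush()
    regions.sort(key=lambda r: (r.chrom, r.start))
    return OfftargetReport(
        regions=regions,
        merge_distance=merge_distance,
        min_samples=min_samples,
        n_samples_scanned=len(per_sample_positions),
        unaligned_pair_counts=unaligned_counts,
    )


def anchored_irr_hotspots(
    per_sample_anchored_positions: Sequence[Sequence[tuple[str, int]]],
    merge_distance: int = 500,
) -> list[tuple[str, int, int, int]]:
    """Per merged locus, the maximum anchored-IRR count over samples.

    This is the cohort summary that separates the true target locus (tens of
    anchored IRRs in expanded samples) from sporadic anchoring noise
    (single-read loci).
    """
    pooled = [
        (chrom, pos, sample_idx)
        for sample_idx, positions in enumerate(per_sample_anchored_positions)
        for chrom, pos in positions
    ]
    if not pooled:
        return []
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, pos, sample_idx in pooled:
        by_chrom[chrom].append((pos, sample_idx))
    out = []
    for chrom, items in sorted(by_chrom.items()):
        items.sort()
        cluster: list[tuple[int, int]] = []

        def flush_cluster() -> None:
            if not cluster:
                return
            per_sample: dict[int, int] = defaultdict(int)
            for pos, sample_idx in cluster:
                per_sample[sample_idx] += 1
            out.append(
                (chrom, cluster[0][0], cluster[-1][0] + 1, max(per_sample.values()))
            )

        for pos, sample_idx in items:
            if cluster and pos - cluster[-1][0] > merge_distance:
                flush_cluster()
                cluster = []
            cluster.append((pos, sample_idx))
        flush_cluster()
    return out
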