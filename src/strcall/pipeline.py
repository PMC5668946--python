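"""End-to-end locus genotyping: reads in, RepeatCall out.

Evidence collection order matters: reads overlapping the repeat interval are
first tested for a spanning/flanking junction decomposition; only reads that
yield no junction evidence remain eligible as in-repeat reads (a read with a
handful of flank bases can clear the WP gate, and its junction is the more
informative signal).  Paired IRRs are included in the size estimate only
when the catalog lists off-target regions for the locus — with a common
motif the origin of a poorly-mapped pair cannot be resolved, and the size is
then bounded by anchored IRRs alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .catalog import (
    AlignedRead,
    ModelParams,
    RepeatSpec,
    SampleParams,
    UnusableSampleError,
    derive_sample_params,
)
from .classify import (
    ReadEvidence,
    ReferenceFlanks,
    classify_spanning_or_flanking,
    find_anchored_irrs,
    find_paired_irrs,
    pair_reads,
)
from .genotyper import RepeatCall, call_genotype
from .purity import weighted_purity_bulk

#: Slack (bp) around the repeat interval when gating junction candidates.
_JUNCTION_GATE_SLOP = 10


@dataclass
class LocusResult:
    spec: RepeatSpec
    call: RepeatCall
    sample_params: SampleParams | None
    evidence: list[ReadEvidence]

    def to_dict(self) -> dict:
        d = {
            "locus_id": self.spec.locus_id,
            "region": self.spec.region_1based,
            "motif": self.spec.motif,
            "pathogenic_cutoff_units": self.spec.pathogenic_cutoff_units,
            **self.call.to_dict(),
        }
        if self.sample_params is not None:
            d["sample_params"] = {
                "read_length": self.sample_params.read_length,
                "mean_depth": round(self.sample_params.mean_depth, 2),
                "pi": round(self.sample_params.pi, 4),
            }
        return d


def collect_evidence(
    reads: Sequence[AlignedRead],
    spec: RepeatSpec,
    flanks: ReferenceFlanks,
    model: ModelParams = ModelParams(),
    use_paired: bool | None = None,
) -> list[ReadEvidence]:
    """Classify every usable read pair into locus evidence.

    ``use_paired=None`` (auto) includes paired IRRs exactly when the catalog
    lists off-target regions for the locus.
    """
    usable = [r for r in reads if r.usable]
    wp = weighted_purity_bulk(usable, spec.motif, model) if usable else np.empty(0)
    wp_cache = {id(r): w for r, w in zip(usable, wp)}

    junction_evidence: list[ReadEvidence] = []
    junction_ids: set[int] = set()
    lo = spec.start - _JUNCTION_GATE_SLOP
    hi = spec.end + _JUNCTION_GATE_SLOP
    for read in usable:
        if not read.is_aligned or read.chrom != spec.chrom:
            continue
        if read.pos + len(read) <= lo or read.pos >= hi:
            continue
        ev = classify_spanning_or_flanking(read, spec, flanks, model)
        if ev is not None:
            junction_evidence.append(ev)
            junction_ids.add(id(read))

    pairs = pair_reads(usable)
    anchored = find_anchored_irrs(pairs, spec, model, wp_cache, exclude_ids=junction_ids)
    if use_paired is None:
        use_paired = bool(spec.offtarget_regions)
    paired = (
        find_paired_irrs(pairs, spec, model, wp_cache, exclude_ids=junction_ids)
        if use_paired
        else []
    )
    return junction_evidence + anchored + paired


def genotype_locus(
    reads: Sequence[AlignedRead],
    spec: RepeatSpec,
    flanks: ReferenceFlanks,
    sample_params: SampleParams | None = None,
    model: ModelParams = ModelParams(),
    ploidy: int = 2,
    use_paired: bool | None = None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    read_length_override: int | None = None,
    depth_override: float | None = None,
) -> LocusResult:
    """Genotype one locus from a read set (the per-locus driver)."""
    if sample_params is None:
        try:
            sample_params = derive_sample_params(
                reads, spec, read_length_override, depth_override
            )
        except UnusableSampleError as exc:
            return LocusResult(
                spec=spec,
                call=RepeatCall(
                    genotype=None,
                    allele_estimates=(),
                    supporting_counts={},
                    label=None,
                    log_likelihood=None,
                    no_call_reason=str(exc),
                ),
                sample_params=None,
                evidence=[],
            )
    evidence = collect_evidence(reads, spec, flanks, model, use_paired)
    call = call_genotype(
        evidence,
        spec,
        sample_params,
        model,
        ploidy=ploidy,
        n_boot=n_boot,
        level=level,
        seed=seed,
    )
    return LocusResult(spec=spec, call=call, sample_params=sample_params, evidence=evidence)
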