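"""Maximum-likelihood repeat genotyping and normal/gray/expanded calling.

The genotype ``G`` is a tuple of allele sizes in repeat units (one entry per
ploidy).  The posterior is ``P(G|R) = P(R|G) P(G) / P(R)`` with a uniform
prior over candidate genotypes, so calling reduces to maximizing ``P(R|G)``.
Each read is drawn with equal probability from either haplotype::

    P(r_i | G) = 1/2 P(r_i | H_1) + 1/2 P(r_i | H_2)

and per-read likelihoods use the capped-geometric frequency function

    f(m | p, n, s) ~ p (1 - p)**d,   d = min(|n - m|, s)

normalized over m in [0, u], where u = floor(read_length / motif_length) is
the largest unit count one read can show.  Spanning reads observe their unit
count m exactly: P(r|H=n) = pi * f(m|n).  Flanking and in-repeat reads only
bound it from below: P(r|H=n) = pi * sum_{k=m}^{u} f(k|n).

Repeats longer than the read length appear as reads with m = u, so u serves
as a stand-in allele; when the winning genotype contains it and IRRs are
present, the stand-in is replaced by the binomial IRR size estimate (the
full expansion length).  When both alleles are expanded, size intervals are
derived from the extremes of how the IRRs could split between haplotypes
(0-50% from the short allele, 50-100% from the long one).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Sequence

import numpy as np

from .catalog import ModelParams, RepeatSpec, SampleParams
from .classify import EvidenceKind, ReadEvidence
from .sizing import (
    EvidenceClass,
    SizeEstimate,
    estimate_size_from_flanking,
    estimate_size_from_irrs,
)


class CallLabel(Enum):
    NORMAL = "normal"
    GRAY = "gray"
    EXPANDED = "expanded"


@dataclass
class RepeatCall:
    """A diploid (or haploid) repeat genotype with per-allele size estimates."""

    genotype: tuple[int, ...] | None
    allele_estimates: tuple[SizeEstimate, ...]
    supporting_counts: dict[str, int]
    label: CallLabel | None
    log_likelihood: float | None
    no_call_reason: str | None = None
    #: ML genotype over candidate alleles, before the read-length stand-in
    #: is replaced by the expansion size estimate.
    ml_genotype: tuple[int, ...] | None = None

    @property
    def is_no_call(self) -> bool:
        return self.genotype is None

    @property
    def long_allele(self) -> SizeEstimate | None:
        if not self.allele_estimates:
            return None
        return self.allele_estimates[-1]

    def to_dict(self) -> dict:
        return {
            "genotype_units": list(self.genotype) if self.genotype else None,
            "alleles": [est.to_dict() for est in self.allele_estimates],
            "supporting_counts": dict(self.supporting_counts),
            "label": self.label.value if self.label else None,
            "log_likelihood": None
            if self.log_likelihood is None
            else round(self.log_likelihood, 4),
            "no_call_reason": self.no_call_reason,
        }


@lru_cache(maxsize=4096)
def _freq_table(n: int, p: float, s: int, u: int) -> tuple[float, ...]:
    m = np.arange(u + 1)
    d = np.minimum(np.abs(n - m), s)
    w = p * (1.0 - p) ** d
    return tuple(w / w.sum())


def repeat_freq(m: int, n: int, p: float = 0.97, s: int = 5, u: int = 25) -> float:
    """f(m | p, n, s), normalized so it sums to 1 over m in [0, u]."""
    if not (0 < p < 1):
        raise ValueError("p must lie in (0, 1)")
    if s < 0:
        raise ValueError("s must be non-negative")
    if not (0 <= m <= u) or not (0 <= n <= u):
        raise ValueError(f"m={m}, n={n} must lie in [0, u={u}]")
    return _freq_table(n, p, s, u)[m]


def read_likelihood(
    evidence: ReadEvidence,
    n: int,
    params: SampleParams,
    model: ModelParams,
    u: int,
) -> float:
    """P(read | allele of n units)."""
    m = evidence.units_m
    if m > u:
        raise ValueError(f"observed unit count {m} exceeds u = {u}")
    table = _freq_table(n, model.p, model.s, u)
    if evidence.kind is EvidenceKind.SPANNING:
        return params.pi * table[m]
    return params.pi * math.fsum(table[m:])


def genotype_likelihood(
    genotype: tuple[int, ...],
    evidence_set: Sequence[ReadEvidence],
    params: SampleParams,
    model: ModelParams,
    u: int,
) -> float | None:
    """Log-likelihood of a genotype; ``None`` for an empty evidence set.

    Diploid reads are an equal mixture over the two haplotypes; a haploid
    genotype degenerates to the single-allele term.
    """
    if len(genotype) not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    if not evidence_set:
        return None
    total = 0.0
    for ev in evidence_set:
        mix = sum(read_likelihood(ev, n, params, model, u) for n in genotype) / len(genotype)
        total += math.log(mix)
    return total


def split_both_expanded(
    total_irr_count: int,
    params: SampleParams,
    motif_len: int,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Size intervals (bp) when both alleles exceed the read length.

    Between 0 and 50% of the IRRs may come from the short allele and between
    50% and 100% from the long one; each bound maps through N = r + i / pi.
    """
    if total_irr_count < 0:
        raise ValueError("IRR count must be non-negative")

    def size(i: float) -> float:
        return params.read_length + i / params.pi

    half = total_irr_count / 2.0
    return (
        (size(0), size(half)),
        (size(half), size(float(total_irr_count))),
    )


def _label_from_ci(lo: int, hi: int, cutoff: int) -> CallLabel:
    if lo > cutoff:
        return CallLabel.EXPANDED
    if lo < cutoff < hi:
        return CallLabel.GRAY
    return CallLabel.NORMAL


def classify_call(call: RepeatCall, cutoff_units: int) -> CallLabel:
    """Normal / gray / expanded from the long allele's CI vs the cutoff.

    Expanded: the whole CI exceeds the cutoff.  Gray: the CI straddles it —
    treated as a potential expansion (and counted positive in any
    sensitivity arithmetic downstream).  Normal otherwise.
    """
    long_allele = call.long_allele
    if long_allele is None:
        raise ValueError("cannot classify a no-call")
    return _label_from_ci(long_allele.ci_lo_units, long_allele.ci_hi_units, cutoff_units)


def _tally(evidence_set: Sequence[ReadEvidence]) -> dict[str, int]:
    counts = {"spanning": 0, "flanking": 0, "anchored_irr": 0, "paired_irr": 0}
    keys = {
        EvidenceKind.SPANNING: "spanning",
        EvidenceKind.FLANKING: "flanking",
        EvidenceKind.IRR_ANCHORED: "anchored_irr",
        EvidenceKind.IRR_PAIRED: "paired_irr",
    }
    for ev in evidence_set:
        counts[keys[ev.kind]] += 1
    return counts


def call_genotype(
    evidence_set: Sequence[ReadEvidence],
    spec: RepeatSpec,
    params: SampleParams,
    model: ModelParams = ModelParams(),
    ploidy: int = 2,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> RepeatCall:
    """Exhaustive ML genotype over candidate alleles, with size estimates.

    Candidate alleles are the distinct spanning/flanking unit counts plus the
    read-length stand-in u whenever IRRs are present.  Ties are broken toward
    the smaller allele sum, then lexicographically, so output is
    deterministic.
    """
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    counts = _tally(evidence_set)
    motif_len = len(spec.motif)
    u = model.max_units(params.read_length, motif_len)
    rng = np.random.default_rng(seed)

    spanning_ms = {ev.units_m for ev in evidence_set if ev.kind is EvidenceKind.SPANNING}
    flanking_ms = {ev.units_m for ev in evidence_set if ev.kind is EvidenceKind.FLANKING}
    irr_evidence = [ev for ev in evidence_set if ev.kind.is_irr]
    candidates = sorted(spanning_ms | flanking_ms | ({u} if irr_evidence else set()))

    # IRR multiplicity is length information, not genotype information: a
    # count of i in-repeat reads is explained equally well by one expanded
    # allele of size r + 2i/pi or two expanded alleles sharing 2i/pi, since
    # the expansion sizes are free parameters fitted after the argmax.
    # Left in the per-read mixture, every IRR would add a spurious ln(2)
    # preference for calling both alleles expanded, eventually outvoting the
    # depth-bounded spanning support for a real short allele.  The argmax
    # therefore sees junction reads individually plus a single representative
    # IRR observation (which is what makes the stand-in allele u callable);
    # the full count i still drives the size estimate below.
    observations = [ev for ev in evidence_set if not ev.kind.is_irr]
    if irr_evidence:
        observations.append(irr_evidence[0])
    if not candidates:
        return RepeatCall(
            genotype=None,
            allele_estimates=(),
            supporting_counts=counts,
            label=None,
            log_likelihood=None,
            no_call_reason="no spanning, flanking, or in-repeat evidence at the locus",
        )

    best_g: tuple[int, ...] | None = None
    best_ll = -math.inf
    for genotype in itertools.combinations_with_replacement(candidates, ploidy):
        ll = genotype_likelihood(genotype, observations, params, model, u)
        better = ll > best_ll or (
            ll == best_ll
            and best_g is not None
            and (sum(genotype), genotype) < (sum(best_g), best_g)
        )
        if better:
            best_g, best_ll = genotype, ll

    i_total = len(irr_evidence)
    estimates: list[SizeEstimate] = []
    n_expanded = sum(1 for n in best_g if n == u and irr_evidence)
    if n_expanded == len(best_g) and irr_evidence and ploidy == 2:
        (s_lo, s_hi), (l_lo, l_hi) = split_both_expanded(i_total, params, motif_len)
        for lo_bp, hi_bp in ((s_lo, s_hi), (l_lo, l_hi)):
            mid = (lo_bp + hi_bp) / 2.0
            estimates.append(
                SizeEstimate(
                    irr_count=i_total,
                    point_bp=mid,
                    point_units=int(mid // motif_len),
                    ci_lo_units=int(lo_bp // motif_len),
                    ci_hi_units=int(math.ceil(hi_bp / motif_len)),
                    evidence=EvidenceClass.IRR,
                )
            )
    else:
        for n in best_g:
            if n == u and irr_evidence:
                # paired IRRs arrive two per fragment; bootstrap over fragments
                n_frag = counts["anchored_irr"] + max(1, counts["paired_irr"] // 2) \
                    if counts["paired_irr"] else counts["anchored_irr"]
                estimates.append(
                    estimate_size_from_irrs(
                        i_total,
                        params,
                        motif_len,
                        n_boot=n_boot,
                        level=level,
                        seed=rng,
                        hap_fraction=n_expanded / ploidy,
                        n_clusters=min(max(n_frag, 1), i_total) if i_total else None,
                    )
                )
            elif n in spanning_ms:
                estimates.append(SizeEstimate.exact(n, motif_len))
            else:
                flank_ev = [ev for ev in evidence_set if ev.kind is EvidenceKind.FLANKING]
                est = estimate_size_from_flanking(
                    flank_ev, params, motif_len, n_boot=n_boot, level=level, seed=rng
                )
                estimates.append(est if est is not None else SizeEstimate.exact(n, motif_len))

    estimates.sort(key=lambda e: (e.point_units, e.ci_hi_units))
    call = RepeatCall(
        # report final allele sizes: the read-length stand-in u is replaced
        # by the IRR-based expansion estimate above
        genotype=tuple(e.point_units for e in estimates),
        allele_estimates=tuple(estimates),
        supporting_counts=counts,
        label=None,
        log_likelihood=best_ll,
        ml_genotype=tuple(sorted(best_g)),
    )
    if spec.pathogenic_cutoff_units is not None:
        call.label = classify_call(call, spec.pathogenic_cutoff_units)
    return call
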