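"""Repeat-length estimation from in-repeat and flanking read counts.

Read starts are modeled as a Bernoulli process with per-base success
probability ``pi = depth / read_length``.  For a repeat of length ``N`` bp
and read length ``r``, every in-repeat read must start in a window of
``N - r`` bases, so the IRR count ``i`` is binomial::

    P(i, N - r) = C(N - r, i) * pi**i * (1 - pi)**(N - r - i)

and the method-of-moments point estimate is ``N = r + i / pi``.  Confidence
intervals come from a parametric bootstrap: resample ``i* ~ Binom(N - r,
pi)`` at the estimated size and re-estimate.

For a heterozygous expansion the IRRs originate from a single haplotype, so
the effective start rate is the rate of expansion-bearing molecules only;
``hap_fraction`` scales pi accordingly (1.0 for a homozygous or haploid
expansion, 0.5 for a diploid heterozygote).

Flanking reads bound repeats near the read length: each flanking read starts
in one of two windows of ~N bases (one per junction), so the expected
flanking count is ``2 * N * pi`` and ``N = k / (2 * pi)``.  The resulting
interval is truncated to the read-length scale from above and to the longest
repeat stretch actually observed in a flanking read from below.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .catalog import SampleParams
from .classify import EvidenceKind, ReadEvidence


class EvidenceClass(Enum):
    SPANNING = "spanning"
    FLANKING = "flanking"
    IRR = "irr"


@dataclass(frozen=True)
class SizeEstimate:
    """Point estimate and CI for one allele, in repeat units and bp."""

    irr_count: int
    point_bp: float
    point_units: int
    ci_lo_units: int
    ci_hi_units: int
    evidence: EvidenceClass

    def __post_init__(self) -> None:
        if not (self.ci_lo_units <= self.point_units <= self.ci_hi_units):
            raise ValueError(
                f"CI [{self.ci_lo_units}, {self.ci_hi_units}] does not bracket "
                f"the point estimate {self.point_units}"
            )

    @classmethod
    def exact(cls, units: int, motif_len: int) -> "SizeEstimate":
        """A spanning-read allele: the unit count is known exactly."""
        return cls(
            irr_count=0,
            point_bp=float(units * motif_len),
            point_units=units,
            ci_lo_units=units,
            ci_hi_units=units,
            evidence=EvidenceClass.SPANNING,
        )

    def to_dict(self) -> dict:
        return {
            "point_units": self.point_units,
            "point_bp": round(self.point_bp, 1),
            "ci_units": [self.ci_lo_units, self.ci_hi_units],
            "evidence": self.evidence.value,
            "irr_count": self.irr_count,
        }


def irr_count_probability(i: int, n_bp: float, params: SampleParams) -> float:
    """Binomial probability of observing ``i`` IRRs from an ``n_bp`` repeat."""
    window = n_bp - params.read_length
    if window < 0:
        raise ValueError(f"repeat size {n_bp} bp is below the read length {params.read_length}")
    if not (0 <= i <= window) and not (window == 0 and i == 0):
        raise ValueError(f"IRR count {i} outside [0, {window}]")
    return float(stats.binom.pmf(i, int(round(window)), params.pi))


def _point_bp(i: int, params: SampleParams, hap_fraction: float) -> float:
    return params.read_length + i / (params.pi * hap_fraction)


def bootstrap_ci(
    i: int,
    params: SampleParams,
    motif_len: int,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    hap_fraction: float = 1.0,
    n_clusters: int | None = None,
) -> tuple[int, int]:
    """Parametric-bootstrap percentile CI (in repeat units) for the IRR estimator.

    ``n_clusters`` is the number of independent fragments the ``i`` IRRs came
    from.  Mates of one fragment are not independent draws — a fragment fully
    inside the tract contributes two IRRs at once — so resampling happens at
    the fragment level and is scaled by the observed mean IRRs per fragment.
    The default (``None``) treats every IRR as its own fragment, which is the
    plain independent-read binomial.
    """
    if i < 0:
        raise ValueError("IRR count must be non-negative")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if n_clusters is not None and not (1 <= n_clusters <= i):
        raise ValueError("n_clusters must lie in [1, i]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi_eff = params.pi * hap_fraction
    cluster_size = 1.0 if (n_clusters is None or i == 0) else i / n_clusters
    window = int(round(i / pi_eff))
    if window > 0:
        k_star = rng.binomial(window, pi_eff / cluster_size, size=n_boot)
        i_star = k_star * cluster_size
    else:
        i_star = np.zeros(n_boot)
    n_star = params.read_length + i_star / pi_eff
    units_star = np.floor(n_star / motif_len).astype(int)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(units_star, [100 * alpha, 100 * (1 - alpha)])
    point_units = int(_point_bp(i, params, hap_fraction) // motif_len)
    return min(int(lo), point_units), max(int(hi), point_units)


def estimate_size_from_irrs(
    i: int,
    params: SampleParams,
    motif_len: int,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    hap_fraction: float = 1.0,
    n_clusters: int | None = None,
) -> SizeEstimate:
    """Point estimate N = r + i/pi with a parametric-bootstrap CI."""
    point = _point_bp(i, params, hap_fraction)
    lo, hi = bootstrap_ci(i, params, motif_len, n_boot, level, seed, hap_fraction, n_clusters)
    return SizeEstimate(
        irr_count=i,
        point_bp=point,
        point_units=int(point // motif_len),
        ci_lo_units=lo,
        ci_hi_units=hi,
        evidence=EvidenceClass.IRR,
    )


def estimate_size_from_flanking(
    flanking_evidence: Sequence[ReadEvidence],
    params: SampleParams,
    motif_len: int,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> SizeEstimate | None:
    """Size estimate from flanking reads alone; ``None`` with no evidence.

    The flanking count plays the role of the binomial event count: each
    flanking read starts in one of two ~N-base windows, so N = k / (2 pi).
    The interval is truncated to [longest observed stretch, read length].
    """
    flanking = [ev for ev in flanking_evidence if ev.kind is EvidenceKind.FLANKING]
    if not flanking:
        return None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(flanking)
    m_max = max(ev.units_m for ev in flanking)
    u = params.read_length // motif_len
    point = k / (2.0 * params.pi)
    window = int(round(2.0 * point))
    k_star = rng.binomial(window, params.pi, size=n_boot) if window > 0 else np.zeros(n_boot, int)
    units_star = np.floor(k_star / (2.0 * params.pi) / motif_len).astype(int)
    # the feasible band for flank-only evidence: at least the longest stretch
    # actually observed in a read, at most the read length
    units_star = np.clip(units_star, m_max, u)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(units_star, [100 * alpha, 100 * (1 - alpha)])
    lo, hi = int(lo), int(hi)
    point_units = min(max(int(point // motif_len), lo), hi)
    point = min(max(point, lo * motif_len), hi * motif_len)
    return SizeEstimate(
        irr_count=k,
        point_bp=point,
        point_units=point_units,
        ci_lo_units=lo,
        ci_hi_units=hi,
        evidence=EvidenceClass.FLANKING,
    )
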