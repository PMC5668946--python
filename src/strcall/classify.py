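"""Read taxonomy at a repeat locus: spanning, flanking, and in-repeat reads.

Four kinds of evidence are extracted from the alignments around a locus:

* SPANNING — the read contains the whole repeat tract plus both flank
  junctions; its unit count is exact.
* FLANKING — the read contains exactly one junction and part of the repeat;
  its unit count is a lower bound.
* IRR_ANCHORED — an in-repeat read whose mate aligns confidently (high MAPQ)
  within the anchor window of the locus, proving where the IRR came from.
* IRR_PAIRED — a read pair with both mates in-repeat; such pairs are either
  unaligned or misaligned with MAPQ 0, at the locus or at a cataloged
  off-target region, because the expansion is absent from the reference.

Spanning/flanking detection is a positional change-point search: the read is
decomposed as (left-flank suffix)(k motif units)(right-flank prefix), each
segment scored with the same +1 / +0.5 / -1 per-base weights as WP, and the
best decomposition is kept.  The composite score must reach the WP threshold,
and each flank segment must beat the alternative of simply extending the
repeat through it by a mismatch margin — otherwise the junction placement is
not trustworthy and the read yields no evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .catalog import AlignedRead, ModelParams, RepeatSpec
from .purity import _as_bytes, mismatch_penalties, weighted_purity

logger = logging.getLogger(__name__)


class EvidenceKind(Enum):
    SPANNING = "spanning"
    FLANKING = "flanking"
    IRR_ANCHORED = "irr_anchored"
    IRR_PAIRED = "irr_paired"

    @property
    def is_irr(self) -> bool:
        return self in (EvidenceKind.IRR_ANCHORED, EvidenceKind.IRR_PAIRED)


@dataclass(frozen=True)
class ReadEvidence:
    """One read's contribution to a locus genotype.

    ``units_m`` is the exact repeat-unit count for spanning reads and an
    observed lower bound for flanking and in-repeat reads (an IRR attests
    "at least u units", u = floor(read length / motif length)).
    """

    read_name: str
    kind: EvidenceKind
    units_m: int
    wp_score: float


@dataclass(frozen=True)
class ReferenceFlanks:
    """Reference sequence immediately left/right of the repeat interval.

    ``left`` ends at the repeat start; ``right`` begins at the repeat end.
    """

    left: str
    right: str


def pair_reads(reads: Iterable[AlignedRead]) -> list[tuple[AlignedRead, AlignedRead | None]]:
    """Group usable primary records into mate pairs by read name.

    Orphaned mates (name seen once) are kept as (read, None) pairs; callers
    that need both mates skip them with a warning rather than failing.
    """
    by_name: dict[str, list[AlignedRead]] = {}
    for read in reads:
        if not read.usable:
            continue
        by_name.setdefault(read.name, []).append(read)
    pairs = []
    for name, group in by_name.items():
        if len(group) > 2:
            logger.warning("read %s has %d primary records; using first two", name, len(group))
            group = group[:2]
        if len(group) == 2:
            pairs.append((group[0], group[1]))
        else:
            pairs.append((group[0], None))
    return pairs


def _wp_of(
    read: AlignedRead,
    spec: RepeatSpec,
    model: ModelParams,
    wp_cache: Mapping[int, float] | None,
) -> float:
    if wp_cache is not None and id(read) in wp_cache:
        return wp_cache[id(read)]
    return weighted_purity(read.bases, read.quals, spec.motif, model)


def _mate_anchors(read: AlignedRead, spec: RepeatSpec, model: ModelParams) -> bool:
    """Does this read qualify as the high-confidence anchor of an IRR mate?"""
    if not read.is_aligned or read.chrom != spec.chrom or read.mapq < model.anchor_mapq_min:
        return False
    lo = spec.start - model.anchor_window_bp
    hi = spec.end + model.anchor_window_bp
    return read.pos + len(read) > lo and read.pos < hi


def find_anchored_irrs(
    read_pairs: Sequence[tuple[AlignedRead, AlignedRead | None]],
    spec: RepeatSpec,
    model: ModelParams = ModelParams(),
    wp_cache: Mapping[int, float] | None = None,
    exclude_ids: frozenset | set = frozenset(),
) -> list[ReadEvidence]:
    """Anchored IRRs: one mate in-repeat, the other a confident local anchor.

    The anchor must itself not be an IRR — a pure-repeat read cannot align
    uniquely, and requiring this keeps anchored and paired IRRs disjoint.
    One evidence record is emitted per qualifying pair (for the IRR mate).
    """
    u = model.max_units(
        max((len(r) for pair in read_pairs for r in pair if r is not None), default=0),
        len(spec.motif),
    )
    out = []
    for first, second in read_pairs:
        if second is None:
            logger.warning("orphaned mate %s skipped during anchored-IRR search", first.name)
            continue
        for irr, mate in ((first, second), (second, first)):
            # exclusion marks reads already counted as junction evidence;
            # such a read cannot be the IRR, but it still anchors its mate
            if id(irr) in exclude_ids:
                continue
            if not _mate_anchors(mate, spec, model):
                continue
            wp_irr = _wp_of(irr, spec, model, wp_cache)
            if wp_irr < model.wp_threshold:
                continue
            if _wp_of(mate, spec, model, wp_cache) >= model.wp_threshold:
                continue  # both mates in-repeat: that is a paired IRR, not anchored
            out.append(
                ReadEvidence(
                    read_name=irr.name,
                    kind=EvidenceKind.IRR_ANCHORED,
                    units_m=len(irr) // len(spec.motif),
                    wp_score=wp_irr,
                )
            )
            break  # at most one record per pair
    return out


def _in_paired_irr_territory(read: AlignedRead, spec: RepeatSpec) -> bool:
    """Unaligned, or MAPQ 0 inside an off-target region or the locus itself."""
    if not read.is_aligned:
        return True
    if read.mapq != 0:
        return False
    regions = [(spec.chrom, spec.start, spec.end), *spec.offtarget_regions]
    for chrom, start, end in regions:
        if read.chrom == chrom and read.pos + len(read) > start and read.pos < end:
            return True
    return False


def find_paired_irrs(
    read_pairs: Sequence[tuple[AlignedRead, AlignedRead | None]],
    spec: RepeatSpec,
    model: ModelParams = ModelParams(),
    wp_cache: Mapping[int, float] | None = None,
    exclude_ids: frozenset | set = frozenset(),
) -> list[ReadEvidence]:
    """Paired IRRs: both mates in-repeat, unaligned or misaligned at MAPQ 0.

    Two evidence records (one per mate) are emitted for each qualifying pair.
    Pairs aligned anywhere else are ignored, so with an empty off-target list
    only unaligned and at-locus MAPQ-0 pairs are recovered.
    """
    out = []
    for first, second in read_pairs:
        if second is None:
            continue
        if id(first) in exclude_ids or id(second) in exclude_ids:
            continue
        if not (_in_paired_irr_territory(first, spec) and _in_paired_irr_territory(second, spec)):
            continue
        wps = [_wp_of(r, spec, model, wp_cache) for r in (first, second)]
        if min(wps) < model.wp_threshold:
            continue
        for read, wp in zip((first, second), wps):
            out.append(
                ReadEvidence(
                    read_name=read.name,
                    kind=EvidenceKind.IRR_PAIRED,
                    units_m=len(read) // len(spec.motif),
                    wp_score=wp,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Spanning / flanking change-point search
# ---------------------------------------------------------------------------


def _diagonal_sums(matrix: np.ndarray) -> np.ndarray:
    """Sums over constant (col - row) diagonals of a square matrix.

    Returns an array indexed by (col - row) + (n - 1), length 2n - 1.
    """
    n = matrix.shape[0]
    rows, cols = np.indices(matrix.shape)
    off = (cols - rows + n - 1).ravel()
    return np.bincount(off, weights=matrix.ravel(), minlength=2 * n - 1)


def _pad_to(seq: str, length: int, left: bool) -> str:
    """Pad flank sequence with 'N' (always-mismatch) when shorter than needed."""
    if len(seq) >= length:
        return seq[-length:] if left else seq[:length]
    pad = "N" * (length - len(seq))
    return (pad + seq) if left else (seq + pad)


def classify_spanning_or_flanking(
    read: AlignedRead,
    spec: RepeatSpec,
    flanks: ReferenceFlanks,
    model: ModelParams = ModelParams(),
) -> ReadEvidence | None:
    """Best (left flank)(repeat)(right flank) decomposition of one read.

    Returns SPANNING evidence with the exact unit count when both junctions
    lie strictly inside the read, FLANKING with the observed complete-unit
    count when exactly one junction is contained, and ``None`` when the read
    is best explained without any junction (pure flank or pure repeat) or the
    composite score / flank-margin tests fail.
    """
    r = len(read)
    if r == 0:
        return None
    L = len(spec.motif)
    seq = _as_bytes(read.bases)
    quals = np.asarray(read.quals)
    pen = mismatch_penalties(quals, model)
    low = quals < model.low_quality_phred

    fl = _as_bytes(_pad_to(flanks.left, r, left=True))    # last r bases of left flank
    fr = _as_bytes(_pad_to(flanks.right, r, left=False))  # first r bases of right flank
    motif_b = _as_bytes(spec.motif)

    # left_score[a]: read[0:a] against the left flank ending at the junction.
    # Alignment read[j] <-> fl[r - a + j] is constant along diagonals of the
    # (read x flank) score matrix, so all a are diagonal sums of one matrix.
    left_mat = np.where(fl[None, :] == seq[:, None], 1.0, pen[:, None])
    left_diag = _diagonal_sums(left_mat)
    left_score = np.zeros(r + 1)
    left_score[1:] = left_diag[2 * r - 1 - np.arange(1, r + 1)]

    # right_score[b]: read[b:] against the right flank starting at the junction.
    right_mat = np.where(fr[None, :] == seq[:, None], 1.0, pen[:, None])
    right_diag = _diagonal_sums(right_mat.T)  # diagonals of constant (row - col)
    right_score = np.zeros(r + 1)
    right_score[:r] = right_diag[np.arange(r) + r - 1]

    # Repeat-segment scores at each motif phase c: read[j] vs motif[(j-c) % L],
    # as prefix cumsums so any [a, b) segment is an O(1) difference.
    idx = np.arange(r)
    rep_ref = motif_b[(idx[None, :] - np.arange(L)[:, None]) % L]  # (L, r)
    rep_per_base = np.where(rep_ref == seq[None, :], 1.0, pen[None, :])
    rep_cum = np.zeros((L, r + 1))
    rep_cum[:, 1:] = np.cumsum(rep_per_base, axis=1)

    NEG = -np.inf
    best_span = (NEG, 0, 0)   # (score, a, b); tract = read[a:b], whole units
    best_flank = (NEG, 0, 0, "")
    best_degenerate = NEG

    for a in range(r + 1):
        c = a % L
        base = left_score[a] - rep_cum[c, a]
        for b in range(a, r + 1, L):
            total = base + rep_cum[c, b] + right_score[b]
            if 1 <= a and b <= r - 1:
                if total > best_span[0]:
                    best_span = (total, a, b)
            elif (a, b) in ((0, r), (0, 0), (r, r)):
                # pure repeat / pure right flank / pure left flank: the
                # no-junction explanations this read must beat
                best_degenerate = max(best_degenerate, total)
            # other edge cases duplicate the flanking families below

    for a in range(r + 1):  # flank-left family: junction at a, repeat to read end
        c = a % L
        total = left_score[a] + rep_cum[c, r] - rep_cum[c, a]
        if 1 <= a <= r - L:
            if total > best_flank[0]:
                best_flank = (total, a, r, "left")
        else:  # pure repeat (a = 0) or a sub-unit repeat tail: no usable junction
            best_degenerate = max(best_degenerate, total)

    for b in range(r + 1):  # flank-right family: repeat from read start to b
        c = b % L
        total = rep_cum[c, b] + right_score[b]
        if L <= b <= r - 1:
            if total > best_flank[0]:
                best_flank = (total, 0, b, "right")
        else:
            best_degenerate = max(best_degenerate, total)

    if best_span[0] >= best_flank[0] and best_span[0] > NEG:
        score, a, b = best_span
        kind, side = EvidenceKind.SPANNING, "both"
        units = (b - a) // L
    elif best_flank[0] > NEG:
        score, a, b, side = best_flank
        kind = EvidenceKind.FLANKING
        units = ((r - a) if side == "left" else b) // L
    else:
        return None

    if best_degenerate >= score:
        return None  # a no-junction explanation fits at least as well
    wp = score / r
    if wp < model.wp_threshold:
        return None

    def flank_beats_extension(lo: int, hi: int, ref: np.ndarray, phase: int) -> bool:
        """Flank call must beat extending the repeat by the mismatch margin."""
        if hi <= lo:
            return True
        mism_flank = seq[lo:hi] != ref[lo:hi]
        mism_ext = seq[lo:hi] != rep_ref[phase, lo:hi]
        lo_q = low[lo:hi]
        hq_gain = int((mism_ext & ~lo_q).sum()) - int((mism_flank & ~lo_q).sum())
        lq_gain = int((mism_ext & lo_q).sum()) - int((mism_flank & lo_q).sum())
        return hq_gain >= 2 or lq_gain >= 4

    if side in ("both", "left"):
        if not flank_beats_extension(0, a, fl[r - a:].copy() if a else fl, a % L):
            return None
    if side in ("both", "right"):
        # right flank segment read[b:] vs fr starting at index 0
        ref_right = np.full(r, 0, dtype=np.uint8)
        ref_right[b:] = fr[: r - b]
        if not flank_beats_extension(b, r, ref_right, b % L):
            return None

    return ReadEvidence(read_name=read.name, kind=kind, units_m=units, wp_score=wp)
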