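"""Weighted-purity (WP) scoring of reads against a perfect repeat.

A read drawn from inside a repeat tract should match a tandem tiling of the
motif — in either strand orientation and at any rotation (phase) of the
motif.  The WP score compares a read positionally against every such tiling
and keeps the best: each matching base scores +1, each mismatch at a
low-quality base +0.5, and each mismatch at a high-quality base -1; the sum
is normalized by the read length, so WP lies in [-1, 1].  Reads with WP at
or above the threshold (default 0.9) are in-repeat reads (IRRs).
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

import numpy as np

from .catalog import AlignedRead, ModelParams, RepeatSpec

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def motif_variants(motif: str) -> frozenset[str]:
    """All cyclic rotations of the motif and of its reverse complement.

    E.g. a CAG repeat read can tile as CAG/AGC/GCA forward or CTG/TGC/GCT
    on the reverse strand.  The set has at most 2 * len(motif) members.
    """
    if not motif or set(motif) - set("ACGT"):
        raise ValueError(f"invalid motif {motif!r}")
    variants = {motif[i:] + motif[:i] for i in range(len(motif))}
    rc = reverse_complement(motif)
    variants |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return frozenset(variants)


@lru_cache(maxsize=64)
def _variant_matrix(motif: str, length: int) -> np.ndarray:
    """(n_variants, length) byte matrix of each variant tiled to `length`."""
    variants = sorted(motif_variants(motif))
    out = np.empty((len(variants), length), dtype=np.uint8)
    for k, v in enumerate(variants):
        tiled = (v * (length // len(v) + 1))[:length]
        out[k] = np.frombuffer(tiled.encode(), dtype=np.uint8)
    return out


def _as_bytes(bases: str) -> np.ndarray:
    return np.frombuffer(bases.upper().encode(), dtype=np.uint8)


def mismatch_penalties(quals: np.ndarray, model: ModelParams) -> np.ndarray:
    """Per-base score applied when the base mismatches the repeat tiling."""
    return np.where(np.asarray(quals) < model.low_quality_phred, 0.5, -1.0)


def weighted_purity(
    bases: str,
    quals: Sequence[int] | np.ndarray,
    motif: str,
    model: ModelParams = ModelParams(),
) -> float:
    """WP score of one read against the best motif variant tiling.

    Because every phase offset of a tiling is itself a rotation of the motif,
    scoring each rotation at phase zero covers all variant x phase pairs.
    """
    if len(bases) == 0:
        raise ValueError("cannot score an empty read")
    seq = _as_bytes(bases)
    quals = np.asarray(quals)
    if len(quals) != len(seq):
        raise ValueError("bases and qualities differ in length")
    pen = mismatch_penalties(quals, model)
    tilings = _variant_matrix(motif, len(seq))
    per_base = np.where(tilings == seq[None, :], 1.0, pen[None, :])
    return float(per_base.sum(axis=1).max() / len(seq))


def weighted_purity_bulk(
    reads: Sequence[AlignedRead],
    motif: str,
    model: ModelParams = ModelParams(),
) -> np.ndarray:
    """Vectorized WP for many reads (grouped internally by read length)."""
    scores = np.empty(len(reads), dtype=float)
    by_len: dict[int, list[int]] = {}
    for idx, read in enumerate(reads):
        by_len.setdefault(len(read), []).append(idx)
    for length, indices in by_len.items():
        if length == 0:
            raise ValueError("cannot score an empty read")
        seqs = np.stack([_as_bytes(reads[i].bases) for i in indices])
        pens = np.stack([mismatch_penalties(reads[i].quals, model) for i in indices])
        tilings = _variant_matrix(motif, length)
        best = np.full(len(indices), -np.inf)
        for row in tilings:
            match = seqs == row[None, :]
            per_read = np.where(match, 1.0, pens).sum(axis=1)
            np.maximum(best, per_read, out=best)
        scores[indices] = best / length
    return scores


def is_irr(read: AlignedRead, spec: RepeatSpec, model: ModelParams = ModelParams()) -> bool:
    """True iff the read's WP against the locus motif reaches the threshold."""
    return weighted_purity(read.bases, read.quals, spec.motif, model) >= model.wp_threshold
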