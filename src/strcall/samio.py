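"""Thin readers: SAM/BAM alignments to AlignedRead, FASTA to reference flanks.

The genotyper needs unaligned mates to be present in the input (standard
aligners emit them placed with their mate), so readers iterate every record
rather than relying on an index; inputs are expected to be region-extracted
or simulated files of locus scale.
"""

from __future__ import annotations

import numpy as np
import pysam
from pyfaidx import Fasta

from .catalog import AlignedRead, RepeatSpec
from .classify import ReferenceFlanks


def read_alignments(path) -> list[AlignedRead]:
    """Load all primary alignment records (SAM or BAM) as AlignedRead."""
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.query_sequence is None:
                continue
            quals = (
                np.array(seg.query_qualities, dtype=np.uint8)
                if seg.query_qualities is not None
                else np.full(len(seg.query_sequence), 30, dtype=np.uint8)
            )
            mate_aligned = seg.is_paired and not seg.mate_is_unmapped
            out.append(
                AlignedRead(
                    name=seg.query_name,
                    bases=seg.query_sequence.upper(),
                    quals=quals,
                    chrom=None if seg.is_unmapped else seg.reference_name,
                    pos=None if seg.is_unmapped else seg.reference_start,
                    mapq=seg.mapping_quality,
                    mate_chrom=seg.next_reference_name if mate_aligned else None,
                    mate_pos=seg.next_reference_start if mate_aligned else None,
                    is_paired=seg.is_paired,
                    is_read1=not seg.is_paired or seg.is_read1,
                    is_reverse=seg.is_reverse,
                    is_proper=seg.is_proper_pair,
                    is_duplicate=seg.is_duplicate,
                    is_secondary=seg.is_secondary,
                    is_supplementary=seg.is_supplementary,
                )
            )
    return out


def load_flanks(fasta_path, spec: RepeatSpec, flank_bp: int = 1000) -> ReferenceFlanks:
    """Extract the reference sequence flanking the repeat interval."""
    ref = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    if spec.chrom not in ref:
        raise ValueError(f"chromosome {spec.chrom!r} not in reference {fasta_path}")
    chrom_len = len(ref[spec.chrom])
    left = str(ref[spec.chrom][max(0, spec.start - flank_bp) : spec.start])
    right = str(ref[spec.chrom][spec.end : min(chrom_len, spec.end + flank_bp)])
    return ReferenceFlanks(left=left, right=right)
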