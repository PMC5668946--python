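"""Paired-end read simulator for diploid repeat loci, with truth labels.

The generator emulates PCR-free WGS of a single repeat locus: two haplotypes
(flank + motif x n + flank), fragments drawn at a per-base Bernoulli rate
matching the target depth with Normal(fragment_mean, fragment_sd) lengths,
paired reads taken from the fragment ends, Phred-scaled two-point base
qualities (Q30 with a low-quality Q10 minority), and substitution errors at
lowered-quality bases, concentrated in the repeat tract where real
sequencing error rates are elevated.  Defaults mirror the sequencing designs
the method targets: 150 bp paired reads, ~45x depth, 350-450 bp fragments.

Alignment assignment has two modes.  ``oracle`` places every read at its
true reference coordinate with MAPQ 60 — useful for testing classification
in isolation.  ``decoy`` reproduces what an aligner does to reads from an
expansion that is absent from the reference: in-repeat reads drop to MAPQ 0
at the locus, and pairs in which both mates are in-repeat are emitted
unaligned (a configurable fraction, default one third) or misaligned with
MAPQ 0 at decoy loci on other contigs — exercising the off-target machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .catalog import AlignedRead, RepeatSpec
from .classify import ReferenceFlanks

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_Q_HIGH = 30
_Q_LOW = 10


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated sample."""

    motif: str = "GGCCCC"
    alleles: tuple[int, ...] = (3, 3)
    ref_units: int = 3
    read_length: int = 150
    mean_depth: float = 45.0
    fragment_mean: float = 400.0
    fragment_sd: float = 50.0
    base_error_rate: float = 0.001
    repeat_error_multiplier: float = 3.0
    low_quality_fraction: float = 0.05
    flank_length: int = 2000
    flank_seqs: tuple[str, str] | None = None
    chrom: str = "sim1"
    n_decoys: int = 0
    decoy_length: int = 1000
    unaligned_fraction: float = 1.0 / 3.0
    pathogenic_cutoff_units: int | None = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fragment_mean <= self.read_length:
            raise ValueError("fragment_mean must exceed the read length")
        if any(a < 0 for a in self.alleles):
            raise ValueError("allele lengths must be non-negative")
        if len(self.alleles) not in (1, 2):
            raise ValueError("one or two alleles (haploid or diploid locus)")
        if set(self.motif) - set("ACGT") or not self.motif:
            raise ValueError(f"invalid motif {self.motif!r}")


@dataclass
class SimRead:
    """One simulated read before alignment assignment (haplotype coordinates)."""

    name: str
    hap: int
    start: int          # reference-orientation start on the haplotype
    bases: str
    quals: np.ndarray
    is_read1: bool
    is_reverse: bool
    category: str       # spanning | flanking | in_repeat | flank_only
    repeat_bp: int
    left_flank_bp: int
    right_flank_bp: int


@dataclass
class SimulatedSample:
    config: SimConfig
    haplotypes: tuple[str, ...]
    truth: dict
    reads: list[AlignedRead]
    sim_reads: list[SimRead]
    spec: RepeatSpec
    reference: dict[str, str]
    flanks: ReferenceFlanks

    def write_sam(self, path) -> None:
        write_alignments(self.reads, self.reference, path)

    def write_reference(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.reference.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def write_truth(self, path) -> None:
        cols = "name\tmate\thap\tcategory\trepeat_bp\tleft_flank_bp\tright_flank_bp\tstart"
        with open(path, "w") as fh:
            fh.write(f"# alleles_units={','.join(map(str, self.truth['alleles_units']))} "
                     f"alleles_bp={','.join(map(str, self.truth['alleles_bp']))}\n")
            fh.write(cols + "\n")
            for sr in self.sim_reads:
                fh.write(
                    f"{sr.name}\t{1 if sr.is_read1 else 2}\t{sr.hap}\t{sr.category}\t"
                    f"{sr.repeat_bp}\t{sr.left_flank_bp}\t{sr.right_flank_bp}\t{sr.start}\n"
                )

    def write_catalog(self, path) -> None:
        from .catalog import write_catalog

        write_catalog([self.spec], path)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def build_haplotypes(config: SimConfig, rng: np.random.Generator | None = None):
    """Flank + motif x n + flank per haplotype, with a truth record."""
    rng = rng or np.random.default_rng(config.seed)
    if config.flank_seqs is not None:
        left, right = config.flank_seqs
    else:
        left = _random_seq(rng, config.flank_length)
        right = _random_seq(rng, config.flank_length)
    haps = tuple(left + config.motif * n + right for n in config.alleles)
    truth = {
        "alleles_units": tuple(sorted(config.alleles)),
        "alleles_bp": tuple(sorted(n * len(config.motif) for n in config.alleles)),
        "left_flank": left,
        "right_flank": right,
    }
    return haps, truth


def _categorize(start: int, end: int, tract_start: int, tract_end: int, hap_len: int):
    repeat_bp = max(0, min(end, tract_end) - max(start, tract_start))
    left_bp = max(0, min(end, tract_start) - start)
    right_bp = max(0, end - max(start, tract_end))
    covers_left = start < tract_start and end > tract_start
    covers_right = start < tract_end and end > tract_end
    if tract_start == tract_end:  # zero-length tract: one junction point
        covers_left = covers_right = start < tract_start < end
    if covers_left and covers_right:
        category = "spanning"
    elif covers_left or covers_right:
        category = "flanking"
    elif repeat_bp == end - start and repeat_bp > 0:
        category = "in_repeat"
    else:
        category = "flank_only"
    return category, repeat_bp, left_bp, right_bp


def sample_reads(
    haplotypes: Sequence[str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    truth: dict | None = None,
) -> list[SimRead]:
    """Draw paired reads from fragment ends at the configured depth.

    Fragment starts follow a per-base Bernoulli process at rate
    depth / (4 r) per haplotype, so read starts (two per fragment, one per
    mate) occur at depth / (2 r) per haplotype — the same Bernoulli-start
    model the size estimators assume.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    r = config.read_length
    L = len(config.motif)
    reads: list[SimRead] = []
    pair_idx = 0
    for h, hap in enumerate(haplotypes):
        g = len(hap)
        if g <= config.fragment_mean:
            raise ValueError("haplotype shorter than the mean fragment length")
        tract_start = (
            len(truth["left_flank"]) if truth else config.flank_length
        )
        tract_end = tract_start + config.alleles[h] * L
        rate = config.mean_depth / (4.0 * r) / len(haplotypes) * 2.0
        n_frag = rng.binomial(g - r, rate)
        starts = np.sort(rng.integers(0, g - r + 1, size=n_frag))
        lengths = rng.normal(config.fragment_mean, config.fragment_sd, size=n_frag)
        lengths = np.clip(np.round(lengths).astype(int), r, None)
        for s, flen in zip(starts, lengths):
            flen = min(int(flen), g - int(s))
            if flen < r:
                continue
            e = int(s) + flen
            name = f"sim{config.seed}_{pair_idx}"
            pair_idx += 1
            for (rs, re), is_read1, is_rev in (
                ((int(s), int(s) + r), True, False),
                ((e - r, e), False, True),
            ):
                seq = np.frombuffer(hap[rs:re].encode(), dtype=np.uint8).copy()
                quals = np.full(r, _Q_HIGH, dtype=np.uint8)
                low_mask = rng.random(r) < config.low_quality_fraction
                quals[low_mask] = _Q_LOW
                if config.base_error_rate > 0:
                    pos = np.arange(rs, re)
                    in_tract = (pos >= tract_start) & (pos < tract_end)
                    err_p = config.base_error_rate * np.where(
                        in_tract, config.repeat_error_multiplier, 1.0
                    )
                    err = rng.random(r) < err_p
                    if err.any():
                        shift = rng.integers(1, 4, size=int(err.sum()))
                        idx = np.searchsorted(_BASES, seq[err])
                        seq[err] = _BASES[(idx + shift) % 4]
                        quals[err] = _Q_LOW
                category, rep_bp, l_bp, r_bp = _categorize(
                    rs, re, tract_start, tract_end, g
                )
                reads.append(
                    SimRead(
                        name=name,
                        hap=h,
                        start=rs,
                        bases=seq.tobytes().decode(),
                        quals=quals,
                        is_read1=is_read1,
                        is_reverse=is_rev,
                        category=category,
                        repeat_bp=rep_bp,
                        left_flank_bp=l_bp,
                        right_flank_bp=r_bp,
                    )
                )
    return reads


def assign_alignments(
    sim_reads: Sequence[SimRead],
    config: SimConfig,
    truth: dict,
    mode: str = "oracle",
    rng: np.random.Generator | None = None,
) -> list[AlignedRead]:
    """Turn simulated reads into alignment records per the chosen mode."""
    if mode not in ("oracle", "decoy"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    rng = rng or np.random.default_rng(config.seed + 2)
    L = len(config.motif)
    tract_start = len(truth["left_flank"])
    ref_tract_end = tract_start + config.ref_units * L

    by_name: dict[str, list[SimRead]] = {}
    for sr in sim_reads:
        by_name.setdefault(sr.name, []).append(sr)

    out: list[AlignedRead] = []
    decoy_cycle = 0
    for name, mates in by_name.items():
        placements: list[tuple[str | None, int | None, int]] = []
        both_in_repeat = len(mates) == 2 and all(m.category == "in_repeat" for m in mates)
        if both_in_repeat and mode == "decoy":
            if config.n_decoys > 0 and rng.random() >= config.unaligned_fraction:
                decoy = f"decoy{decoy_cycle % config.n_decoys + 1}"
                decoy_cycle += 1
                hi = max(101, config.decoy_length - 2 * config.read_length)
                base = int(rng.integers(100, hi))
                second = min(base + 60, max(base, config.decoy_length - config.read_length))
                placements = [(decoy, base, 0), (decoy, second, 0)]
            else:
                placements = [(None, None, 0) for _ in mates]
        else:
            for m in mates:
                n_units = config.alleles[m.hap]
                shift = (n_units - config.ref_units) * L
                tract_end_hap = tract_start + n_units * L
                if m.start < tract_start:
                    placements.append((config.chrom, m.start, 60))
                elif m.start >= tract_end_hap:
                    placements.append((config.chrom, m.start - shift, 60))
                else:  # starts inside the tract
                    mapq = 60 if mode == "oracle" or m.category != "in_repeat" else 0
                    placements.append((config.chrom, tract_start, mapq))
        for k, m in enumerate(mates):
            chrom, pos, mapq = placements[k]
            mate_chrom, mate_pos = (None, None)
            if len(mates) == 2:
                mate_chrom, mate_pos = placements[1 - k][0], placements[1 - k][1]
            out.append(
                AlignedRead(
                    name=name,
                    bases=m.bases,
                    quals=m.quals,
                    chrom=chrom,
                    pos=pos,
                    mapq=mapq,
                    mate_chrom=mate_chrom,
                    mate_pos=mate_pos,
                    is_paired=len(mates) == 2,
                    is_read1=m.is_read1,
                    is_reverse=m.is_reverse,
                    is_proper=chrom is not None
                    and mate_chrom is not None
                    and chrom == mate_chrom,
                )
            )
    return out


def simulate_sample(config: SimConfig, mode: str = "oracle") -> SimulatedSample:
    """Full sample simulation: haplotypes, reads, alignments, truth, catalog."""
    rng = np.random.default_rng(config.seed)
    haps, truth = build_haplotypes(config, rng)
    sim_reads = sample_reads(haps, config, rng, truth)
    aligned = assign_alignments(sim_reads, config, truth, mode=mode, rng=rng)

    left, right = truth["left_flank"], truth["right_flank"]
    L = len(config.motif)
    reference = {config.chrom: left + config.motif * config.ref_units + right}
    decoy_regions = []
    for d in range(config.n_decoys):
        name = f"decoy{d + 1}"
        reference[name] = _random_seq(rng, config.decoy_length)
        decoy_regions.append((name, 0, config.decoy_length))
    spec = RepeatSpec(
        locus_id="simulated_locus",
        chrom=config.chrom,
        start=len(left),
        end=len(left) + config.ref_units * L,
        motif=config.motif,
        offtarget_regions=tuple(decoy_regions),
        pathogenic_cutoff_units=config.pathogenic_cutoff_units,
    )
    return SimulatedSample(
        config=config,
        haplotypes=haps,
        truth=truth,
        reads=aligned,
        sim_reads=sim_reads,
        spec=spec,
        reference=reference,
        flanks=ReferenceFlanks(left=left, right=right),
    )


def write_alignments(reads: Sequence[AlignedRead], reference: dict[str, str], path) -> None:
    """Serialize alignment records as plain-text SAM with a valid header."""
    import pysam

    chroms = list(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(reference[c])} for c in chroms],
    }
    chrom_id = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for read in reads:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = read.name
            seg.query_sequence = read.bases
            seg.query_qualities = [int(q) for q in read.quals]
            flag = 0
            if read.is_paired:
                flag |= 0x1
                flag |= 0x40 if read.is_read1 else 0x80
                if read.is_proper:
                    flag |= 0x2
            if read.chrom is None:
                flag |= 0x4
            if read.is_reverse:
                flag |= 0x10
            if read.is_paired and read.mate_chrom is None:
                flag |= 0x8
            seg.flag = flag
            if read.chrom is not None:
                seg.reference_id = chrom_id[read.chrom]
                seg.reference_start = read.pos
                seg.mapping_quality = read.mapq
                seg.cigarstring = f"{len(read.bases)}M"
            else:
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 0
            if read.is_paired and read.mate_chrom is not None:
                seg.next_reference_id = chrom_id[read.mate_chrom]
                seg.next_reference_start = read.mate_pos
            else:
                seg.next_reference_id = -1
                seg.next_reference_start = -1
            fh.write(seg)
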