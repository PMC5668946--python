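"""Domain types, the repeat-catalog format, and per-sample sequencing parameters.

A *repeat catalog* is a JSON array of locus definitions.  Each entry names a
short tandem repeat by its reference interval (0-based, half-open), its repeat
motif in the catalog's literal orientation, an optional list of off-target
regions where reads from an expanded allele are known to misalign, and an
optional pathogenic cutoff in repeat units.

Sample-level parameters reduce to two numbers: the read length ``r`` and the
mean per-base depth ``D``.  Their ratio ``pi = D / r`` is the per-base
probability that a read starts at a given position under the Bernoulli
read-start model used throughout the size estimators.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

_MOTIF_RE = re.compile(r"^[ACGT]+$")
_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


class CatalogError(ValueError):
    """Malformed repeat catalog (bad JSON, bad motif, bad coordinates...)."""


class UnusableSampleError(ValueError):
    """Sample parameters cannot be derived (no reads and no overrides)."""


def _interval_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


@dataclass(frozen=True)
class RepeatSpec:
    """One repeat-catalog entry.

    Coordinates are 0-based half-open (BED convention).  ``offtarget_regions``
    lists ``(chrom, start, end)`` intervals where paired in-repeat reads from
    an expansion of this motif are known to misalign; an empty list puts the
    locus in anchored-only mode.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    motif: str
    offtarget_regions: tuple[tuple[str, int, int], ...] = ()
    pathogenic_cutoff_units: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CatalogError(
                f"locus {self.locus_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if not _MOTIF_RE.match(self.motif or ""):
            raise CatalogError(
                f"locus {self.locus_id!r}: motif {self.motif!r} must be a nonempty ACGT string"
            )
        for chrom, s, e in self.offtarget_regions:
            if e <= s:
                raise CatalogError(
                    f"locus {self.locus_id!r}: off-target region {chrom}:{s}-{e} is empty"
                )
            if chrom == self.chrom and _interval_overlap(s, e, self.start, self.end) > 0:
                raise CatalogError(
                    f"locus {self.locus_id!r}: off-target region {chrom}:{s}-{e} "
                    f"overlaps the repeat interval"
                )
        if self.pathogenic_cutoff_units is not None and self.pathogenic_cutoff_units <= 0:
            raise CatalogError(
                f"locus {self.locus_id!r}: pathogenic cutoff must be a positive integer"
            )

    @property
    def region(self) -> str:
        """0-based half-open region string, as stored in the catalog."""
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def region_1based(self) -> str:
        """1-based inclusive rendering for human-facing output."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def to_dict(self) -> dict:
        d = {
            "locus_id": self.locus_id,
            "region": self.region,
            "motif": self.motif,
            "offtarget_regions": [f"{c}:{s}-{e}" for c, s, e in self.offtarget_regions],
        }
        if self.pathogenic_cutoff_units is not None:
            d["pathogenic_cutoff_units"] = self.pathogenic_cutoff_units
        return d


@dataclass(frozen=True)
class SampleParams:
    """Read length ``r`` (bp) and mean depth ``D`` of the sample.

    ``pi = D / r`` is the Bernoulli read-start probability per base.
    """

    read_length: int
    mean_depth: float

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if not (0.0 < self.pi < 1.0):
            raise ValueError(
                f"pi = mean_depth / read_length = {self.pi:.4g} must lie in (0, 1)"
            )

    @property
    def pi(self) -> float:
        return self.mean_depth / self.read_length


@dataclass(frozen=True)
class ModelParams:
    """Tunable model parameters.

    p
        Repeat-size fidelity: the proportion of molecules whose observed unit
        count equals the allele's true count.
    s
        Cap on the deviation ``|n - m|`` entering the geometric-style
        frequency function.
    wp_threshold
        Minimum weighted-purity score for a read to count as in-repeat, and
        for the composite spanning/flanking test.
    anchor_mapq_min, anchor_window_bp
        The mate of an anchored in-repeat read must align with at least this
        MAPQ within this many bp of the repeat interval.
    low_quality_phred
        Bases below this Phred score are "low quality" for WP scoring.
    """

    p: float = 0.97
    s: int = 5
    wp_threshold: float = 0.9
    anchor_mapq_min: int = 60
    anchor_window_bp: int = 1000
    low_quality_phred: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError("p must lie in (0, 1)")
        if self.s < 0:
            raise ValueError("s must be a non-negative integer")
        if not (-1.0 <= self.wp_threshold <= 1.0):
            raise ValueError("wp_threshold must lie in [-1, 1]")

    def max_units(self, read_length: int, motif_len: int) -> int:
        """u: the maximum number of repeat units representable in one read."""
        return read_length // motif_len


@dataclass
class AlignedRead:
    """A single alignment record, with only the fields evidence needs.

    ``chrom is None`` marks an unaligned read; likewise for the mate.  Bases
    are stored in reference orientation for aligned reads (as SAM does), and
    qualities are Phred scores, one per base.
    """

    name: str
    bases: str
    quals: np.ndarray
    chrom: str | None = None
    pos: int | None = None
    mapq: int = 0
    mate_chrom: str | None = None
    mate_pos: int | None = None
    is_paired: bool = True
    is_read1: bool = True
    is_reverse: bool = False
    is_proper: bool = False
    is_duplicate: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.uint8)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.name!r}: {len(self.bases)} bases but {len(self.quals)} quality scores"
            )

    @property
    def is_aligned(self) -> bool:
        return self.chrom is not None

    @property
    def usable(self) -> bool:
        """Secondary/supplementary/duplicate records are never evidence."""
        return not (self.is_secondary or self.is_supplementary or self.is_duplicate)

    def __len__(self) -> int:
        return len(self.bases)


def _parse_region(text: str, locus_id: str) -> tuple[str, int, int]:
    m = _REGION_RE.match(text)
    if not m:
        raise CatalogError(f"locus {locus_id!r}: cannot parse region {text!r}")
    return m.group(1), int(m.group(2)), int(m.group(3))


_KNOWN_FIELDS = {"locus_id", "region", "motif", "offtarget_regions", "pathogenic_cutoff_units"}


def load_catalog(path) -> list[RepeatSpec]:
    """Read a JSON repeat catalog; reject malformed entries naming the locus."""
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CatalogError(f"catalog {path}: invalid JSON ({exc})") from exc
    if not isinstance(raw, list):
        raise CatalogError(f"catalog {path}: top level must be a JSON array")
    specs: list[RepeatSpec] = []
    seen: set[str] = set()
    for entry in raw:
        locus_id = str(entry.get("locus_id", "<missing locus_id>"))
        unknown = set(entry) - _KNOWN_FIELDS
        if unknown:
            raise CatalogError(f"locus {locus_id!r}: unknown fields {sorted(unknown)}")
        if "region" not in entry or "motif" not in entry:
            raise CatalogError(f"locus {locus_id!r}: 'region' and 'motif' are required")
        chrom, start, end = _parse_region(entry["region"], locus_id)
        offtargets = tuple(
            _parse_region(r, locus_id) for r in entry.get("offtarget_regions", [])
        )
        spec = RepeatSpec(
            locus_id=locus_id,
            chrom=chrom,
            start=start,
            end=end,
            motif=str(entry["motif"]),
            offtarget_regions=offtargets,
            pathogenic_cutoff_units=entry.get("pathogenic_cutoff_units"),
        )
        if spec.locus_id in seen:
            raise CatalogError(f"locus {locus_id!r}: duplicate locus_id")
        seen.add(spec.locus_id)
        specs.append(spec)
    return specs


def write_catalog(specs: Sequence[RepeatSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in specs], fh, indent=2)
        fh.write("\n")


def derive_sample_params(
    reads: Iterable[AlignedRead],
    spec: RepeatSpec,
    read_length_override: int | None = None,
    depth_override: float | None = None,
    flank_bp: int = 1000,
) -> SampleParams:
    """Estimate (r, D) for a sample, or take the provided overrides.

    Depth is the mean per-base coverage of usable primary reads over the two
    ``flank_bp`` flanks of the locus — a local estimate that is robust to
    genome-wide coverage variation.  The windows are set back one read length
    from the repeat interval and only confidently mapped reads (MAPQ > 0)
    count: aligners pile poorly mapped repeat reads onto the locus boundary,
    which would otherwise inflate the local depth and deflate every size
    estimate built on pi.  Read length is the most common length.
    """
    if read_length_override is not None and depth_override is not None:
        return SampleParams(read_length_override, depth_override)

    reads = [
        r
        for r in reads
        if r.usable and r.is_aligned and r.chrom == spec.chrom
    ]
    lengths: dict[int, int] = {}
    for read in reads:
        lengths[len(read)] = lengths.get(len(read), 0) + 1
    if not lengths and (read_length_override is None or depth_override is None):
        raise UnusableSampleError(
            f"locus {spec.locus_id!r}: no usable aligned reads near the locus and "
            f"no read-length/depth overrides"
        )
    read_length = read_length_override or max(lengths, key=lengths.get)
    if depth_override is not None:
        depth = depth_override
    else:
        setback = read_length
        windows = [
            (max(0, spec.start - setback - flank_bp), max(0, spec.start - setback)),
            (spec.end + setback, spec.end + setback + flank_bp),
        ]
        total_bp = 0
        for read in reads:
            if read.mapq == 0:
                continue
            for w_start, w_end in windows:
                total_bp += _interval_overlap(
                    read.pos, read.pos + len(read), w_start, w_end
                )
        window_bp = sum(e - s for s, e in windows)
        depth = total_bp / window_bp
    if depth <= 0:
        raise UnusableSampleError(
            f"locus {spec.locus_id!r}: zero flank coverage; cannot estimate depth"
        )
    return SampleParams(read_length, depth)
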