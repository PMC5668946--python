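# strcall

Targeted genotyping of short tandem repeats (STRs) — including pathogenic
repeat expansions far longer than the read length — from paired-end,
PCR-free whole-genome sequencing alignments.

Large STR expansions cause diseases such as ALS/FTD (a GGCCCC hexamer in
*C9orf72*, pathogenic above ~30 units), fragile X syndrome (*FMR1*, CGG),
Friedreich's ataxia (*FXN*, GAA) and Huntington's disease (*HTT*, CAG).
Standard small-variant callers need reads that span the whole allele, which
caps them at the read length (~150 bp); pathogenic expansions run to
thousands of bp. `strcall` genotypes a cataloged repeat locus from three
kinds of read evidence:

* **spanning reads** contain the whole repeat plus both flank junctions and
  give the exact unit count;
* **flanking reads** contain one junction and bound the repeat from below;
* **in-repeat reads (IRRs)** lie entirely inside the repeat.  An IRR is
  *anchored* when its mate aligns confidently (MAPQ ≥ 60) within 1 kbp of
  the locus, and *paired* when both mates are IRRs — such pairs are
  unaligned or misaligned (MAPQ 0) at reproducible *off-target* loci
  because the expansion is absent from the reference.

## Model

Reads are recognized as in-repeat by a quality-aware **weighted purity**
score against the best motif rotation on either strand: +1 per match, +0.5
per low-quality mismatch (Phred < 20), −1 per high-quality mismatch,
normalized by read length; WP ≥ 0.9 marks an IRR.

Read starts follow a Bernoulli process with per-base rate π = depth / read
length, so the IRR count *i* from a repeat of length *N* bp is binomial
over its *N − r* eligible start positions and the repeat length is
estimated as

    N̂ = r + i / π

with a parametric-bootstrap confidence interval (resampled at the fragment
level — see `docs/methods.md`).

The diploid genotype *G* = (n₁, n₂), in repeat units, maximizes the read
likelihood P(R|G) with each read an equal mixture over the two haplotypes
and per-read likelihoods built from the capped-geometric frequency
function f(m|p, n, s) ∝ p(1−p)^min(|n−m|, s) (defaults p = 0.97, s = 5).
Repeats longer than the read appear as the stand-in allele u = ⌊r/|motif|⌋
and are then sized from the IRR count.  A call is labeled **expanded** when
the long allele's CI lies entirely above the locus cutoff, **gray** when
the CI straddles it (treated as a potential expansion), **normal**
otherwise.

## Worked example

Simulate a 45×-style PCR-free sample heterozygous for a 350-unit (2100 bp)
GGCCCC expansion, then genotype it:

```sh
strcall simulate --alleles 3,350 --depth 40 --decoys 2 \
    --error-rate 0.001 --flank-length 2000 --seed 7 --out-prefix example
strcall genotype --reads example.sam --catalog example_catalog.json \
    --reference example.fa --output example_calls.json --seed 1
```

The JSON report contains one record per catalog locus; for this sample:

```json
{
  "locus_id": "simulated_locus",
  "motif": "GGCCCC",
  "pathogenic_cutoff_units": 30,
  "genotype_units": [3, 340],
  "alleles": [
    {"point_units": 3,   "ci_units": [3, 3],     "evidence": "spanning"},
    {"point_units": 340, "ci_units": [293, 392], "evidence": "irr",
     "point_bp": 2042.0, "irr_count": 246}
  ],
  "supporting_counts": {"spanning": 17, "flanking": 39,
                        "anchored_irr": 34, "paired_irr": 212},
  "label": "expanded",
  "sample_params": {"read_length": 150, "mean_depth": 39.01, "pi": 0.26}
}
```

Reading: 17 spanning reads pin the short allele at exactly 3 units; 246
in-repeat reads (34 anchored, 212 recovered from off-target/unaligned
pairs) size the long allele at ~2042 bp ≈ 340 units with a 95% CI of
293–392 units — the simulated truth was 350 units (2100 bp).  The CI sits
entirely above the 30-unit cutoff, so the call is `expanded`.

Off-target regions for a motif are discovered from a cohort with

```sh
strcall discover-offtarget --reads s1.sam --reads s2.sam ... \
    --motif GGCCCC --merge-distance 500 --min-samples 5 --out-prefix offt
```

which writes a BED of regions recurrent in ≥ 5 samples, pasteable into a
catalog entry's `offtarget_regions`.

## Repeat catalog format

A JSON array; coordinates are 0-based half-open:

```json
[{"locus_id": "C9orf72",
  "region": "chr9:27573483-27573546",
  "motif": "GGCCCC",
  "offtarget_regions": ["chr2:33141000-33141600"],
  "pathogenic_cutoff_units": 30}]
```

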