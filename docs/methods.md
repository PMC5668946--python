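# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the bundled simulator can demonstrate.

## Read classification

**Weighted purity (WP).** A read is compared positionally against the
infinite perfect repeat of every cyclic rotation of the motif and of its
reverse complement (at most 2·|motif| tilings; every phase offset of a
tiling is itself a rotation, so rotations at phase zero cover all
variant × phase pairs).  Per base: +1 for a match, +0.5 for a mismatch at
a low-quality base, −1 for a mismatch at a high-quality base; the sum is
divided by the read length and the maximum over tilings is the score.
Reads with WP ≥ 0.9 (`wp_threshold`) are in-repeat reads.  The low/high
quality boundary is Phred 20 (`low_quality_phred`) — the conventional
Q20 line; it is a configuration knob, not a fitted value.  The comparison
is purely positional: a read with an indel inside the repeat scores as a
run of mismatches and will usually fall below the gate.  This is an
accepted limitation, not a bug.

**Junction decomposition.** Spanning/flanking detection searches every
decomposition of a read into (left-flank suffix)(k complete motif
units)(right-flank prefix), scored with the same per-base weights, using
the reference flank sequences anchored at the junctions.  The search is
O(r²/|motif|) per read after O(r²) table construction (diagonal sums of
two read × flank score matrices plus per-phase cumulative sums against the
motif).  A candidate wins only if

1. its composite score ≥ `wp_threshold` × read length (the flanks and the
   repeat segment are scored jointly);
2. no junction-free explanation (pure flank, pure repeat) scores as well;
3. each contained flank segment beats the alternative of extending the
   repeat through it by a mismatch margin: the extension must carry at
   least 2 more high-quality mismatches **or** at least 4 more low-quality
   mismatches.  The OR combination was chosen where the rule's
   conjunction was genuinely ambiguous; it is the weaker (more
   conservative) reading, demanding more flank sequence when the flank
   resembles the motif.  The margin test applies to both flanks of a
   spanning read and to the single contained flank of a flanking read.

Spanning reads report their exact unit count; flanking reads report
complete motif copies only (floor).  Reads with a junction result are
excluded from IRR evidence: a read that is 95% repeat can clear the WP
gate, and its junction is the more informative signal.

**Anchoring.** An anchored IRR's mate must align with MAPQ ≥ 60
(`anchor_mapq_min`) within 1 kbp (`anchor_window_bp`) of the repeat
interval, and must not itself be an IRR — a pure-repeat read cannot align
uniquely, and the exclusion keeps anchored and paired IRR sets disjoint.
Paired IRRs (both mates in-repeat) are accepted when each mate is
unaligned or mapped with MAPQ 0 inside the locus or a cataloged
off-target region.  They enter the size estimate only when the catalog
lists off-target regions for the locus: with a common motif (CAG, GAA)
the origin of a poorly mapped pair cannot be resolved, and the estimate
then falls back to anchored IRRs alone, which bound the expansion from
below at roughly the fragment length.  Duplicate, secondary and
supplementary records are never evidence.

## Repeat size estimation

Read starts are modeled as a Bernoulli process with per-base success
probability π = depth / read length.  An in-repeat read must start in a
window of N − r bases, so the count i is Binomial(N − r, π) and the
method-of-moments estimate is N̂ = r + i/π.  Two refinements:

* **Haplotype fraction.** π is the whole-sample rate.  For a heterozygous
  expansion the IRRs come from one haplotype, so the estimator uses
  π · `hap_fraction` with `hap_fraction` = (expanded alleles)/ploidy (0.5
  for a diploid heterozygote).  The default of 1.0 reproduces the plain
  formula and is exact for homozygous or haploid expansions.
* **Fragment-level bootstrap.** The 95% CI is a parametric-bootstrap
  percentile interval.  Mates are not independent draws: a fragment fully
  inside the tract yields two IRRs at once, so the IRR count is
  overdispersed relative to the independent-read binomial.  The bootstrap
  therefore resamples fragments (clusters) and scales by the observed
  mean IRRs per fragment (i / (anchored + pairs)).  In calibration runs
  (200 replicates of a homozygous 2 kb expansion at 40×) independent-read
  resampling covered truth in ~81% of nominal-95% intervals; fragment
  resampling covers ~92–94%.  Defaults: `n_boot` = 1000, level = 95%,
  percentile method, seeded generator; the bootstrap method and its
  settings were open choices.

Flanking reads bound repeats near the read length.  Each flanking read
starts in one of two ~N-base windows (one per junction), so the expected
count is k ≈ 2Nπ and N̂ = k/(2π); the bootstrap distribution is clipped
to the feasible band [longest repeat stretch observed in any flanking
read, ⌊r/|motif|⌋] before percentiles are taken.  The flanking procedure
is an interpretation — what exactly is resampled for flank-only evidence
was an open design point — and is documented here rather than asserted as
canonical.

## Genotyping

Genotypes are tuples of allele sizes in repeat units (ploidy 1 or 2).
With a uniform prior over candidate genotypes, calling is an exhaustive
argmax of the log-likelihood; each read mixes equally over the two
haplotypes, P(r|G) = ½P(r|H₁) + ½P(r|H₂).  Per-read likelihoods use the
capped-geometric frequency function

    f(m | p, n, s) ∝ p (1 − p)^d,  d = min(|n − m|, s)

normalized per allele n over m ∈ [0, u]; spanning reads contribute
π·f(m|n), flanking and in-repeat reads the tail π·Σ_{k=m..u} f(k|n).
Defaults p = 0.97 and s = 5 are taken as given (pedigree-tuned upstream;
re-tuning is out of scope).  Candidate alleles are the distinct observed
spanning/flanking unit counts plus the stand-in u = ⌊r/|motif|⌋ whenever
IRR evidence exists — not the full grid, which keeps the search small and
ties candidates to observations.  Ties break toward the smaller allele
sum, then lexicographically, so output is deterministic.

**IRR multiplicity is excluded from the argmax.** A count of i IRRs is
explained equally well by one expanded allele of size r + 2i/π or by two
expanded alleles sharing that total — the sizes are free parameters
estimated after the argmax — so the count is ancillary for the
genotype-shape question.  Left in the per-read mixture, every IRR would
add ln 2 of spurious preference for "both alleles expanded" and
eventually outvote the depth-bounded spanning support for a genuine short
allele.  The argmax therefore sees junction reads individually plus one
representative IRR observation (which is what makes u callable at all);
the full count drives the size estimate.  This is the package's own
correction to the plain per-read mixture.

After the argmax: an allele equal to u with IRRs present is replaced by
the binomial IRR size estimate (full expansion length, haplotype-aware
rate, fragment-level CI).  If both alleles equal u, size intervals come
from the extreme splits of the IRR count — 0–50% from the short allele,
50–100% from the long one — each end mapped through N = r + i′/π; the
reported point is the interval midpoint.  Short alleles supported by
spanning reads are exact (degenerate CI); alleles supported only by
flanking reads carry the flanking estimate.

**Labels.** With a pathogenic cutoff c (in units): `expanded` if the long
allele's CI lower bound exceeds c; `gray` if the CI straddles c (lo < c <
hi); `normal` otherwise.  Gray calls are potential expansions and should
be counted positive in any screening sensitivity arithmetic; machine
output always reports them as their own label.

Sample parameters (r, depth) default to local estimates: r is the modal
read length and depth the mean coverage of confidently mapped (MAPQ > 0)
usable primary reads over two 1 kbp windows set back one read length from
the repeat interval.  Local depth is robust to genome-wide coverage
variation; the setback and MAPQ gate matter because aligners pile poorly
mapped repeat reads onto the locus boundary, and letting that pile-up leak
into the depth windows inflates π and systematically deflates every
IRR-based size estimate.  How depth "should" be computed was an open
choice; when the sample's depth is known (as in a controlled sequencing
design) passing it explicitly removes the estimation noise entirely.

## Simulator

The generator emulates the targeted sequencing design: diploid haplotypes
(flank + motif×n + flank with seeded random flanks), fragment starts at a
per-base Bernoulli rate matching the requested depth, fragment lengths
Normal(400, 50) truncated at the read length (the design's 350–450 bp
range), 150 bp (or 100 bp) paired reads from fragment ends, two-point
quality profile (Q30 with a Q10 minority, default 5%), and substitution
errors at lowered-quality bases with a 3× rate multiplier inside the
repeat tract, where real error rates are elevated.  Default depth 45×.
Alignment assignment is either `oracle` (true coordinates, MAPQ 60) or
`decoy` (in-repeat reads MAPQ 0 at the locus; both-IRR pairs one-third
unaligned, the rest MAPQ 0 at configurable decoy contigs), reproducing
aligner behavior for sequence absent from the reference.  Output is
plain-text SAM plus reference FASTA, truth TSV, and a matching catalog.

What the simulator does **not** model: PCR artifacts, GC-dependent
coverage droop (an optional knob exists for robustness tests only, since
the targeted protocol is PCR-free), somatic mosaicism, indel errors, and
alignment reference bias beyond the decoy mechanism.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated sampling model, not robustness to mosaic or PCR-biased libraries;
mosaic expansions in particular would be underestimated.

## Validation experiment sizes

The acceptance experiments use problem sizes chosen to make Monte-Carlo
noise small relative to the tested tolerances while keeping the suite
quick to run: 1000 random triples for scorer/oracle agreement, 200
simulated samples (40×, 150 bp reads, homozygous 2 kb GGCCCC expansion,
800 bp flanks) for estimator recovery and CI coverage, 50 replicates per
genotype for exact short-call recovery (1.2 kb flanks), 10-sample cohorts
for off-target discovery, and 100 random evidence sets for genotyper
enumeration equivalence.

## Known limitations

* Two alleles both slightly above the read length are intrinsically hard
  to separate; the both-expanded split intervals are crude extremes, and
  a flanking-derived candidate near u may absorb one of them.
* Indel-containing reads are not realigned; they are dropped by the WP
  gate rather than rescued.
* The per-read mixture model carries no expected-count term for spanning
  reads, so a homozygous short call relies on the candidate set rather
  than on depth consistency.
* Anchored-only mode saturates near the fragment length; reported sizes
  there are lower bounds, as the evidence type in the output indicates.
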