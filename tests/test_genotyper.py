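"""Frequency function, read/genotype likelihoods, ML calling, labels."""

import itertools
import math
import random

import numpy as np
import pytest

from strcall.catalog import ModelParams, RepeatSpec, SampleParams
from strcall.classify import EvidenceKind, ReadEvidence
from strcall.genotyper import (
    CallLabel,
    RepeatCall,
    call_genotype,
    classify_call,
    genotype_likelihood,
    read_likelihood,
    repeat_freq,
    split_both_expanded,
)
from strcall.sizing import EvidenceClass, SizeEstimate

PARAMS = SampleParams(read_length=150, mean_depth=45)  # pi = 0.3
MODEL = ModelParams()
U = 25  # 150 / 6

SPEC = RepeatSpec("g", "chrT", 1000, 1018, "GGCCCC", pathogenic_cutoff_units=30)


def span(m, name="s"):
    return ReadEvidence(name, EvidenceKind.SPANNING, m, 1.0)


def flank(m, name="f"):
    return ReadEvidence(name, EvidenceKind.FLANKING, m, 1.0)


def irr(name="i", m=U):
    return ReadEvidence(name, EvidenceKind.IRR_ANCHORED, m, 1.0)


class TestRepeatFreq:
    @pytest.mark.parametrize("n", [0, 5, 12, 25])
    def test_mode_at_allele_size(self, n):
        values = [repeat_freq(m, n, u=U) for m in range(U + 1)]
        assert max(range(U + 1), key=lambda m: values[m]) == n

    @pytest.mark.parametrize("n", [0, 3, 13, 25])
    def test_normalizes_to_one(self, n):
        assert sum(repeat_freq(m, n, u=U) for m in range(U + 1)) == pytest.approx(1.0)

    def test_deviation_capped_at_s(self):
        n = 5
        r1 = repeat_freq(n + 5, n, u=U) / repeat_freq(n + 4, n, u=U)
        r2 = repeat_freq(n + 7, n, u=U) / repeat_freq(n + 6, n, u=U)
        assert r1 < 1.0
        assert r2 == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            repeat_freq(26, 5, u=U)
        with pytest.raises(ValueError):
            repeat_freq(5, -1, u=U)


class TestReadLikelihood:
    def test_spanning_maximal_at_true_allele(self):
        like = [read_likelihood(span(10), n, PARAMS, MODEL, U) for n in range(U + 1)]
        assert np.argmax(like) == 10
        assert like[10] == pytest.approx(PARAMS.pi * repeat_freq(10, 10, u=U))

    def test_flanking_m0_is_total_mass(self):
        assert read_likelihood(flank(0), 7, PARAMS, MODEL, U) == pytest.approx(PARAMS.pi)

    def test_irr_tail_no_more_than_full_sum(self):
        at_u = read_likelihood(irr(), U, PARAMS, MODEL, U)
        full = read_likelihood(flank(0), U, PARAMS, MODEL, U)
        assert at_u <= full

    def test_observed_count_above_u_rejected(self):
        with pytest.raises(ValueError):
            read_likelihood(span(U + 1), 5, PARAMS, MODEL, U)


class TestGenotypeLikelihood:
    def test_homozygous_mixture_collapses(self):
        evs = [span(3, f"s{k}") for k in range(5)]
        hom = genotype_likelihood((3, 3), evs, PARAMS, MODEL, U)
        single = sum(math.log(read_likelihood(e, 3, PARAMS, MODEL, U)) for e in evs)
        assert hom == pytest.approx(single)

    def test_order_invariance(self):
        evs = [span(3), span(5), flank(2), irr()]
        ll = genotype_likelihood((3, U), evs, PARAMS, MODEL, U)
        random.Random(0).shuffle(evs)
        assert genotype_likelihood((3, U), evs, PARAMS, MODEL, U) == pytest.approx(ll)

    def test_empty_evidence_sentinel(self):
        assert genotype_likelihood((3, 5), [], PARAMS, MODEL, U) is None

    def test_two_spanning_clusters_call_distinct_alleles(self):
        evs = [span(3, f"a{k}") for k in range(10)] + [span(5, f"b{k}") for k in range(10)]
        grid = itertools.combinations_with_replacement(range(U + 1), 2)
        best = max(grid, key=lambda g: genotype_likelihood(g, evs, PARAMS, MODEL, U))
        assert best == (3, 5)


class TestCallGenotype:
    def test_homozygous_short(self):
        evs = [span(2, f"s{k}") for k in range(38)]
        call = call_genotype(evs, SPEC, SampleParams(150, 44), seed=0)
        assert call.ml_genotype == (2, 2)
        assert call.label is CallLabel.NORMAL

    def test_het_short(self):
        evs = [span(3, f"a{k}") for k in range(10)] + [span(5, f"b{k}") for k in range(10)]
        call = call_genotype(evs, SPEC, PARAMS, seed=0)
        assert call.genotype == (3, 5)
        assert [e.evidence for e in call.allele_estimates] == [EvidenceClass.SPANNING] * 2

    def test_single_expansion_uses_irr_estimate(self):
        # ~20 spanning reads of the short allele is depth-consistent at 45x
        evs = [span(3, f"s{k}") for k in range(20)] + [irr(f"i{k}") for k in range(300)]
        call = call_genotype(evs, SPEC, PARAMS, seed=0)
        assert call.ml_genotype == (3, U)
        long = call.long_allele
        # 300 IRRs at haplotype rate pi/2: N = 150 + 300/0.15 = 2150 bp
        assert long.point_bp == pytest.approx(2150.0)
        assert long.ci_lo_units <= long.point_units <= long.ci_hi_units
        assert call.label is CallLabel.EXPANDED

    def test_both_expanded_split_intervals(self):
        evs = [irr(f"i{k}") for k in range(200)]
        call = call_genotype(evs, SPEC, PARAMS, seed=0)
        assert call.ml_genotype == (U, U)
        short, long = call.allele_estimates
        assert short.ci_hi_units >= long.ci_lo_units  # shared 50% boundary
        assert long.ci_hi_units >= long.point_units

    def test_no_evidence_is_no_call(self):
        call = call_genotype([], SPEC, PARAMS)
        assert call.is_no_call
        assert call.no_call_reason

    def test_haploid(self):
        evs = [span(4, f"s{k}") for k in range(12)]
        call = call_genotype(evs, SPEC, PARAMS, ploidy=1, seed=0)
        assert call.genotype == (4,)

    def test_exchangeability(self):
        evs = [span(3), span(7), flank(2), flank(6), irr("i1"), irr("i2")]
        calls = []
        for perm_seed in range(4):
            shuffled = list(evs)
            random.Random(perm_seed).shuffle(shuffled)
            calls.append(call_genotype(shuffled, SPEC, PARAMS, seed=0))
        assert len({c.genotype for c in calls}) == 1
        for c in calls[1:]:
            assert c.log_likelihood == pytest.approx(calls[0].log_likelihood)

    def test_every_call_gets_exactly_one_label(self):
        for evs in ([span(2)], [span(3), span(5)], [irr(f"i{k}") for k in range(50)]):
            call = call_genotype(evs, SPEC, PARAMS, seed=0)
            assert isinstance(call.label, CallLabel)


def oracle_call(evidence, params, model, u, ploidy=2):
    """Naive enumeration with direct probability products (no logs)."""

    def f_direct(m, n):
        weights = [model.p * (1 - model.p) ** min(abs(n - k), s_cap) for k in range(u + 1)]
        return weights[m] / sum(weights)

    s_cap = model.s
    spanning = {e.units_m for e in evidence if e.kind is EvidenceKind.SPANNING}
    flanking = {e.units_m for e in evidence if e.kind is EvidenceKind.FLANKING}
    irrs = [e for e in evidence if e.kind.is_irr]
    cands = sorted(spanning | flanking | ({u} if irrs else set()))
    # same observation rule as the caller: junction reads individually,
    # in-repeat evidence as one representative record
    observed = [e for e in evidence if not e.kind.is_irr] + irrs[:1]
    best, best_key = None, None
    for g in itertools.combinations_with_replacement(cands, ploidy):
        prob = 1.0
        for e in observed:
            per_hap = []
            for n in g:
                if e.kind is EvidenceKind.SPANNING:
                    per_hap.append(params.pi * f_direct(e.units_m, n))
                else:
                    per_hap.append(params.pi * sum(f_direct(k, n) for k in range(e.units_m, u + 1)))
            prob *= sum(per_hap) / len(per_hap)
        key = (prob, -sum(g), tuple(-x for x in g))
        if best_key is None or key > best_key:
            best, best_key = g, key
    return tuple(sorted(best)) if best else None


def test_matches_bruteforce_enumeration_on_random_evidence():
    """ML call equals naive candidate-set enumeration for small problems."""
    rng = random.Random(77)
    spec = RepeatSpec("o", "chrT", 100, 118, "CAG", pathogenic_cutoff_units=30)
    for trial in range(60):
        u = rng.randint(6, 12)
        params = SampleParams(read_length=3 * u, mean_depth=0.3 * 3 * u)
        n_reads = rng.randint(1, 15)
        evidence = []
        for k in range(n_reads):
            kind = rng.choice(
                [EvidenceKind.SPANNING, EvidenceKind.SPANNING, EvidenceKind.FLANKING,
                 EvidenceKind.IRR_ANCHORED]
            )
            m = u if kind is EvidenceKind.IRR_ANCHORED else rng.randint(0, u)
            evidence.append(ReadEvidence(f"r{k}", kind, m, 1.0))
        call = call_genotype(evidence, spec, params, MODEL, n_boot=100, seed=1)
        assert call.ml_genotype == oracle_call(evidence, params, MODEL, u)


class TestSplitBothExpanded:
    def test_zero_count_collapses_to_read_length(self):
        short, long = split_both_expanded(0, PARAMS, 6)
        assert short == (150.0, 150.0)
        assert long == (150.0, 150.0)

    def test_worked_split(self):
        params = SampleParams(read_length=150, mean_depth=37.5)  # pi = 0.25
        short, long = split_both_expanded(100, params, 6)
        assert short == (150.0, 350.0)
        assert long == (350.0, 550.0)

    def test_shared_midpoint(self):
        for i in (1, 17, 256):
            short, long = split_both_expanded(i, PARAMS, 6)
            assert short[1] == long[0]


class TestClassifyCall:
    def _call(self, lo, hi):
        est = SizeEstimate(0, float(hi * 6), hi, lo, hi, EvidenceClass.IRR)
        return RepeatCall((hi,), (est,), {}, None, 0.0)

    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (16, 26, CallLabel.NORMAL),     # just under the cutoff
            (28, 45, CallLabel.GRAY),       # straddles the cutoff
            (40, 200, CallLabel.EXPANDED),  # fully above
            (31, 31, CallLabel.EXPANDED),
            (2, 2, CallLabel.NORMAL),
        ],
    )
    def test_rule(self, lo, hi, expected):
        assert classify_call(self._call(lo, hi), 30) is expected

    def test_no_call_rejected(self):
        with pytest.raises(ValueError):
            classify_call(RepeatCall(None, (), {}, None, None), 30)
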