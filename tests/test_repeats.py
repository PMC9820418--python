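"""Repeat detectors against examples, brute-force oracles, and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitorecomb as m
from mitorecomb.repeats import (
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    repeat_evalue,
)

from .conftest import random_seq
from .oracles import (
    detector_pairs_as_set,
    oracle_dispersed,
    oracle_no_tandem,
    oracle_ssrs,
)


def _ssr_set(records):
    return {(r.motif, r.copies, r.start, r.end) for r in records}


class TestSSRs:
    def test_mono_run_forced_by_threshold(self):
        recs = find_ssrs("CC" + "A" * 12 + "GG")
        assert _ssr_set(recs) == {("A", 12, 3, 14)}

    def test_dimer_ta_run(self):
        recs = find_ssrs("GCGT" + "TA" * 7 + "GGC", {2: 5})
        assert _ssr_set(recs) == {("TA", 7, 5, 18)}

    def test_empty_sequence(self):
        assert find_ssrs("") == []

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_exhaustive_oracle_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 2000)
        # lowered thresholds so random sequence produces hits to compare
        thresholds = {1: 5, 2: 3, 3: 2, 4: 2, 5: 2, 6: 2}
        assert _ssr_set(find_ssrs(seq, thresholds)) == oracle_ssrs(seq, thresholds)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=80))
    def test_matches_oracle_property(self, seq):
        thresholds = {1: 4, 2: 3, 3: 2, 4: 2, 5: 2, 6: 2}
        assert _ssr_set(find_ssrs(seq, thresholds)) == oracle_ssrs(seq, thresholds)

    def test_circular_run_spanning_origin_reported_wrapped(self):
        rng = np.random.default_rng(8)
        body = random_seq(rng, 300)
        seq = "A" * 6 + body + "A" * 6  # A12 run across the origin
        recs = find_ssrs(seq, circular=True)
        wrapped = [r for r in recs if r.wrapped]
        assert len(wrapped) == 1
        rec = wrapped[0]
        assert rec.motif == "A" and rec.copies >= 12
        assert rec.end > len(seq) >= rec.start


class TestTandemRepeats:
    def test_perfect_three_copy_array(self):
        recs = find_tandem_repeats("ACGTG" * 3, 5, 27, 80.0, min_array_length=10)
        assert len(recs) == 1
        rec = recs[0]
        assert (rec.unit_length, rec.copy_number, rec.percent_matches) == (5, 3.0, 100.0)

    def test_planted_imperfect_array_detected_in_published_similarity_regime(self):
        spec = m.GenomeSpec(
            [2000], planted_tandems=[m.TandemPlan(20, 3, 2, 0, 501)], seed=3
        )
        seqs, truth = m.generate_genome(spec)
        recs = find_tandem_repeats(seqs["chr1"], 15, 27, 78.0)
        assert len(recs) == 1
        rec = recs[0]
        assert 78.0 <= rec.percent_matches <= 97.0
        row = truth[truth.feature_class == "tandem"].iloc[0]
        assert (rec.start, rec.end) == (row.start, row.end)

    @pytest.mark.parametrize("seed", [4, 5])
    def test_absence_on_random_sequence_confirmed_by_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 120)
        args = dict(min_period=15, max_period=20, min_percent=84.0,
                    min_array_length=30)
        assert find_tandem_repeats(seq, **args) == []
        assert oracle_no_tandem(seq, 15, 20, 84.0, 30)

    def test_invalid_period_range_rejected(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("ACGT" * 10, 1, 5)


class TestDispersedRepeats:
    def test_exact_forward_pair(self):
        spec = m.GenomeSpec(
            [600],
            planted_repeats=[m.RepeatPlan(40, 0, "direct", (0, 201), (0, 441), "F")],
            seed=31,
        )
        seqs, _ = m.generate_genome(spec)
        pairs = [p for p in find_dispersed_repeats(seqs) if p.length >= 40]
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.length, p.identity, p.type) == (40, 100.0, "forward")
        assert (p.start_1, p.start_2) == (201, 441)

    def test_exact_palindromic_pair(self):
        spec = m.GenomeSpec(
            [500],
            planted_repeats=[m.RepeatPlan(40, 0, "inverted", (0, 151), (0, 341), "P")],
            seed=32,
        )
        seqs, _ = m.generate_genome(spec)
        pairs = [p for p in find_dispersed_repeats(seqs) if p.length >= 40]
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.length, p.identity, p.type) == (40, 100.0, "palindromic")
        assert (p.start_1, p.start_2) == (151, 341)

    def test_planted_published_pair_identity(self):
        """137 bp direct pair with 12 substitutions reports 91.24% identity."""
        spec = m.GenomeSpec(
            [8000],
            planted_repeats=[m.RepeatPlan(137, 12, "direct", (0, 2001), (0, 5001), "R4")],
            seed=1,
        )
        seqs, _ = m.generate_genome(spec)
        hits = [
            p for p in find_dispersed_repeats(seqs)
            if (p.start_1, p.start_2) == (2001, 5001)
        ]
        assert len(hits) == 1
        assert hits[0].length == 137
        assert hits[0].identity == 91.24

    @pytest.mark.parametrize("seed", [41, 42, 43])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        block = random_seq(rng, 45)
        mutated = list(block)
        for pos in (12, 22, 33):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        seq = (
            random_seq(rng, 150) + block + random_seq(rng, 120)
            + "".join(mutated) + random_seq(rng, 80) + m.revcomp(block)
            + random_seq(rng, 60)
        )
        seqs = {"chr1": seq, "chr2": random_seq(rng, 300) + block + random_seq(rng, 50)}
        got = detector_pairs_as_set(find_dispersed_repeats(seqs))
        assert got == oracle_dispersed(seqs)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(51)
        block = random_seq(rng, 60)
        seq = (random_seq(rng, 120) + block + random_seq(rng, 90)
               + m.revcomp(block) + random_seq(rng, 130) + block)
        n = len(seq)
        fwd = find_dispersed_repeats(seq)
        rev = find_dispersed_repeats(m.revcomp(seq))

        def mapped(pairs):
            out = set()
            for p in pairs:
                iv1 = (n - p.end_1 + 1, n - p.start_1 + 1)
                iv2 = (n - p.end_2 + 1, n - p.start_2 + 1)
                lo, hi = sorted([iv1, iv2])
                out.add((lo, hi, p.length, p.type, p.matches))
            return out

        direct = {
            (tuple(sorted([(p.start_1, p.end_1), (p.start_2, p.end_2)])[0]),
             tuple(sorted([(p.start_1, p.end_1), (p.start_2, p.end_2)])[1]),
             p.length, p.type, p.matches)
            for p in fwd
        }
        assert mapped(rev) == direct

    def test_planted_pairs_recovered_at_exact_truth_coordinates(self, paper_topology):
        truth = paper_topology["truth"]
        pairs = find_dispersed_repeats(paper_topology["seqs"])
        by_coords = {
            (p.chromosome_1, p.start_1, p.end_1): p for p in pairs
        } | {(p.chromosome_2, p.start_2, p.end_2): p for p in pairs}
        planted = truth[truth.feature_class == "repeat_pair"]
        for _, row in planted.iterrows():
            assert (row.chromosome, row.start, row.end) in by_coords

    def test_anchor_larger_than_min_length_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            find_dispersed_repeats("ACGT" * 100, min_length=10, anchor_k=13)


class TestEvalue:
    def test_closed_form_unit_case(self):
        assert repeat_evalue(30, 4**15) == pytest.approx(1.0)

    def test_monotone_decreasing_in_length(self):
        vals = [repeat_evalue(L, 406_009) for L in (30, 60, 120, 500, 5000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == 0.0  # underflows to the printed 0

    def test_doubles_when_genome_grows_by_sqrt2(self):
        n = 406_009
        ratio = repeat_evalue(40, int(n * math.sqrt(2))) / repeat_evalue(40, n)
        assert ratio == pytest.approx(2.0, rel=1e-4)

    def test_mismatch_correction_factor(self):
        base = repeat_evalue(50, 10**6)
        assert repeat_evalue(50, 10**6, 2) == pytest.approx(base * math.comb(50, 2) * 9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            repeat_evalue(0, 100)
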