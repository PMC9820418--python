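"""MTPT detection, merging, statistics, and gene containment."""

import logging

import numpy as np
import pytest

import mitorecomb as m
from mitorecomb.mtpt import MTPTFragment, RawMatch, merge_fragments, transfer_stats
from mitorecomb.simulate import make_plastid_gff

from .oracles import oracle_union


@pytest.fixture(scope="module")
def transfer_genome():
    spec = m.GenomeSpec(
        [30000],
        planted_transfers=[
            m.TransferPlan(0, 5000, 6577, 2001, 0),   # 1,578 bp
            m.TransferPlan(0, 10000, 10499, 6001, 0),
            m.TransferPlan(0, 15000, 15299, 8001, 0),
            m.TransferPlan(0, 20000, 20199, 10001, 0),
        ],
        seed=101,
    )
    seqs, _ = m.generate_genome(spec)
    plastid, truth = m.derive_plastid_with_transfers(
        seqs, spec.planted_transfers, 15590, seed=102
    )
    return dict(spec=spec, seqs=seqs, plastid=plastid, truth=truth)


class TestScanHomology:
    def test_verbatim_transfer_found_full_length_full_identity(self, transfer_genome):
        matches = m.scan_homology(transfer_genome["seqs"], transfer_genome["plastid"])
        top = max(matches, key=lambda x: x.length)
        assert (top.length, top.identity) == (1578, 100.0)
        assert (top.mito_start, top.mito_end) == (5000, 6577)

    def test_unrelated_random_genomes_share_nothing(self):
        a, _ = m.generate_genome(m.GenomeSpec([20000], seed=111))
        b, _ = m.generate_genome(m.GenomeSpec([15000], seed=112))
        assert m.scan_homology(a, b["chr1"], min_length=100) == []

    def test_diverged_transfer_recovered_with_matching_identity(self):
        spec = m.GenomeSpec(
            [20000],
            planted_transfers=[m.TransferPlan(0, 5001, 6000, 3001, 50)],  # 5% subs
            seed=115,
        )
        seqs, _ = m.generate_genome(spec)
        plastid, _ = m.derive_plastid_with_transfers(
            seqs, spec.planted_transfers, 12000, seed=116
        )
        matches = m.scan_homology(seqs, plastid)
        top = max(matches, key=lambda x: x.length)
        assert 93.0 <= top.identity <= 97.0
        assert abs(top.mito_start - 5001) <= 10 and abs(top.mito_end - 6000) <= 10

    def test_reverse_strand_homology_detected(self, transfer_genome):
        flipped = m.revcomp(transfer_genome["plastid"])
        matches = m.scan_homology(transfer_genome["seqs"], flipped)
        top = max(matches, key=lambda x: x.length)
        assert top.strand == "-"
        assert (top.mito_start, top.mito_end) == (5000, 6577)

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            m.scan_homology({}, "ACGT")


def _match(chrom, s, e, identity=100.0, ps=1):
    return RawMatch(chrom, s, e, ps, ps + (e - s), "+", identity, e - s + 1)


class TestMergeFragments:
    def test_overlapping_intervals_merge(self):
        frags = merge_fragments([_match("chr1", 100, 200), _match("chr1", 150, 300)])
        assert [(f.mito_start, f.mito_end) for f in frags] == [(100, 300)]

    def test_disjoint_intervals_unchanged(self):
        frags = merge_fragments([_match("chr1", 100, 200), _match("chr1", 300, 400)])
        assert len(frags) == 2

    def test_bookended_intervals_merge(self):
        frags = merge_fragments([_match("chr1", 100, 200), _match("chr1", 201, 300)])
        assert [(f.mito_start, f.mito_end) for f in frags] == [(100, 300)]

    def test_identity_is_length_weighted_mean(self):
        frags = merge_fragments(
            [_match("chr1", 1, 100, identity=100.0), _match("chr1", 101, 400, identity=80.0)]
        )
        assert frags[0].identity == pytest.approx(85.0)

    def test_thousand_random_intervals_match_bitmap_oracle(self):
        rng = np.random.default_rng(120)
        intervals = []
        for _ in range(1000):
            s = int(rng.integers(1, 9000))
            intervals.append((s, s + int(rng.integers(0, 500))))
        frags = merge_fragments([_match("chr1", s, e) for s, e in intervals])
        assert [(f.mito_start, f.mito_end) for f in frags] == oracle_union(intervals, 10000)

    def test_merging_is_idempotent(self):
        rng = np.random.default_rng(121)
        matches = [
            _match("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(1, 5000, 200), rng.integers(0, 300, 200))
        ]
        once = merge_fragments(matches)
        again = merge_fragments(
            [
                RawMatch(f.mito_chromosome, f.mito_start, f.mito_end, f.plastid_start,
                         f.plastid_end, f.strand, f.identity, f.length)
                for f in once
            ]
        )
        assert [(f.mito_start, f.mito_end) for f in again] == [
            (f.mito_start, f.mito_end) for f in once
        ]


class TestTransferStats:
    def test_published_fraction_arithmetic(self):
        """23,747 transferred bases on a 406,009 bp mitogenome -> 5.85%."""
        frags = [
            MTPTFragment("chr1", 1, 1578, 1, 1578, "+", 100.0, 1578),
            MTPTFragment("chr1", 3000, 3000 + 22169 - 1, 1, 22169, "+", 100.0, 22169),
        ]
        stats = transfer_stats(frags, 406_009)
        assert stats.total_length == 23_747
        assert stats.fraction_percent == 5.85
        assert stats.longest == 22_169

    def test_empty_fragment_list(self):
        stats = transfer_stats([], 1000)
        assert (stats.fragment_count, stats.total_length, stats.fraction_percent) == (0, 0, 0.0)

    def test_full_coverage_is_one_hundred_percent(self):
        frags = [MTPTFragment("chr1", 1, 1000, 1, 1000, "+", 100.0, 1000)]
        assert transfer_stats(frags, 1000).fraction_percent == 100.00

    def test_stats_consistency_with_emitted_fragments(self, transfer_genome):
        matches = m.scan_homology(transfer_genome["seqs"], transfer_genome["plastid"])
        frags = m.merge_fragments(matches)
        stats = m.transfer_stats(frags, 30000)
        assert stats.total_length == sum(f.length for f in frags)
        assert stats.fraction_percent == round(100.0 * stats.total_length / 30000, 2)

    def test_zero_length_genome_rejected(self):
        with pytest.raises(ValueError):
            transfer_stats([], 0)


class TestAnnotateTransfers:
    def _frag(self, ps, pe):
        return MTPTFragment("chr1", 1, pe - ps + 1, ps, pe, "+", 100.0, pe - ps + 1)

    def test_gene_fully_inside_fragment_reported(self):
        gff = ("##gff-version 3\n"
               "plastid\tx\tgene\t1100\t1169\t.\t+\t.\tID=g1;Name=petN\n")
        out = m.annotate_transfers([self._frag(1000, 2000)], gff)
        assert out[0].genes == ["petN"]

    def test_gene_overlapping_boundary_by_one_base_excluded(self):
        gff = ("##gff-version 3\n"
               "plastid\tx\tgene\t1950\t2001\t.\t+\t.\tID=g1;Name=edge\n")
        out = m.annotate_transfers([self._frag(1000, 2000)], gff)
        assert out[0].genes == []

    def test_malformed_rows_skipped_with_warning(self, caplog):
        gff = ("##gff-version 3\n"
               "badline with no tabs\n"
               "plastid\tx\tgene\t1100\t1169\t.\t+\t.\tID=g1;Name=ok\n")
        with caplog.at_level(logging.WARNING):
            out = m.annotate_transfers([self._frag(1000, 2000)], gff)
        assert out[0].genes == ["ok"]
        assert any("malformed" in r.message for r in caplog.records)

    def test_exactly_the_fully_contained_planted_genes_reported(self, transfer_genome):
        """Eight genes planted inside transfers, four straddling boundaries:
        exactly the eight complete ones are reported."""
        gff = make_plastid_gff(
            transfer_genome["truth"], inside_per_fragment=2, n_boundary=4
        )
        assert gff.count("\tgene\t") == 12
        matches = m.scan_homology(transfer_genome["seqs"], transfer_genome["plastid"])
        frags = m.merge_fragments(matches)
        annotated = m.annotate_transfers(frags, gff)
        genes = sorted(g for f in annotated for g in f.genes)
        assert len(genes) == 8
        assert all(not g.startswith("bgene") for g in genes)
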