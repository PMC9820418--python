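"""Conformation algebra: templates, events, canonical keys, enumeration."""

import numpy as np
import pytest

import mitorecomb as m
from mitorecomb.recombination import total_bases

from .conftest import random_seq


def canonical_circular_strings(seqs: list[str]) -> tuple:
    """Sequence-level canonical form: per circle, the lexicographic minimum
    over all rotations of the string and of its reverse complement."""

    def canon(s):
        d = s + s
        best = min(d[i : i + len(s)] for i in range(len(s)))
        r = m.revcomp(s)
        dr = r + r
        return min(best, min(dr[i : i + len(s)] for i in range(len(s))))

    return tuple(sorted(canon(s) for s in seqs))


class TestTemplates:
    def test_template_length_arithmetic(self, two_circle_genome):
        q = m.build_templates(two_circle_genome["seqs"], two_circle_genome["pair"], 1000)
        assert [len(t) for t in q.templates().values()] == [2360] * 4
        assert not q.unresolvable

    def test_swap_is_ref_prefix_plus_other_ref_suffix(self, two_circle_genome):
        q = m.build_templates(two_circle_genome["seqs"], two_circle_genome["pair"], 1000)
        L = 360
        assert q.swap_1 == q.ref_1[: 1000 + L] + q.ref_2[-1000:]
        assert q.swap_2 == q.ref_2[: 1000 + L] + q.ref_1[-1000:]

    def test_identical_flanks_flagged_unresolvable(self):
        rng = np.random.default_rng(61)
        flank_u, repeat, flank_d = (random_seq(rng, x) for x in (1000, 100, 1000))
        seqs = {
            "chr1": flank_u + repeat + flank_d + random_seq(rng, 2000),
            "chr2": flank_u + repeat + flank_d + random_seq(rng, 1500),
        }
        pair = m.RepeatPair("X", 100, 100.0, "direct",
                            ("chr1", 1001, 1100), ("chr2", 1001, 1100))
        assert m.build_templates(seqs, pair, 1000).unresolvable

    def test_flanks_wrap_across_the_circular_origin(self):
        rng = np.random.default_rng(62)
        seq = random_seq(rng, 5000)
        # copy 1 starts 200 bp after the origin: upstream flank must wrap
        pair = m.RepeatPair("W", 100, 100.0, "direct",
                            ("chr1", 201, 300), ("chr1", 3001, 3100))
        q = m.build_templates({"chr1": seq}, pair, 1000)
        assert q.ref_1[:1000] == seq[-800:] + seq[:200]

    def test_copies_within_flank_distance_rejected(self, two_circle_genome):
        pair = m.RepeatPair("Y", 360, 100.0, "direct",
                            ("chr1", 4001, 4360), ("chr1", 4500, 4859))
        with pytest.raises(ValueError, match="share sequence"):
            m.build_templates(two_circle_genome["seqs"], pair, 1000)


class TestEvents:
    def test_cross_circle_fusion_yields_one_circle(self, two_circle_genome):
        fused = m.apply_recombination(
            two_circle_genome["major"], "RP", two_circle_genome["segments"]
        )
        assert len(fused.circles) == 1
        assert fused.event_path[-1].mode == "fusion"

    def test_same_circle_fission_yields_three_circles(self, paper_topology):
        out = m.apply_recombination(
            paper_topology["major"], "R4", paper_topology["segments"]
        )
        assert len(out.circles) == 3
        assert out.event_path[-1].mode == "fission"

    def test_every_event_is_an_involution(self, paper_topology):
        major, segs = paper_topology["major"], paper_topology["segments"]
        key = m.canonical_key(major)
        for pid in ("R1", "R2", "R3", "R4"):
            once = m.apply_recombination(major, pid, segs)
            twice = m.apply_recombination(once, pid, segs)
            assert m.canonical_key(twice) == key

    def test_circle_count_parity_and_base_conservation(self, paper_topology):
        major, segs = paper_topology["major"], paper_topology["segments"]
        base_total = total_bases(major, segs)
        expected_delta = {"fusion": -1, "fission": 1, "inversion": 0}
        frontier = [major]
        for _ in range(2):
            nxt = []
            for conf in frontier:
                for pid in ("R1", "R2", "R3", "R4"):
                    mode = m.derive_mode(conf, pid, segs)
                    out = m.apply_recombination(conf, pid, segs)
                    assert len(out.circles) - len(conf.circles) == expected_delta[mode]
                    assert total_bases(out, segs) == base_total
                    nxt.append(out)
            frontier = nxt[:3]

    def test_inversion_reverses_intervening_block_at_sequence_level(self):
        spec = m.GenomeSpec(
            [9000],
            planted_repeats=[m.RepeatPlan(300, 0, "inverted", (0, 2001), (0, 6001), "RI")],
            seed=6,
        )
        seqs, _ = m.generate_genome(spec)
        pair = m.RepeatPair("RI", 300, 100.0, "inverted",
                            ("chr1", 2001, 2300), ("chr1", 6001, 6300))
        major, segs = m.segment_genome(seqs, [pair])
        inv = m.apply_recombination(major, "RI", segs)
        assert len(inv.circles) == 1
        assert inv.event_path[-1].mode == "inversion"
        s = seqs["chr1"]
        expected = s[:2300] + m.revcomp(s[2300:6000]) + s[6000:]
        got = m.realize_conformation(inv, segs)
        assert canonical_circular_strings(got) == canonical_circular_strings([expected])

    def test_unknown_pair_rejected(self, two_circle_genome):
        with pytest.raises(ValueError, match="expected 2 copies"):
            m.apply_recombination(
                two_circle_genome["major"], "nope", two_circle_genome["segments"]
            )


class TestCanonicalKey:
    def test_invariant_under_rotation_and_flip(self, paper_topology):
        major = paper_topology["major"]
        key = m.canonical_key(major)
        rotated = m.Conformation(
            circles=[c[3:] + c[:3] for c in major.circles], label="r"
        )
        assert m.canonical_key(rotated) == key
        flipped = m.Conformation(
            circles=[tuple((sid, -o) for sid, o in reversed(c)) for c in major.circles],
            label="f",
        )
        assert m.canonical_key(flipped) == key

    def test_key_equality_matches_circular_string_equality(self, paper_topology):
        """Random event walks agree with brute-force circular-string identity."""
        major, segs = paper_topology["major"], paper_topology["segments"]
        rng = np.random.default_rng(99)
        pids = ["R1", "R2", "R3", "R4"]
        confs = [major]
        for _ in range(50):
            base = confs[int(rng.integers(0, len(confs)))]
            conf = m.apply_recombination(base, pids[int(rng.integers(0, 4))], segs)
            confs.append(conf)
        keys = [m.canonical_key(c, segs) for c in confs]
        strings = [
            canonical_circular_strings(m.realize_conformation(c, segs)) for c in confs
        ]
        for a in range(len(confs)):
            for b in range(a + 1, len(confs)):
                assert (keys[a] == keys[b]) == (strings[a] == strings[b])


class TestEnumeration:
    def test_no_events_returns_major_only(self, paper_topology):
        out = m.enumerate_conformations(
            paper_topology["major"], [], paper_topology["segments"]
        )
        assert [c.label for c in out] == ["major"]

    def test_published_event_set_yields_five_minors(self, paper_topology):
        out = m.enumerate_conformations(
            paper_topology["major"], paper_topology["plans"], paper_topology["segments"]
        )
        assert len(out) == 6
        assert out[0].label == "major"
        labels = [c.label for c in out[1:]]
        assert labels == [f"minor-{k}" for k in range(1, 6)]
        by_path = {
            tuple((e.pair_id, e.mode) for e in c.event_path): len(c.circles)
            for c in out
        }
        assert by_path == {
            (): 2,
            (("R1", "fusion"),): 1,
            (("R1", "fusion"), ("R2", "inversion")): 1,
            (("R3", "fusion"),): 1,
            (("R3", "fusion"), ("R2", "inversion")): 1,
            (("R4", "fission"),): 3,
        }

    def test_single_cross_circle_direct_pair_yields_one_minor(self, two_circle_genome):
        out = m.enumerate_conformations(
            two_circle_genome["major"],
            [m.EventPlan("RP")],
            two_circle_genome["segments"],
        )
        assert len(out) == 2
        assert len(out[1].circles) == 1

    def test_enumeration_is_deterministic(self, paper_topology):
        a = m.enumerate_conformations(
            paper_topology["major"], paper_topology["plans"], paper_topology["segments"]
        )
        b = m.enumerate_conformations(
            paper_topology["major"], paper_topology["plans"], paper_topology["segments"]
        )
        assert [m.canonical_key(c) for c in a] == [m.canonical_key(c) for c in b]
        assert [c.label for c in a] == [c.label for c in b]
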