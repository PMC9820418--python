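"""Shared fixtures: small synthetic genomes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import mitorecomb as m


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.44) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


@pytest.fixture(scope="session")
def two_circle_genome():
    """Two small circles with one 360 bp direct cross-circle repeat pair."""
    spec = m.GenomeSpec(
        chromosome_lengths=[10000, 10000],
        planted_repeats=[
            m.RepeatPlan(360, 0, "direct", (0, 4001), (1, 4001), pair_id="RP")
        ],
        seed=11,
    )
    seqs, truth = m.generate_genome(spec)
    pair = m.RepeatPair(
        "RP", 360, 100.0, "direct", ("chr1", 4001, 4360), ("chr2", 4001, 4360)
    )
    major, segments = m.segment_genome(seqs, [pair])
    return dict(spec=spec, seqs=seqs, truth=truth, pair=pair,
                major=major, segments=segments)


@pytest.fixture(scope="session")
def paper_topology():
    """Synthetic replica of the published two-circle repeat topology:
    R1/R3 direct cross-circle, R4 direct same-circle, R2 inverted
    cross-circle; scaled chromosome lengths."""
    from mitorecomb.pipeline import _parse_genome_spec, paper_like_config, truth_repeat_pairs

    cfg = paper_like_config(seed=7)
    spec = _parse_genome_spec(cfg.synthetic, 7)
    seqs, truth = m.generate_genome(spec)
    pairs = truth_repeat_pairs(spec)
    major, segments = m.segment_genome(seqs, pairs)
    plans = [
        m.EventPlan("R1", "fusion", from_major_only=True),
        m.EventPlan("R3", "fusion", from_major_only=True),
        m.EventPlan("R4", "fission", from_major_only=True),
        m.EventPlan("R2", "inversion"),
    ]
    return dict(cfg=cfg, spec=spec, seqs=seqs, truth=truth, pairs=pairs,
                major=major, segments=segments, plans=plans)
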