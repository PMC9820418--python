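"""Shared ungapped local-alignment engine.

Similar interval pairs -- within one sequence, between sequences, or against
a reverse complement -- are found by seed-and-extend: exact k-mer anchors
select candidate diagonals, and each anchored diagonal is decomposed into
locally optimal ungapped alignments under integer scoring (match +1,
mismatch -penalty).  Reported segments are the maximal-scoring subsequences
of the diagonal score series: the highest-scoring segment is extracted
first and the flanking regions are decomposed recursively (the classic
divide-and-conquer characterisation of Ruzzo-Tompa maximal subsequences).
A positive score forces the mismatch fraction below 1/(penalty+1), so the
penalty encodes the identity floor.

The decomposition is computed inside windows around anchor clusters; window
padding is chosen so that a reportable segment cannot extend past its
anchors by more than the pad (every k bases beyond the last exact k-run
carry at least one mismatch), and windows are re-expanded whenever a
substantial segment touches a window edge.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (ACGTN, case preserved)."""
    return seq.translate(_COMP)[::-1]


def identity_penalty(max_mismatch_fraction: float) -> int:
    """Integer mismatch penalty enforcing the given mismatch-fraction ceiling.

    With match +1 / mismatch -p, a positive-score segment has mismatch
    fraction < 1/(p+1); p = ceil((1-f)/f) guarantees 1/(p+1) <= f.
    """
    f = float(max_mismatch_fraction)
    if not 0.0 < f < 1.0:
        raise ValueError(f"mismatch fraction must be in (0, 1), got {f}")
    return max(1, math.ceil((1.0 - f) / f))


def guaranteed_anchor_k(min_len: int, penalty: int, cap: int = 13) -> int:
    """Largest anchor size that cannot miss a reportable segment.

    Any positive-score segment of length L with m mismatches contains an
    exact run of at least ceil((L-m)/(m+1)) bases (pigeonhole); the minimum
    of that bound over admissible (L, m) is the safe seed size.
    """
    best = penalty  # asymptotic bound for large L
    for length in range(min_len, max(8 * min_len, 400)):
        m_max = (length - 1) // (penalty + 1)
        best = min(best, math.ceil((length - m_max) / (m_max + 1)))
    return max(4, min(best, cap))


def _best_segment(pref: np.ndarray, lo: int, hi: int) -> tuple[int, int, int]:
    """Highest-scoring segment of scores[lo:hi] given score prefix sums.

    Ties resolved by smallest start, then largest end.  Returns
    (start, end_exclusive, score); score <= 0 means no positive segment.
    """
    seg = pref[lo : hi + 1]
    mins = np.minimum.accumulate(seg[:-1])
    vals = seg[1:] - mins
    best = int(vals.max())
    if best <= 0:
        return lo, lo, 0
    cand = np.flatnonzero(vals == best)
    bs = be = -1
    for e_rel in cand:
        s_rel = int(np.argmin(seg[: e_rel + 1]))  # first occurrence -> smallest s
        if bs < 0 or s_rel < bs or (s_rel == bs and e_rel + 1 > be):
            bs, be = s_rel, int(e_rel) + 1
    return lo + bs, lo + be, best


def maximal_scoring_segments(
    match: np.ndarray, penalty: int, prune_len: int = 1
) -> list[tuple[int, int, int]]:
    """Decompose a boolean match vector into maximal-scoring segments.

    Returns (start, end_exclusive, score) triples in no particular order;
    regions shorter than prune_len are not explored.
    """
    scores = np.where(match, np.int64(1), np.int64(-penalty))
    pref = np.concatenate(([np.int64(0)], np.cumsum(scores)))
    out: list[tuple[int, int, int]] = []
    stack = [(0, match.size)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < max(1, prune_len):
            continue
        s, e, score = _best_segment(pref, lo, hi)
        if score <= 0:
            continue
        out.append((s, e, score))
        stack.append((lo, s))
        stack.append((e, hi))
    return out


def _clusters(positions: list[int], gap: int) -> list[tuple[int, int]]:
    positions = sorted(positions)
    spans = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p - prev > gap:
            spans.append((start, prev))
            start = p
        prev = p
    spans.append((start, prev))
    return spans


def ungapped_local_alignments(
    seq_a: str,
    seq_b: str,
    *,
    min_len: int,
    penalty: int,
    anchor_k: int,
    self_forward: bool = False,
) -> list[tuple[int, int, int, int]]:
    """All maximal ungapped local alignments between two sequences.

    Returns (start_a, start_b, length, matches) tuples, 0-based, in the
    frames of the sequences as given (the caller maps reverse-complement
    frames back to plus-strand coordinates).  With ``self_forward`` the two
    sequences are the same molecule and only diagonals with start_a <
    start_b are scanned, which drops the trivial self-match and strand
    duplicates.
    """
    if anchor_k > min_len:
        raise ValueError(f"anchor size {anchor_k} exceeds minimum length {min_len}")
    la, lb = len(seq_a), len(seq_b)
    if la < anchor_k or lb < anchor_k:
        return []
    a_arr = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)
    b_arr = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)

    index: dict[str, list[int]] = defaultdict(list)
    for j in range(lb - anchor_k + 1):
        index[seq_b[j : j + anchor_k]].append(j)

    by_diag: dict[int, list[int]] = defaultdict(list)
    for i in range(la - anchor_k + 1):
        hits = index.get(seq_a[i : i + anchor_k])
        if not hits:
            continue
        for j in hits:
            d = j - i
            if self_forward and d <= 0:
                continue
            by_diag[d].append(i)

    pad = (penalty + 1) * anchor_k + 2 * min_len
    prune = min(min_len, anchor_k)
    # quick reject: a reportable segment has non-negative prefix scores, so
    # its first min_len bases carry at least this many matches
    need = math.ceil(min_len * penalty / (penalty + 1))
    kernel = np.ones(min_len, dtype=np.int32)
    out: list[tuple[int, int, int, int]] = []
    for d, anchors in by_diag.items():
        lo_lim = max(0, -d)
        hi_lim = min(la, lb - d)
        seen: set[tuple[int, int]] = set()
        for c0, c1 in _clusters(anchors, gap=2 * pad):
            w0 = max(lo_lim, c0 - pad)
            w1 = min(hi_lim, c1 + anchor_k + pad)
            m = a_arr[w0:w1] == b_arr[w0 + d : w1 + d]
            if m.size < min_len:
                continue
            dense = np.convolve(m.astype(np.int32), kernel, mode="valid")
            if int(dense.max()) < need:
                continue
            while True:
                m = a_arr[w0:w1] == b_arr[w0 + d : w1 + d]
                segs = maximal_scoring_segments(m, penalty, prune)
                grow = False
                for s, e, score in segs:
                    if score >= anchor_k and (
                        (s == 0 and w0 > lo_lim) or (e == w1 - w0 and w1 < hi_lim)
                    ):
                        grow = True
                        break
                if not grow:
                    break
                w0 = max(lo_lim, w0 - 2 * pad)
                w1 = min(hi_lim, w1 + 2 * pad)
            mpref = np.concatenate(([0], np.cumsum(m.astype(np.int64))))
            for s, e, _score in segs:
                if e - s < min_len:
                    continue
                key = (w0 + s, e - s)
                if key in seen:
                    continue
                seen.add(key)
                out.append((w0 + s, w0 + s + d, e - s, int(mpref[e] - mpref[s])))
    return out
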