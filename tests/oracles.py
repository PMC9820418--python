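"""Independent brute-force oracles used to validate the detectors.

Everything here is written from the definitions, in plain Python, without
reusing the package's seed-and-extend machinery: SSRs are enumerated by
testing every motif at every position, dispersed-repeat alignments by
decomposing every diagonal of the full comparison matrix, interval unions
by per-base bitmaps.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# SSRs


def oracle_ssrs(seq: str, thresholds: dict[int, int]) -> set[tuple]:
    """Every maximal perfect run of a primitive 1-6 bp motif, brute force.

    Returns {(motif, copies, start_1based, end_1based)}.
    """
    n = len(seq)
    found = set()
    for p in range(1, 7):
        thr = thresholds.get(p)
        if thr is None:
            continue
        for i in range(n - p + 1):
            motif = seq[i : i + p]
            # primitive motif only
            if any(p % d == 0 and motif[:d] * (p // d) == motif for d in range(1, p)):
                continue
            # leftmost phase of the maximal tract
            if i >= 1 and i - 1 + p < n and seq[i - 1] == seq[i - 1 + p]:
                continue
            copies = 1
            while seq[i + copies * p : i + (copies + 1) * p] == motif:
                copies += 1
            if copies >= thr:
                found.add((motif, copies, i + 1, i + copies * p))
    return found


# ---------------------------------------------------------------------------
# dispersed repeats


def _best_segment(pref: list[int], lo: int, hi: int) -> tuple[int, int, int]:
    bv, bs, be = 0, -1, -1
    minv, mins = pref[lo], lo
    for e in range(lo + 1, hi + 1):
        v = pref[e] - minv
        if v > bv:
            bv, bs, be = v, mins, e
        elif v == bv and bv > 0 and (mins < bs or (mins == bs and e > be)):
            bs, be = mins, e
        if pref[e] < minv:
            minv, mins = pref[e], e
    return bs, be, bv


def _segments(matches: list[bool], penalty: int) -> list[tuple[int, int, int]]:
    pref = [0]
    for x in matches:
        pref.append(pref[-1] + (1 if x else -penalty))
    out = []
    stack = [(0, len(matches))]
    while stack:
        lo, hi = stack.pop()
        if hi <= lo:
            continue
        s, e, v = _best_segment(pref, lo, hi)
        if v <= 0:
            continue
        nmatch = sum(matches[s:e])
        out.append((s, e, nmatch))
        stack.append((lo, s))
        stack.append((e, hi))
    return out


def _diag_alignments(a: str, b: str, min_len: int, penalty: int, self_fwd: bool):
    la, lb = len(a), len(b)
    for d in range(-(lb - 1), la):
        d = -d  # j - i
        if self_fwd and d <= 0:
            continue
        i0, i1 = max(0, -d), min(la, lb - d)
        if i1 - i0 < min_len:
            continue
        matches = [a[i] == b[i + d] for i in range(i0, i1)]
        for s, e, nmatch in _segments(matches, penalty):
            if e - s >= min_len:
                yield (i0 + s, i0 + s + d, e - s, nmatch)


def oracle_dispersed(
    seqs: dict[str, str], min_len: int = 30, max_mismatch_fraction: float = 0.1
) -> set[tuple]:
    """All maximal forward/palindromic pairs, full diagonal sweep.

    Returns {(chrom1, start1, end1, chrom2, start2, end2, type, matches)},
    1-based inclusive, pair order canonical (position_1 <= position_2).
    """
    penalty = math.ceil((1 - max_mismatch_fraction) / max_mismatch_fraction)
    names = list(seqs)
    found = set()

    def emit(c1, i1, c2, i2, length, nmatch, kind):
        if (names.index(c2), i2) < (names.index(c1), i1):
            c1, i1, c2, i2 = c2, i2, c1, i1
        found.add(
            (c1, i1 + 1, i1 + length, c2, i2 + 1, i2 + length, kind, nmatch)
        )

    for ai, a in enumerate(names):
        for i, j, L, nm in _diag_alignments(
            seqs[a], seqs[a], min_len, penalty, self_fwd=True
        ):
            emit(a, i, a, j, L, nm, "forward")
        for b in names[ai + 1 :]:
            for i, j, L, nm in _diag_alignments(
                seqs[a], seqs[b], min_len, penalty, self_fwd=False
            ):
                emit(a, i, b, j, L, nm, "forward")
    for ai, a in enumerate(names):
        la = len(seqs[a])
        for i, j, L, nm in _diag_alignments(
            seqs[a], rc(seqs[a]), min_len, penalty, self_fwd=False
        ):
            i2 = la - j - L
            if i == i2:
                continue
            emit(a, min(i, i2), a, max(i, i2), L, nm, "palindromic")
        for b in names[ai + 1 :]:
            lb = len(seqs[b])
            for i, j, L, nm in _diag_alignments(
                seqs[a], rc(seqs[b]), min_len, penalty, self_fwd=False
            ):
                emit(a, i, b, lb - j - L, L, nm, "palindromic")
    return found


def detector_pairs_as_set(pairs) -> set[tuple]:
    return {
        (p.chromosome_1, p.start_1, p.end_1, p.chromosome_2, p.start_2, p.end_2,
         p.type, p.matches)
        for p in pairs
    }


# ---------------------------------------------------------------------------
# tandem absence


def oracle_no_tandem(
    seq: str, min_period: int, max_period: int, min_percent: float,
    min_array_length: int, min_copies: float = 1.8,
) -> bool:
    """Exhaustively confirm no qualifying tandem array exists (tiny n only)."""
    n = len(seq)
    for p in range(min_period, max_period + 1):
        for s in range(n):
            min_e = s + max(min_array_length, math.ceil(min_copies * p))
            for e in range(min_e, n + 1):
                counts = [dict() for _ in range(p)]
                for k in range(s, e):
                    c = counts[(k - s) % p]
                    c[seq[k]] = c.get(seq[k], 0) + 1
                matches = sum(max(c.values()) for c in counts)
                if 100.0 * matches / (e - s) >= min_percent:
                    return False
    return True


# ---------------------------------------------------------------------------
# interval union


def oracle_union(intervals: list[tuple[int, int]], n: int) -> list[tuple[int, int]]:
    """Per-base bitmap union of 1-based inclusive intervals on [1, n]."""
    mask = [False] * (n + 2)
    for s, e in intervals:
        for k in range(s, e + 1):
            mask[k] = True
    out = []
    k = 1
    while k <= n:
        if mask[k]:
            s = k
            while k <= n and mask[k]:
                k += 1
            out.append((s, k - 1))
        else:
            k += 1
    return out
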