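"""Repeat census: microsatellites, tandem arrays, dispersed repeat pairs.

Three detector families cover the repeat classes routinely reported for
organelle genomes:

* ``find_ssrs`` -- perfect microsatellites (SSRs) with 1-6 bp primitive
  motifs above per-class copy thresholds (MISA-class behaviour);
* ``find_tandem_repeats`` -- imperfect tandem arrays of longer units,
  scored against a column-majority consensus (a simplified tandem-repeat
  finder for the 15-27 bp unit regime);
* ``find_dispersed_repeats`` -- forward and palindromic repeat pairs of at
  least 30 bp, found by seed-and-extend over exact k-mer anchors and
  reported with percent identity and a REPuter-style E-value.

All emitted coordinates are 1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._align import (
    guaranteed_anchor_k,
    identity_penalty,
    maximal_scoring_segments,
    revcomp,
    ungapped_local_alignments,
)

#: copy-number floors per motif class (mono..hexa); common organelle-scale
#: microsatellite settings, fully configurable per call.
DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}

_CLASS_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass
class SSRRecord:
    chromosome: str
    motif: str
    copies: int
    start: int  # 1-based inclusive
    end: int
    motif_class: str
    wrapped: bool = False


@dataclass
class TandemRepeatRecord:
    chromosome: str
    unit_length: int
    copy_number: float
    start: int
    end: int
    unit_consensus: str
    percent_matches: float


@dataclass
class DispersedRepeatPair:
    chromosome_1: str
    start_1: int
    end_1: int
    chromosome_2: str
    start_2: int
    end_2: int
    length: int
    identity: float  # percent, 2 decimals
    type: str  # "forward" | "palindromic"
    e_value: float
    matches: int = 0


# ---------------------------------------------------------------------------
# SSRs


def _is_primitive(motif: str) -> bool:
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif[:d] * (p // d) == motif:
            return False
    return True


def _true_runs(m: np.ndarray) -> list[tuple[int, int]]:
    if not m.any():
        return []
    padded = np.concatenate(([False], m, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _ssrs_linear(sequence: str, thresholds: dict[int, int], chromosome: str) -> list[SSRRecord]:
    n = len(sequence)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    records: list[SSRRecord] = []
    for p in range(1, 7):
        thr = thresholds.get(p)
        if thr is None or n < p * thr:
            continue
        m = arr[:-p] == arr[p:]
        for a, b in _true_runs(m):
            copies = (b - a + p) // p
            if copies < thr:
                continue
            motif = sequence[a : a + p]
            if not _is_primitive(motif):
                continue
            records.append(
                SSRRecord(
                    chromosome=chromosome,
                    motif=motif,
                    copies=copies,
                    start=a + 1,
                    end=a + copies * p,
                    motif_class=_CLASS_NAMES[p],
                )
            )
    records.sort(key=lambda r: (r.start, len(r.motif)))
    return records


def find_ssrs(
    sequence: str,
    thresholds: dict[int, int] | None = None,
    chromosome: str = "chr1",
    circular: bool = False,
) -> list[SSRRecord]:
    """All maximal perfect SSR runs meeting per-class copy thresholds.

    Motifs are reported as their primitive unit at the leftmost phase of
    the maximal tract.  With ``circular`` the sequence is additionally
    scanned rotated by half its length; runs spanning the origin are
    reported in original coordinates with ``end`` exceeding the sequence
    length and ``wrapped`` set, and the partial linear calls they subsume
    are dropped.
    """
    if not sequence:
        return []
    thresholds = dict(thresholds or DEFAULT_SSR_THRESHOLDS)
    records = _ssrs_linear(sequence, thresholds, chromosome)
    if not circular:
        return records
    n = len(sequence)
    h = n // 2
    rotated = sequence[h:] + sequence[:h]
    wrapped: list[SSRRecord] = []
    for rec in _ssrs_linear(rotated, thresholds, chromosome):
        start0 = (rec.start - 1 + h) % n
        end0 = start0 + (rec.end - rec.start)
        if end0 < n:
            continue  # does not span the origin; already in the linear scan
        wrapped.append(
            SSRRecord(chromosome, rec.motif, rec.copies, start0 + 1, end0 + 1,
                      rec.motif_class, wrapped=True)
        )

    def _subsumed(rec: SSRRecord) -> bool:
        for w in wrapped:
            if rec.start >= w.start and rec.end <= w.end:
                return True
            if rec.end <= w.end - n:  # prefix part of the wrapped run
                return True
        return False

    records = [r for r in records if not _subsumed(r)] + wrapped
    records.sort(key=lambda r: (r.start, len(r.motif)))
    return records


# ---------------------------------------------------------------------------
# tandem repeats


def _consensus(sequence: str, start: int, end: int, period: int, phase: int) -> str:
    """Column-majority consensus of sequence[start:end] tiled with the given
    period, columns anchored at ``phase``."""
    counts = [dict() for _ in range(period)]
    for k in range(start, end):
        col = (k - phase) % period
        ch = sequence[k]
        counts[col][ch] = counts[col].get(ch, 0) + 1
    return "".join(
        max(sorted(c), key=lambda ch: c[ch]) if c else "A" for c in counts
    )


def _consensus_matches(sequence: str, start: int, end: int, period: int,
                       phase: int, cons: str) -> int:
    return sum(
        1 for k in range(start, end) if sequence[k] == cons[(k - phase) % period]
    )


def find_tandem_repeats(
    sequence: str,
    min_period: int = 15,
    max_period: int = 27,
    min_percent: float = 78.0,
    min_array_length: int = 30,
    min_copies: float = 1.8,
    chromosome: str = "chr1",
) -> list[TandemRepeatRecord]:
    """Imperfect tandem arrays with unit length in [min_period, max_period].

    Candidate arrays are seeded from self-matches at lag ``period``,
    extended greedily while the period-lag match fraction stays above the
    floor, then re-bounded as the maximal-scoring segment of agreement with
    the column-majority consensus (so boundaries end on consensus-matching
    bases).  Overlapping calls at different periods are resolved by highest
    percent match, then longest array.
    """
    if not 2 <= min_period <= max_period:
        raise ValueError("need 2 <= min_period <= max_period")
    n = len(sequence)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    floor = min_percent / 100.0
    penalty = identity_penalty(1.0 - floor)
    candidates: list[TandemRepeatRecord] = []
    for p in range(min_period, max_period + 1):
        if n < 2 * p:
            continue
        m = (arr[:-p] == arr[p:]).astype(np.int32)
        mp = np.concatenate(([0], np.cumsum(m)))

        def frac(i: int, j: int) -> float:
            # period-lag match fraction of array [i, j)
            return (mp[j - p] - mp[i]) / max(1, j - i - p)

        ws = np.convolve(m, np.ones(p, dtype=np.int32), mode="valid")
        seeds = np.flatnonzero(ws >= math.ceil(p * floor))
        if seeds.size == 0:
            continue
        seen: set[tuple[int, int]] = set()
        # one seed per run of consecutive seed positions
        starts = [int(seeds[0])] + [
            int(s) for s, prev in zip(seeds[1:], seeds[:-1]) if s - prev > 1
        ]
        for i0 in starts:
            i, j = i0, min(n, i0 + 2 * p)
            if frac(i, j) < floor:
                continue
            while j < n and frac(i, j + 1) >= floor:
                j += 1
            while i > 0 and frac(i - 1, j) >= floor:
                i -= 1
            cons = _consensus(sequence, i, j, p, i0)
            # re-bound on consensus agreement within a padded window
            w0, w1 = max(0, i - p), min(n, j + p)
            tiled = "".join(cons[(k - i0) % p] for k in range(w0, w1))
            agree = np.frombuffer(tiled.encode("ascii"), dtype=np.uint8) == arr[w0:w1]
            segs = maximal_scoring_segments(agree, penalty, prune_len=p)
            segs = [s for s in segs if w0 + s[0] <= i0 + p and w0 + s[1] >= i0 + p]
            if not segs:
                continue
            s, e, _ = max(segs, key=lambda t: t[2])
            i, j = w0 + s, w0 + e
            if (i, j) in seen:
                continue
            seen.add((i, j))
            length = j - i
            copy_number = length / p
            if length < min_array_length or copy_number < min_copies:
                continue
            cons = _consensus(sequence, i, j, p, i0)
            matches = _consensus_matches(sequence, i, j, p, i0, cons)
            pct = 100.0 * matches / length
            if pct < min_percent:
                continue
            candidates.append(
                TandemRepeatRecord(
                    chromosome=chromosome,
                    unit_length=p,
                    copy_number=round(copy_number, 2),
                    start=i + 1,
                    end=j,
                    unit_consensus=cons,
                    percent_matches=round(pct, 2),
                )
            )
    # resolve overlaps: highest percent, then longest array
    candidates.sort(
        key=lambda r: (-r.percent_matches, -(r.end - r.start), r.start, r.unit_length)
    )
    kept: list[TandemRepeatRecord] = []
    for rec in candidates:
        if all(rec.end < k.start or rec.start > k.end for k in kept):
            kept.append(rec)
    kept.sort(key=lambda r: r.start)
    return kept


# ---------------------------------------------------------------------------
# dispersed repeats


def repeat_evalue(
    alignment_length: int, genome_length: int, mismatches: int = 0
) -> float:
    """Expected chance occurrences of the alignment in a genome of size N.

    REPuter-style model: E = N^2 / 4^L for an exact match of length L,
    multiplied by C(L, m) * 3^m for m mismatches (an approximation for
    imperfect repeats).  Monotonically decreasing in L, increasing in N.
    """
    if alignment_length <= 0 or genome_length <= 0:
        raise ValueError("lengths must be positive")
    L, N, m = alignment_length, genome_length, mismatches
    log_e = 2.0 * math.log(N) - L * math.log(4.0)
    if m:
        log_e += (
            math.lgamma(L + 1) - math.lgamma(m + 1) - math.lgamma(L - m + 1)
            + m * math.log(3.0)
        )
    return math.exp(log_e) if log_e > -700.0 else 0.0


def find_dispersed_repeats(
    sequences: dict[str, str] | str,
    min_length: int = 30,
    orientations: tuple[str, ...] = ("forward", "palindromic"),
    max_mismatch_fraction: float = 0.1,
    anchor_k: int | None = None,
) -> list[DispersedRepeatPair]:
    """Maximal forward/palindromic repeat pairs of at least ``min_length``.

    Seed-and-extend over exact k-mer anchors shared within and between
    chromosomes (and against reverse complements for palindromic pairs);
    extension reports locally optimal ungapped alignments whose mismatch
    fraction is below ``max_mismatch_fraction``.  Self-trivial matches and
    strand/mirror duplicates are excluded; each pair carries percent
    identity (2 decimals) and an E-value.

    ``anchor_k=None`` selects the largest seed that provably cannot miss a
    reportable pair (see :func:`mitorecomb._align.guaranteed_anchor_k`).
    """
    if isinstance(sequences, str):
        sequences = {"chr1": sequences}
    penalty = identity_penalty(max_mismatch_fraction)
    k = anchor_k if anchor_k is not None else guaranteed_anchor_k(min_length, penalty)
    if k > min_length:
        raise ValueError(f"anchor size {k} exceeds min repeat length {min_length}")
    names = list(sequences)
    genome_n = sum(len(s) for s in sequences.values())
    out: list[DispersedRepeatPair] = []

    def emit(c1, i1, c2, i2, length, matches, kind):
        # canonical order: position_1 <= position_2
        if (names.index(c2), i2) < (names.index(c1), i1):
            c1, i1, c2, i2 = c2, i2, c1, i1
        mism = length - matches
        out.append(
            DispersedRepeatPair(
                chromosome_1=c1, start_1=i1 + 1, end_1=i1 + length,
                chromosome_2=c2, start_2=i2 + 1, end_2=i2 + length,
                length=length,
                identity=round(100.0 * matches / length, 2),
                type=kind,
                e_value=repeat_evalue(length, genome_n, mism),
                matches=matches,
            )
        )

    if "forward" in orientations:
        for ai, a in enumerate(names):
            for i, j, L, mt in ungapped_local_alignments(
                sequences[a], sequences[a], min_len=min_length, penalty=penalty,
                anchor_k=k, self_forward=True,
            ):
                emit(a, i, a, j, L, mt, "forward")
            for b in names[ai + 1 :]:
                for i, j, L, mt in ungapped_local_alignments(
                    sequences[a], sequences[b], min_len=min_length,
                    penalty=penalty, anchor_k=k,
                ):
                    emit(a, i, b, j, L, mt, "forward")

    if "palindromic" in orientations:
        for ai, a in enumerate(names):
            la = len(sequences[a])
            seen: set[tuple[int, int, int]] = set()
            for i, j, L, mt in ungapped_local_alignments(
                sequences[a], revcomp(sequences[a]), min_len=min_length,
                penalty=penalty, anchor_k=k,
            ):
                i2 = la - j - L  # plus-strand start of the rc-frame interval
                if i == i2:
                    continue  # an interval matching its own reverse complement
                key = (min(i, i2), max(i, i2), L)
                if key in seen:
                    continue
                seen.add(key)
                emit(a, key[0], a, key[1], L, mt, "palindromic")
            for b in names[ai + 1 :]:
                lb = len(sequences[b])
                for i, j, L, mt in ungapped_local_alignments(
                    sequences[a], revcomp(sequences[b]), min_len=min_length,
                    penalty=penalty, anchor_k=k,
                ):
                    emit(a, i, b, lb - j - L, L, mt, "palindromic")

    out.sort(
        key=lambda r: (-r.length, r.chromosome_1, r.start_1, r.chromosome_2, r.start_2)
    )
    return out


# ---------------------------------------------------------------------------
# summaries


def ssr_class_counts(records: list[SSRRecord]) -> dict[str, int]:
    counts = {name: 0 for name in _CLASS_NAMES.values()}
    for rec in records:
        counts[rec.motif_class] += 1
    return counts


def percent(part: float, whole: float) -> float:
    """Share as a percentage, 2 decimals; 0.0 for an empty denominator."""
    return round(100.0 * part / whole, 2) if whole else 0.0
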