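"""Repeat-mediated recombination: templates, conformations, enumeration.

A plant mitogenome with recombination-active repeats exists as a mixture of
arrangements ("conformations") of the same sequence content.  This module
models a conformation as a set of circular chromosomes, each an ordered
list of oriented segments; crossover between two copies of a repeat pair
is a splice of those lists:

* copies on two different circles  -> fusion   (circle count -1)
* direct copies on one circle      -> fission  (circle count +1)
* inverted copies on one circle    -> inversion (segment block reversed)

The event mode is derived from copy co-circularity and relative repeat
orientation, never user-set, and every event conserves total base content
exactly.  Reference and flank-swapped template sequences per repeat pair
(the junction signatures a spanning long read can discriminate) are built
by :func:`build_templates`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from ._align import revcomp

Oriented = tuple[str, int]  # (segment id, +1/-1)
Circle = tuple[Oriented, ...]


@dataclass(frozen=True)
class Segment:
    """A piece of chromosome sequence; repeat copies carry their pair id.

    ``repeat_strand`` is the orientation of the repeat consensus within the
    stored plus-strand sequence: +1 for a copy placed forward, -1 for the
    reverse-complemented copy of an inverted pair.
    """

    seg_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    sequence: str
    repeat_id: str | None = None
    repeat_strand: int = 1

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RepeatPair:
    """Two genomic placements of a repeated sequence (recombination schema)."""

    pair_id: str
    length: int
    identity: float
    orientation: str  # "direct" | "inverted"
    placement_1: tuple[str, int, int]  # (chromosome, start, end) 1-based
    placement_2: tuple[str, int, int]
    e_value: float = 0.0


@dataclass(frozen=True)
class RecombinationEvent:
    pair_id: str
    mode: str  # "fusion" | "fission" | "inversion" (derived)


@dataclass
class Conformation:
    circles: list[Circle]
    label: str = "major"
    event_path: tuple[RecombinationEvent, ...] = ()

    def total_segments(self) -> int:
        return sum(len(c) for c in self.circles)


@dataclass
class EventPlan:
    """One entry of the supported-event list driving enumeration."""

    pair_id: str
    mode: str | None = None  # apply only when the derived mode matches
    from_major_only: bool = False


@dataclass
class TemplateQuartet:
    pair_id: str
    ref_1: str
    ref_2: str
    swap_1: str
    swap_2: str
    repeat_length: int
    flank_length: int
    unresolvable: bool = False  # identical flanks: swaps equal refs

    def templates(self) -> dict[str, str]:
        return {
            "ref_1": self.ref_1, "ref_2": self.ref_2,
            "swap_1": self.swap_1, "swap_2": self.swap_2,
        }


# ---------------------------------------------------------------------------
# genome segmentation


def segment_genome(
    chrom_seqs: dict[str, str], repeat_pairs: list[RepeatPair]
) -> tuple[Conformation, dict[str, Segment]]:
    """Cut circular chromosomes at repeat-copy boundaries.

    Returns the major conformation (one circle per chromosome, all segments
    in plus orientation) and the segment registry.  Repeat copies become
    their own segments tagged with the pair id.
    """
    cuts: dict[str, list[tuple[int, int, str, int]]] = {c: [] for c in chrom_seqs}
    for pair in repeat_pairs:
        for copy_no, (chrom, start, end) in enumerate(
            (pair.placement_1, pair.placement_2), start=1
        ):
            if chrom not in chrom_seqs:
                raise ValueError(f"unknown chromosome {chrom} for pair {pair.pair_id}")
            if not 1 <= start <= end <= len(chrom_seqs[chrom]):
                raise ValueError(
                    f"pair {pair.pair_id} copy {copy_no} out of bounds on {chrom}"
                )
            strand = -1 if (pair.orientation == "inverted" and copy_no == 2) else 1
            cuts[chrom].append((start, end, pair.pair_id, strand))
    segments: dict[str, Segment] = {}
    circles: list[Circle] = []
    for chrom in chrom_seqs:
        seq = chrom_seqs[chrom]
        intervals = sorted(cuts[chrom])
        for (s1, e1, p1, _), (s2, e2, p2, _) in zip(intervals, intervals[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"repeat copies overlap on {chrom}: {p1} ({s1}-{e1}) vs {p2} ({s2}-{e2})"
                )
        circle: list[Oriented] = []
        pos = 1
        n_plain = 0
        copy_count: dict[str, int] = {}
        for start, end, pair_id, strand in intervals:
            if pos < start:
                n_plain += 1
                sid = f"{chrom}.s{n_plain}"
                segments[sid] = Segment(sid, chrom, pos, start - 1, seq[pos - 1 : start - 1])
                circle.append((sid, 1))
            copy_count[pair_id] = copy_count.get(pair_id, 0) + 1
            sid = f"{pair_id}.copy{copy_count[pair_id]}.{chrom}.{start}"
            segments[sid] = Segment(
                sid, chrom, start, end, seq[start - 1 : end],
                repeat_id=pair_id, repeat_strand=strand,
            )
            circle.append((sid, 1))
            pos = end + 1
        if pos <= len(seq):
            n_plain += 1
            sid = f"{chrom}.s{n_plain}"
            segments[sid] = Segment(sid, chrom, pos, len(seq), seq[pos - 1 :])
            circle.append((sid, 1))
        if not circle:
            raise ValueError(f"chromosome {chrom} produced an empty circle")
        circles.append(tuple(circle))
    return Conformation(circles=circles, label="major"), segments


def realize_conformation(
    conformation: Conformation, segments: dict[str, Segment]
) -> list[str]:
    """Concrete circle sequences (rotation chosen by stored segment order)."""
    out = []
    for circle in conformation.circles:
        parts = []
        for sid, orient in circle:
            seq = segments[sid].sequence
            parts.append(seq if orient > 0 else revcomp(seq))
        out.append("".join(parts))
    return out


def total_bases(conformation: Conformation, segments: dict[str, Segment]) -> int:
    return sum(len(segments[sid]) for c in conformation.circles for sid, _ in c)


# ---------------------------------------------------------------------------
# events


def _flip(circle: Circle) -> Circle:
    return tuple((sid, -o) for sid, o in reversed(circle))


def _locate(
    conformation: Conformation, pair_id: str, segments: dict[str, Segment]
) -> list[tuple[int, int, int]]:
    """(circle index, position, repeat-frame orientation) of each copy."""
    occ = []
    for ci, circle in enumerate(conformation.circles):
        for pos, (sid, orient) in enumerate(circle):
            seg = segments[sid]
            if seg.repeat_id == pair_id:
                occ.append((ci, pos, orient * seg.repeat_strand))
    return occ


def derive_mode(
    conformation: Conformation, pair_id: str, segments: dict[str, Segment]
) -> str:
    """Event mode implied by copy co-circularity and relative orientation."""
    occ = _locate(conformation, pair_id, segments)
    if len(occ) != 2:
        raise ValueError(
            f"repeat pair {pair_id}: expected 2 copies, found {len(occ)}"
        )
    (c1, _, f1), (c2, _, f2) = occ
    if c1 != c2:
        return "fusion"
    return "fission" if f1 == f2 else "inversion"


def apply_recombination(
    conformation: Conformation,
    pair_id: str,
    segments: dict[str, Segment],
) -> Conformation:
    """Crossover between the two copies of a repeat pair.

    Fusion merges two circles, fission splits one, inversion reverses the
    block between inverted copies.  The repeat segments themselves are
    never duplicated or lost, so total base content is conserved exactly.
    """
    occ = _locate(conformation, pair_id, segments)
    if len(occ) != 2:
        raise ValueError(
            f"repeat pair {pair_id}: expected 2 copies, found {len(occ)}"
        )
    (c1, i, f1), (c2, j, f2) = occ
    circles = list(conformation.circles)
    if c1 != c2:
        mode = "fusion"
        x, y = circles[c1], circles[c2]
        if f1 != f2:  # flip the second circle so repeat frames agree
            y = _flip(y)
            j = len(y) - 1 - j
        fused = x[: i + 1] + y[j + 1 :] + y[: j + 1] + x[i + 1 :]
        circles = [c for k, c in enumerate(circles) if k not in (c1, c2)] + [fused]
    else:
        x = circles[c1]
        if i > j:
            i, j = j, i
        if f1 == f2:
            mode = "fission"
            left = x[: i + 1] + x[j + 1 :]
            right = x[i + 1 : j + 1]
            circles = [c for k, c in enumerate(circles) if k != c1] + [left, right]
        else:
            mode = "inversion"
            new = x[: i + 1] + _flip(x[i + 1 : j]) + x[j:]
            circles = [c for k, c in enumerate(circles) if k != c1] + [new]
    event = RecombinationEvent(pair_id=pair_id, mode=mode)
    return Conformation(
        circles=circles,
        label="",
        event_path=conformation.event_path + (event,),
    )


# ---------------------------------------------------------------------------
# canonical form


def _canonical_circle(circle: Circle) -> Circle:
    best = None
    for variant in (circle, _flip(circle)):
        for r in range(len(variant)):
            rot = variant[r:] + variant[:r]
            if best is None or rot < best:
                best = rot
    return best


def canonical_key(
    conformation: Conformation, segments: dict[str, Segment] | None = None
) -> tuple:
    """Key invariant under circle rotation, relabeling, and strand flip.

    With the segment registry supplied, segments are labelled by sequence
    content (up to reverse complement), so two copies of an identical
    repeat are interchangeable -- conformations then compare equal exactly
    when their realized circular sequences do.  Without it the key is
    purely structural (segment ids), which distinguishes identical-sequence
    copies.
    """
    if segments is None:
        circles = conformation.circles
    else:
        labels: dict[str, tuple[int, int]] = {}
        class_ids: dict[str, int] = {}
        for sid in sorted(segments):
            seq = segments[sid].sequence
            rev = revcomp(seq)
            if seq < rev:
                key, sign = seq, 1
            elif rev < seq:
                key, sign = rev, -1
            else:
                key, sign = seq, 0  # palindromic content: orientation-free
            cid = class_ids.setdefault(key, len(class_ids))
            labels[sid] = (cid, sign)
        circles = [
            tuple(
                (f"c{labels[sid][0]}", orient * labels[sid][1])
                for sid, orient in circle
            )
            for circle in conformation.circles
        ]
    return tuple(sorted(_canonical_circle(c) for c in circles))


# ---------------------------------------------------------------------------
# enumeration


def enumerate_conformations(
    major: Conformation,
    plans: list[EventPlan],
    segments: dict[str, Segment],
    max_depth: int = 2,
) -> list[Conformation]:
    """Breadth-first application of supported events, deduplicated.

    Each plan entry applies only where its mode constraint matches the
    derived mode (and, if flagged, only to the major conformation).  Output
    is the major followed by the distinct minors sorted by event path;
    minors are labelled minor-1..minor-n in that order.
    """
    majors_key = canonical_key(major, segments)
    seen = {majors_key}
    frontier = [major]
    minors: list[Conformation] = []
    for _ in range(max_depth):
        nxt: list[Conformation] = []
        for conf in frontier:
            for plan in plans:
                if plan.from_major_only and conf.event_path:
                    continue
                occ = _locate(conf, plan.pair_id, segments)
                if len(occ) != 2:
                    continue
                mode = derive_mode(conf, plan.pair_id, segments)
                if plan.mode is not None and mode != plan.mode:
                    continue
                new = apply_recombination(conf, plan.pair_id, segments)
                key = canonical_key(new, segments)
                if key in seen:
                    continue
                seen.add(key)
                minors.append(new)
                nxt.append(new)
        frontier = nxt
        if not frontier:
            break
    minors.sort(key=lambda c: tuple((e.pair_id, e.mode) for e in c.event_path))
    out = [replace(major, label="major")]
    for k, conf in enumerate(minors, start=1):
        conf.label = f"minor-{k}"
        out.append(conf)
    return out


# ---------------------------------------------------------------------------
# templates


def _circ_slice(seq: str, start0: int, length: int) -> str:
    """Slice a circular sequence; start0 may be negative or beyond the end."""
    n = len(seq)
    if length > n:
        raise ValueError("slice longer than the circle")
    start0 %= n
    if start0 + length <= n:
        return seq[start0 : start0 + length]
    return seq[start0:] + seq[: start0 + length - n]


def _expanded_overlap(n: int, a: tuple[int, int], b: tuple[int, int]) -> bool:
    """Do two circular 0-based half-open intervals on a circle of size n overlap?"""

    def unwrap(iv):
        s, e = iv
        s %= n
        length = e - iv[0]
        return [(s, min(s + length, n))] + (
            [(0, s + length - n)] if s + length > n else []
        )

    for s1, e1 in unwrap(a):
        for s2, e2 in unwrap(b):
            if s1 < e2 and s2 < e1:
                return True
    return False


def build_templates(
    chrom_seqs: dict[str, str],
    pair: RepeatPair,
    flank_length: int = 1000,
) -> TemplateQuartet:
    """Reference and flank-swapped junction templates for one repeat pair.

    Each template is upstream flank + repeat copy + downstream flank; the
    swap templates exchange downstream flanks between the two copies.  For
    an inverted pair the second copy's flanks are taken on its own strand
    (the reverse complement of the plus-strand neighbourhood).  Flanks wrap
    across the circular origin rather than truncating.  Copies whose
    flank-extended intervals overlap are rejected: their templates would
    share sequence and spanning reads could not discriminate them.
    """
    if flank_length < 1:
        raise ValueError("flank_length must be >= 1")
    (ch1, s1, e1), (ch2, s2, e2) = pair.placement_1, pair.placement_2
    seq1, seq2 = chrom_seqs[ch1], chrom_seqs[ch2]
    if ch1 == ch2 and _expanded_overlap(
        len(seq1),
        (s1 - 1 - flank_length, e1 + flank_length),
        (s2 - 1 - flank_length, e2 + flank_length),
    ):
        raise ValueError(
            f"pair {pair.pair_id}: copies within flank distance on {ch1}; "
            "templates would share sequence"
        )
    len1, len2 = e1 - s1 + 1, e2 - s2 + 1
    u1 = _circ_slice(seq1, s1 - 1 - flank_length, flank_length)
    r1 = _circ_slice(seq1, s1 - 1, len1)
    d1 = _circ_slice(seq1, e1, flank_length)
    if pair.orientation == "inverted":
        view = revcomp(_circ_slice(seq2, s2 - 1 - flank_length, len2 + 2 * flank_length))
        u2, r2, d2 = view[:flank_length], view[flank_length : flank_length + len2], view[-flank_length:]
    else:
        u2 = _circ_slice(seq2, s2 - 1 - flank_length, flank_length)
        r2 = _circ_slice(seq2, s2 - 1, len2)
        d2 = _circ_slice(seq2, e2, flank_length)
    return TemplateQuartet(
        pair_id=pair.pair_id,
        ref_1=u1 + r1 + d1,
        ref_2=u2 + r2 + d2,
        swap_1=u1 + r1 + d2,
        swap_2=u2 + r2 + d1,
        repeat_length=max(len1, len2),
        flank_length=flank_length,
        unresolvable=(u1 == u2 and d1 == d2),
    )
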