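"""Mitochondrial plastid sequences (MTPTs).

Fragments of the plastid genome that migrated into the mitochondrial
genome are detected as ungapped local homologies between the two genomes
(both strands), merged into non-redundant intervals on the mitochondrial
axis, summarised (count, total length, fraction of the mitogenome), and
annotated with plastid genes fully contained in the transferred interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gffutils

from ._align import identity_penalty, revcomp, ungapped_local_alignments

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RawMatch:
    mito_chromosome: str
    mito_start: int  # 1-based inclusive
    mito_end: int
    plastid_start: int
    plastid_end: int
    strand: str  # plastid interval is always reported on plus; strand flags sense
    identity: float  # percent
    length: int


@dataclass
class MTPTFragment:
    mito_chromosome: str
    mito_start: int
    mito_end: int
    plastid_start: int
    plastid_end: int
    strand: str
    identity: float
    length: int
    genes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class TransferStats:
    fragment_count: int
    total_length: int
    fraction_percent: float  # of the mitogenome, 2 decimals
    count_over_1kb: int
    longest: int


def scan_homology(
    mito_seqs: dict[str, str],
    plastid_seq: str,
    min_length: int = 100,
    min_identity: float = 70.0,
    anchor_k: int = 11,
) -> list[RawMatch]:
    """Ungapped local matches between mitochondrial and plastid genomes.

    Both strands are scanned; matches shorter than ``min_length`` or below
    the identity floor are dropped.  The anchor size is a heuristic seed:
    homologies with exact runs shorter than ``anchor_k`` throughout (more
    than ~1 difference per anchor length) can be missed, which is far below
    the divergence of recent organellar transfers.
    """
    if not mito_seqs or not plastid_seq:
        raise ValueError("both genomes must be non-empty")
    penalty = identity_penalty(1.0 - min_identity / 100.0)
    lp = len(plastid_seq)
    rc_plastid = revcomp(plastid_seq)
    matches: list[RawMatch] = []
    for chrom, seq in mito_seqs.items():
        for strand, target in (("+", plastid_seq), ("-", rc_plastid)):
            for i, j, L, mt in ungapped_local_alignments(
                seq, target, min_len=min_length, penalty=penalty, anchor_k=anchor_k
            ):
                ps = j if strand == "+" else lp - j - L
                matches.append(
                    RawMatch(
                        mito_chromosome=chrom,
                        mito_start=i + 1,
                        mito_end=i + L,
                        plastid_start=ps + 1,
                        plastid_end=ps + L,
                        strand=strand,
                        identity=round(100.0 * mt / L, 2),
                        length=L,
                    )
                )
    matches.sort(key=lambda m: (m.mito_chromosome, m.mito_start, m.mito_end))
    return matches


def merge_fragments(matches: list[RawMatch]) -> list[MTPTFragment]:
    """Union of overlapping or book-ended mito intervals.

    Identity of a merged fragment is the length-weighted mean of its
    constituents; the reported plastid partner is the constituent with the
    highest identity (alternatives are logged).  Output sorted by mito
    coordinate.
    """
    out: list[MTPTFragment] = []
    by_chrom: dict[str, list[RawMatch]] = {}
    for m in matches:
        by_chrom.setdefault(m.mito_chromosome, []).append(m)
    for chrom in sorted(by_chrom):
        group: list[RawMatch] = []
        start = end = None
        for m in sorted(by_chrom[chrom], key=lambda x: (x.mito_start, x.mito_end)):
            if start is None:
                start, end, group = m.mito_start, m.mito_end, [m]
            elif m.mito_start <= end + 1:
                end = max(end, m.mito_end)
                group.append(m)
            else:
                out.append(_finish(chrom, start, end, group))
                start, end, group = m.mito_start, m.mito_end, [m]
        if start is not None:
            out.append(_finish(chrom, start, end, group))
    return out


def _finish(chrom: str, start: int, end: int, group: list[RawMatch]) -> MTPTFragment:
    wsum = sum(m.identity * m.length for m in group)
    lsum = sum(m.length for m in group)
    best = max(group, key=lambda m: (m.identity, m.length, -m.mito_start))
    if len(group) > 1:
        alts = [
            f"{m.plastid_start}-{m.plastid_end}({m.strand})"
            for m in group
            if m is not best
        ]
        logger.debug(
            "fragment %s:%d-%d merged from %d matches; alternative plastid "
            "partners: %s", chrom, start, end, len(group), ", ".join(alts),
        )
    return MTPTFragment(
        mito_chromosome=chrom,
        mito_start=start,
        mito_end=end,
        plastid_start=best.plastid_start,
        plastid_end=best.plastid_end,
        strand=best.strand,
        identity=round(wsum / lsum, 2),
        length=end - start + 1,
    )


def transfer_stats(fragments: list[MTPTFragment], mitogenome_length: int) -> TransferStats:
    if mitogenome_length <= 0:
        raise ValueError("mitogenome length must be positive")
    total = sum(f.length for f in fragments)
    return TransferStats(
        fragment_count=len(fragments),
        total_length=total,
        fraction_percent=round(100.0 * total / mitogenome_length, 2),
        count_over_1kb=sum(1 for f in fragments if f.length > 1000),
        longest=max((f.length for f in fragments), default=0),
    )


def _clean_gff(text: str) -> str:
    kept = []
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            kept.append(line)
            continue
        fields = line.split("\t")
        if len(fields) != 9 or not fields[3].isdigit() or not fields[4].isdigit():
            logger.warning("skipping malformed annotation row %d: %r", ln, line[:80])
            continue
        kept.append(line)
    return "\n".join(kept) + "\n"


def annotate_transfers(
    fragments: list[MTPTFragment],
    gff3: str,
    featuretypes: tuple[str, ...] = ("gene",),
) -> list[MTPTFragment]:
    """Attach plastid genes whose full span lies within a fragment's
    plastid interval (complete genes only; partial overlaps excluded).

    ``gff3`` is a path or GFF3 text; malformed rows are skipped with a
    warning.  Returns new fragment objects, input left untouched.
    """
    try:
        with open(gff3) as fh:
            text = fh.read()
    except (OSError, ValueError):
        text = gff3
    db = gffutils.create_db(
        _clean_gff(text), dbfn=":memory:", from_string=True,
        merge_strategy="create_unique", keep_order=True,
    )
    genes = [
        (f.start, f.end, f.attributes.get("Name", [f.id])[0])
        for ft in featuretypes
        for f in db.features_of_type(ft)
    ]
    out = []
    for frag in fragments:
        contained = sorted(
            name for s, e, name in genes
            if frag.plastid_start <= s and e <= frag.plastid_end
        )
        out.append(replace(frag, genes=contained))
    return out
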