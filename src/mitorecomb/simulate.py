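"""Synthetic organelle genomes, planted features, and simulated long reads.

The generator emulates the kind of data the analysis assumes: a small
number of circular chromosomes with i.i.d. background composition at a
target GC, carrying planted microsatellites, tandem arrays, dispersed
repeat pairs (recombination-active), and plastid-homologous fragments.
Every planted feature is recorded in a truth table (1-based inclusive
coordinates) so downstream detectors can be scored against ground truth.

Planted truth is made *detector-well-defined*: substitutions between the
two copies of a planted repeat pair are spread evenly with an interior
margin, and the background bases immediately flanking a planted feature are
forced to mismatch the feature's continuation.  Without this, the maximal
alignment containing a planted pair would extend stochastically into the
background and truth coordinates would not correspond to any detectable
object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

TRUTH_COLUMNS = ["feature_class", "chromosome", "start", "end", "strand", "attributes"]

#: interior margin (bases) kept free of substitutions at either end of a
#: planted repeat copy; matches the mismatch penalty of the default
#: dispersed-repeat scoring (9) plus one, so end trimming never pays.
END_MARGIN = 10


# ---------------------------------------------------------------------------
# plans and specs


@dataclass
class RepeatPlan:
    """Two placements of a repeated sequence, direct or inverted."""

    length: int
    n_mismatches: int
    orientation: str  # "direct" | "inverted"
    placement_1: tuple[int, int]  # (chromosome index, 1-based start)
    placement_2: tuple[int, int]
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"orientation must be direct/inverted: {self.orientation}")
        if not 0 <= self.n_mismatches < self.length:
            raise ValueError("n_mismatches must be < repeat length")


@dataclass
class SSRPlan:
    motif: str
    copies: int
    chromosome: int
    start: int  # 1-based


@dataclass
class TandemPlan:
    unit_length: int
    copies: int
    n_substitutions: int  # applied within the second copy
    chromosome: int
    start: int


@dataclass
class TransferPlan:
    """A mitochondrial interval copied into the plastid genome."""

    mito_chromosome: int
    mito_start: int  # 1-based inclusive
    mito_end: int
    plastid_start: int
    n_substitutions: int = 0


@dataclass
class GenomeSpec:
    chromosome_lengths: list[int]
    gc_content: float = 0.4443
    planted_repeats: list[RepeatPlan] = field(default_factory=list)
    planted_ssrs: list[SSRPlan] = field(default_factory=list)
    planted_tandems: list[TandemPlan] = field(default_factory=list)
    planted_transfers: list[TransferPlan] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosome_lengths or any(n <= 0 for n in self.chromosome_lengths):
            raise ValueError("all chromosome lengths must be positive")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")


@dataclass
class ReadSimSpec:
    conformation_weights: dict[str, float]
    coverage: float
    read_length_mean: float = 3000.0
    read_length_sd: float = 2000.0
    per_base_error_rate: float = 0.05
    seed: int = 0
    min_read_length: int = 500

    def __post_init__(self) -> None:
        if not self.conformation_weights or sum(self.conformation_weights.values()) <= 0:
            raise ValueError("conformation weights must sum to > 0")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.per_base_error_rate <= 0.3:
            raise ValueError("per-base error rate must lie in [0, 0.3]")


@dataclass
class SimRead:
    read_id: str
    sequence: str


# ---------------------------------------------------------------------------
# helpers


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(BASES, size=length, p=probs)
    return arr.tobytes().decode("ascii")


def _even_substitution_positions(length: int, n: int, margin: int) -> list[int]:
    """Deterministic, evenly spread interior substitution positions."""
    if n == 0:
        return []
    interior = length - 2 * margin
    if interior < n:
        margin = max(0, (length - n) // 2)
        interior = length - 2 * margin
    pos = [margin + int((i + 0.5) * interior / n) for i in range(n)]
    # guard against rounding collisions
    for i in range(1, n):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    if pos and pos[-1] >= length - margin:
        raise ValueError(f"cannot place {n} substitutions in length {length}")
    return pos


def mutate(seq: str, positions: list[int], rng: np.random.Generator) -> str:
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def _attr(**kw) -> str:
    return ";".join(f"{k}={v}" for k, v in kw.items())


class _Chromosome:
    """Mutable byte buffer for one chromosome plus its reserved intervals."""

    def __init__(self, name: str, seq: str):
        self.name = name
        self.buf = bytearray(seq.encode("ascii"))
        self.reserved: list[tuple[int, int, str]] = []  # 1-based inclusive

    def reserve(self, start: int, end: int, what: str) -> None:
        if start < 1 or end > len(self.buf):
            raise ValueError(
                f"feature {what} ({start}-{end}) exceeds {self.name} bounds 1-{len(self.buf)}"
            )
        for s, e, w in self.reserved:
            if start <= e and s <= end:
                raise ValueError(
                    f"planted features overlap on {self.name}: {what} "
                    f"({start}-{end}) vs {w} ({s}-{e})"
                )
        self.reserved.append((start, end, what))

    def write(self, start: int, seq: str) -> None:
        self.buf[start - 1 : start - 1 + len(seq)] = seq.encode("ascii")

    def base(self, pos: int) -> str:
        return chr(self.buf[pos - 1])

    def set_base_not(self, pos: int, avoid: str) -> None:
        """Force the (background) base at pos to differ from ``avoid``."""
        if pos < 1 or pos > len(self.buf):
            return
        for s, e, _w in self.reserved:
            if s <= pos <= e:
                return  # never touch another planted feature
        if self.base(pos) in avoid:
            repl = next(b for b in "ACGT" if b not in avoid)
            self.buf[pos - 1] = ord(repl)

    def sequence(self) -> str:
        return self.buf.decode("ascii")


# ---------------------------------------------------------------------------
# genome generation


def generate_genome(spec: GenomeSpec) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate chromosome sequences and the matching truth table.

    Identical spec and seed give byte-identical output.  Overlapping plans
    and out-of-bounds features are rejected with the offending pair named.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = [
        _Chromosome(f"chr{i + 1}", random_sequence(rng, n, spec.gc_content))
        for i, n in enumerate(spec.chromosome_lengths)
    ]
    truth: list[dict] = []

    def chrom(idx: int) -> _Chromosome:
        try:
            return chroms[idx]
        except IndexError:
            raise ValueError(f"chromosome index {idx} out of range") from None

    # reserve everything first so any overlap is reported before writing
    for k, plan in enumerate(spec.planted_repeats):
        pid = plan.pair_id or f"R{k + 1}"
        for ci, start in (plan.placement_1, plan.placement_2):
            chrom(ci).reserve(start, start + plan.length - 1, f"repeat {pid}")
    for plan in spec.planted_ssrs:
        end = plan.start + len(plan.motif) * plan.copies - 1
        chrom(plan.chromosome).reserve(plan.start, end, f"ssr {plan.motif}")
    for plan in spec.planted_tandems:
        end = plan.start + plan.unit_length * plan.copies - 1
        chrom(plan.chromosome).reserve(plan.start, end, f"tandem u{plan.unit_length}")
    for plan in spec.planted_transfers:
        chrom(plan.mito_chromosome).reserve(
            plan.mito_start, plan.mito_end, "mtpt source"
        )

    for k, plan in enumerate(spec.planted_repeats):
        pid = plan.pair_id or f"R{k + 1}"
        copy1 = random_sequence(rng, plan.length, spec.gc_content)
        subs = _even_substitution_positions(plan.length, plan.n_mismatches, END_MARGIN)
        copy2 = mutate(copy1, subs, rng)
        c1, s1 = plan.placement_1
        c2, s2 = plan.placement_2
        placed2 = copy2 if plan.orientation == "direct" else revcomp(copy2)
        chrom(c1).write(s1, copy1)
        chrom(c2).write(s2, placed2)
        e1 = s1 + plan.length - 1
        e2 = s2 + plan.length - 1
        # flank guards: make the planted alignment maximal
        if plan.orientation == "direct":
            chrom(c2).set_base_not(s2 - 1, chrom(c1).base(s1 - 1) if s1 > 1 else "")
            if e1 < len(chrom(c1).buf):
                chrom(c2).set_base_not(e2 + 1, chrom(c1).base(e1 + 1))
        else:
            # in the inverted alignment, left of copy1 pairs with right of copy2
            if e1 < len(chrom(c1).buf) and s1 > 1:
                chrom(c2).set_base_not(s2 - 1, revcomp(chrom(c1).base(e1 + 1)))
                chrom(c2).set_base_not(e2 + 1, revcomp(chrom(c1).base(s1 - 1)))
        strand2 = "+" if plan.orientation == "direct" else "-"
        truth.append(
            dict(
                feature_class="repeat_pair",
                chromosome=chrom(c1).name,
                start=s1,
                end=e1,
                strand="+",
                attributes=_attr(
                    pair_id=pid, copy=1, orientation=plan.orientation,
                    mismatches=plan.n_mismatches, length=plan.length,
                ),
            )
        )
        truth.append(
            dict(
                feature_class="repeat_pair",
                chromosome=chrom(c2).name,
                start=s2,
                end=e2,
                strand=strand2,
                attributes=_attr(
                    pair_id=pid, copy=2, orientation=plan.orientation,
                    mismatches=plan.n_mismatches, length=plan.length,
                ),
            )
        )

    for plan in spec.planted_ssrs:
        ch = chrom(plan.chromosome)
        tract = plan.motif * plan.copies
        ch.write(plan.start, tract)
        end = plan.start + len(tract) - 1
        ch.set_base_not(plan.start - 1, plan.motif[-1])
        ch.set_base_not(end + 1, plan.motif[0])
        truth.append(
            dict(
                feature_class="ssr",
                chromosome=ch.name,
                start=plan.start,
                end=end,
                strand="+",
                attributes=_attr(motif=plan.motif, copies=plan.copies),
            )
        )

    for plan in spec.planted_tandems:
        ch = chrom(plan.chromosome)
        unit = random_sequence(rng, plan.unit_length, spec.gc_content)
        copies = [unit] * plan.copies
        if plan.n_substitutions and plan.copies >= 2:
            subs = _even_substitution_positions(
                plan.unit_length, plan.n_substitutions, 1
            )
            copies[1] = mutate(unit, subs, rng)
        array = "".join(copies)
        ch.write(plan.start, array)
        end = plan.start + len(array) - 1
        ch.set_base_not(plan.start - 1, unit[-1])
        ch.set_base_not(end + 1, unit[0])
        truth.append(
            dict(
                feature_class="tandem",
                chromosome=ch.name,
                start=plan.start,
                end=end,
                strand="+",
                attributes=_attr(
                    unit=unit, copies=plan.copies, substitutions=plan.n_substitutions
                ),
            )
        )

    for k, plan in enumerate(spec.planted_transfers):
        ch = chrom(plan.mito_chromosome)
        truth.append(
            dict(
                feature_class="mtpt_source",
                chromosome=ch.name,
                start=plan.mito_start,
                end=plan.mito_end,
                strand="+",
                attributes=_attr(
                    transfer_id=f"T{k + 1}",
                    length=plan.mito_end - plan.mito_start + 1,
                    substitutions=plan.n_substitutions,
                ),
            )
        )

    seqs = {ch.name: ch.sequence() for ch in chroms}
    return seqs, pd.DataFrame(truth, columns=TRUTH_COLUMNS)


def derive_plastid_with_transfers(
    mito_seqs: dict[str, str],
    transfer_plans: list[TransferPlan],
    plastid_length: int,
    seed: int = 0,
    gc_content: float = 0.38,
) -> tuple[str, pd.DataFrame]:
    """Random plastid background carrying copies of mitochondrial intervals.

    Each transferred fragment appears in both genomes (with the configured
    number of substitutions on the plastid copy); the truth table records
    both placements.
    """
    rng = np.random.default_rng(seed)
    names = list(mito_seqs)
    plastid = _Chromosome("plastid", random_sequence(rng, plastid_length, gc_content))
    truth: list[dict] = []
    for k, plan in enumerate(transfer_plans):
        name = names[plan.mito_chromosome]
        mseq = mito_seqs[name]
        if not 1 <= plan.mito_start <= plan.mito_end <= len(mseq):
            raise ValueError(
                f"transfer interval {plan.mito_start}-{plan.mito_end} exceeds "
                f"{name} bounds 1-{len(mseq)}"
            )
        frag = mseq[plan.mito_start - 1 : plan.mito_end]
        if plan.n_substitutions:
            subs = _even_substitution_positions(
                len(frag), plan.n_substitutions, END_MARGIN
            )
            frag = mutate(frag, subs, rng)
        plastid.reserve(
            plan.plastid_start, plan.plastid_start + len(frag) - 1, f"transfer T{k + 1}"
        )
        plastid.write(plan.plastid_start, frag)
        tid = f"T{k + 1}"
        truth.append(
            dict(
                feature_class="mtpt",
                chromosome=name,
                start=plan.mito_start,
                end=plan.mito_end,
                strand="+",
                attributes=_attr(transfer_id=tid, genome="mito", length=len(frag)),
            )
        )
        truth.append(
            dict(
                feature_class="mtpt",
                chromosome="plastid",
                start=plan.plastid_start,
                end=plan.plastid_start + len(frag) - 1,
                strand="+",
                attributes=_attr(
                    transfer_id=tid, genome="plastid",
                    substitutions=plan.n_substitutions, length=len(frag),
                ),
            )
        )
    # flank guards for verbatim transfers keep homology boundaries sharp
    for plan in transfer_plans:
        if plan.n_substitutions == 0:
            name = names[plan.mito_chromosome]
            mseq = mito_seqs[name]
            pstart = plan.plastid_start
            pend = pstart + (plan.mito_end - plan.mito_start)
            if plan.mito_start > 1:
                plastid.set_base_not(pstart - 1, mseq[plan.mito_start - 2])
            if plan.mito_end < len(mseq):
                plastid.set_base_not(pend + 1, mseq[plan.mito_end])
    return plastid.sequence(), pd.DataFrame(truth, columns=TRUTH_COLUMNS)


# ---------------------------------------------------------------------------
# long-read simulation


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution/insertion/deletion noise at 60:20:20 of the given rate."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    r = rng.random(arr.size)
    sub = r < 0.6 * rate
    ins = (r >= 0.6 * rate) & (r < 0.8 * rate)
    dele = (r >= 0.8 * rate) & (r < rate)
    if sub.any():
        idx = _BASE_INDEX[arr[sub]]
        shift = rng.integers(1, 4, size=idx.size)
        arr[sub] = BASES[(idx + shift) % 4]
    counts = np.ones(arr.size, dtype=np.int64)
    counts[dele] = 0
    counts[ins] += 1  # duplicate slot, overwritten with a random base below
    out = np.repeat(arr, counts)
    if ins.any():
        cum = np.cumsum(counts)
        pos = cum[np.flatnonzero(ins)] - 1
        out[pos] = BASES[rng.integers(0, 4, size=pos.size)]
    return out.tobytes().decode("ascii")


def simulate_long_reads(
    conformations: dict[str, list[str]],
    sim: ReadSimSpec,
) -> tuple[list[SimRead], pd.DataFrame]:
    """Draw noisy long reads from a weighted mixture of circular conformations.

    Reads are substrings of a circle (wrapping the origin allowed), reverse
    complemented with probability 0.5, with log-normal lengths truncated to
    [min_read_length, circle length].  Total error-free bases reach
    coverage x genome length (the genome length of the first conformation;
    all conformations derived from one major share it).
    """
    if not conformations:
        raise ValueError("empty conformation set")
    for label in sim.conformation_weights:
        if label not in conformations:
            raise ValueError(f"unknown conformation in weights: {label}")
    rng = np.random.default_rng(sim.seed)
    labels = sorted(sim.conformation_weights)
    w = np.array([sim.conformation_weights[x] for x in labels], dtype=float)
    w = w / w.sum()
    genome_len = sum(len(c) for c in next(iter(conformations.values())))
    target = sim.coverage * genome_len

    mean, sd = sim.read_length_mean, sim.read_length_sd
    sigma2 = math.log(1.0 + (sd / mean) ** 2) if sd > 0 else 0.0
    mu = math.log(mean) - sigma2 / 2.0

    reads: list[SimRead] = []
    truth: list[dict] = []
    total = 0
    n = 0
    while total < target:
        label = labels[int(rng.choice(len(labels), p=w))]
        circles = conformations[label]
        lens = np.array([len(c) for c in circles], dtype=float)
        ci = int(rng.choice(len(circles), p=lens / lens.sum()))
        circle = circles[ci]
        raw = rng.lognormal(mu, math.sqrt(sigma2)) if sigma2 > 0 else mean
        length = int(min(max(raw, sim.min_read_length), len(circle)))
        start = int(rng.integers(0, len(circle)))
        sub = (circle + circle)[start : start + length]
        strand = "-" if rng.random() < 0.5 else "+"
        clean = revcomp(sub) if strand == "-" else sub
        noisy = _apply_errors(clean, sim.per_base_error_rate, rng)
        n += 1
        rid = f"read{n:06d}"
        reads.append(SimRead(rid, noisy))
        truth.append(
            dict(
                read_id=rid,
                conformation=label,
                circle=ci,
                start=start + 1,
                strand=strand,
                clean_length=length,
                length=len(noisy),
            )
        )
        total += length
    return reads, pd.DataFrame(truth)


def constant_quality(error_rate: float) -> int:
    """Phred quality matching the configured per-base error rate."""
    if error_rate <= 0:
        return 40
    return min(40, max(2, round(-10.0 * math.log10(error_rate))))


def make_plastid_gff(
    plastid_truth: pd.DataFrame,
    inside_per_fragment: int = 2,
    n_boundary: int = 0,
    gene_length: int = 70,
) -> str:
    """Synthetic plastid GFF3: genes fully inside transferred intervals plus
    optional genes straddling interval boundaries (for completeness-rule
    tests).  Deterministic given the truth table."""
    rows = plastid_truth[
        (plastid_truth["feature_class"] == "mtpt")
        & (plastid_truth["chromosome"] == "plastid")
    ]
    lines = ["##gff-version 3"]
    g = 0
    for _, row in rows.iterrows():
        span = row["end"] - row["start"] + 1
        k = min(inside_per_fragment, max(0, span // (gene_length + 10)))
        for i in range(k):
            g += 1
            start = row["start"] + 5 + i * (gene_length + 10)
            end = start + gene_length - 1
            if end > row["end"] - 5:
                break
            lines.append(
                f"plastid\tsynthetic\tgene\t{start}\t{end}\t.\t+\t.\tID=gene{g};Name=gene{g}"
            )
    for _, row in rows.head(n_boundary).iterrows():
        g += 1
        start = row["end"] - gene_length // 2
        end = start + gene_length - 1
        lines.append(
            f"plastid\tsynthetic\tgene\t{start}\t{end}\t.\t+\t.\tID=bgene{g};Name=bgene{g}"
        )
    return "\n".join(lines) + "\n"
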