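"""Pipeline orchestration: synthesize -> repeats -> recombination -> mtpt -> report.

A single YAML-configurable entry point wires the stages together.  A run
consumes either real inputs (genome FASTA, long reads, optional plastid
FASTA and GFF3 annotations) or a synthetic-data block that generates a
genome, truth tables, and simulated reads first; exactly one of the two
must be present.  Stages can be skipped individually; each stage logs its
parameters, seed, and wall time, and any stage rejection propagates with
the stage name attached.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from . import mtpt as mtpt_mod
from .recombination import (
    EventPlan,
    RepeatPair,
    build_templates,
    enumerate_conformations,
    realize_conformation,
    segment_genome,
)
from .repeats import find_dispersed_repeats, find_ssrs, find_tandem_repeats
from .report import SummaryReport, genome_stats, write_reports
from .simulate import (
    GenomeSpec,
    ReadSimSpec,
    RepeatPlan,
    SSRPlan,
    TandemPlan,
    TransferPlan,
    constant_quality,
    derive_plastid_with_transfers,
    generate_genome,
    make_plastid_gff,
    simulate_long_reads,
)
from .support import count_spanning_support, support_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 42
    output_dir: str = "mitorecomb_out"
    synthetic: dict | None = None
    inputs: dict | None = None
    reads: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    repeats: dict = field(default_factory=dict)
    recombination: dict = field(default_factory=dict)
    mtpt: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError(
                "config must provide exactly one of a synthetic block or real inputs"
            )

    def stage_enabled(self, name: str) -> bool:
        return bool(self.stages.get(name, True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: getattr(self, k)
            for k in ("seed", "output_dir", "synthetic", "inputs", "reads",
                      "stages", "repeats", "recombination", "mtpt")
            if getattr(self, k) not in (None, {})
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# synthetic block parsing


def _parse_genome_spec(block: dict, seed: int) -> GenomeSpec:
    repeats = [RepeatPlan(**d) for d in block.get("repeats", [])]
    for plan in repeats:
        plan.placement_1 = tuple(plan.placement_1)
        plan.placement_2 = tuple(plan.placement_2)
    return GenomeSpec(
        chromosome_lengths=list(block["chromosome_lengths"]),
        gc_content=float(block.get("gc_content", 0.4443)),
        planted_repeats=repeats,
        planted_ssrs=[SSRPlan(**d) for d in block.get("ssrs", [])],
        planted_tandems=[TandemPlan(**d) for d in block.get("tandems", [])],
        planted_transfers=[TransferPlan(**d) for d in block.get("transfers", [])],
        seed=seed,
    )


def truth_repeat_pairs(spec: GenomeSpec) -> list[RepeatPair]:
    """Planted repeat plans as recombination-schema pairs, longest first."""
    plans = sorted(spec.planted_repeats, key=lambda p: -p.length)
    pairs = []
    for k, plan in enumerate(plans, start=1):
        pid = plan.pair_id or f"R{k}"
        c1, s1 = plan.placement_1
        c2, s2 = plan.placement_2
        pairs.append(
            RepeatPair(
                pair_id=pid,
                length=plan.length,
                identity=round(100.0 * (plan.length - plan.n_mismatches) / plan.length, 2),
                orientation=plan.orientation,
                placement_1=(f"chr{c1 + 1}", s1, s1 + plan.length - 1),
                placement_2=(f"chr{c2 + 1}", s2, s2 + plan.length - 1),
            )
        )
    return pairs


def _parse_event_plans(entries: list[dict] | None) -> list[EventPlan] | None:
    if not entries:
        return None
    return [
        EventPlan(
            pair_id=d["pair"],
            mode=d.get("mode"),
            from_major_only=bool(d.get("from_major_only", False)),
        )
        for d in entries
    ]


def _conformation_mixture(labels: list[str], major_weight: float) -> dict[str, float]:
    minors = [x for x in labels if x != "major"]
    if not minors:
        return {"major": 1.0}
    share = (1.0 - major_weight) / len(minors)
    weights = {"major": major_weight}
    weights.update({m: share for m in minors})
    return weights


# ---------------------------------------------------------------------------
# stages


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("synthesize")
def _run_synthesize(config: PipelineConfig, outdir: Path) -> dict:
    block = config.synthetic
    spec = _parse_genome_spec(block, config.seed)
    seqs, truth = generate_genome(spec)
    plastid = None
    plastid_truth = None
    gff_path = None
    if spec.planted_transfers and block.get("plastid_length"):
        plastid, plastid_truth = derive_plastid_with_transfers(
            seqs, spec.planted_transfers, int(block["plastid_length"]),
            seed=config.seed + 1,
        )
        if block.get("plastid_genes", True):
            gff_path = outdir / "plastid_genes.gff3"
            gff_path.write_text(
                make_plastid_gff(plastid_truth, inside_per_fragment=2, n_boundary=1)
            )
    pairs = truth_repeat_pairs(spec)
    major, segments = segment_genome(seqs, pairs)
    plans = _parse_event_plans(config.recombination.get("event_plan")) or [
        EventPlan(p.pair_id) for p in pairs
    ]
    confs = enumerate_conformations(
        major, plans, segments, max_depth=int(config.recombination.get("max_depth", 2))
    )
    realized = {c.label: realize_conformation(c, segments) for c in confs}
    rblock = dict(config.reads)
    major_weight = float(rblock.pop("major_weight", 0.5))
    sim = ReadSimSpec(
        conformation_weights=_conformation_mixture(list(realized), major_weight),
        coverage=float(rblock.get("coverage", 30.0)),
        read_length_mean=float(rblock.get("read_length_mean", 3000.0)),
        read_length_sd=float(rblock.get("read_length_sd", 2000.0)),
        per_base_error_rate=float(rblock.get("per_base_error_rate", 0.05)),
        seed=config.seed + 2,
    )
    reads, read_truth = simulate_long_reads(realized, sim)
    logger.info(
        "synthesized %d chromosomes, %d reads (coverage %.1fx, error %.3f, seed %d)",
        len(seqs), len(reads), sim.coverage, sim.per_base_error_rate, config.seed,
    )
    mio.write_fasta(seqs, outdir / "genome.fasta")
    mio.write_fastq(reads, outdir / "reads.fastq",
                    constant_quality(sim.per_base_error_rate))
    mio.write_table(truth, outdir / "genome_truth.tsv")
    mio.write_table(read_truth, outdir / "read_truth.tsv")
    if plastid is not None:
        mio.write_fasta({"plastid": plastid}, outdir / "plastid.fasta")
        mio.write_table(plastid_truth, outdir / "plastid_truth.tsv")
    return dict(
        seqs=seqs, reads=reads, plastid=plastid, annotations=gff_path,
        truth=truth, plastid_truth=plastid_truth,
    )


@_stage("load-inputs")
def _run_load(config: PipelineConfig) -> dict:
    inputs = config.inputs
    genome_path = inputs.get("genome")
    if not genome_path or not Path(genome_path).exists():
        raise FileNotFoundError(f"genome FASTA not found: {genome_path}")
    seqs = mio.read_fasta(genome_path)
    reads = []
    if inputs.get("reads"):
        if not Path(inputs["reads"]).exists():
            raise FileNotFoundError(f"reads file not found: {inputs['reads']}")
        reads = mio.read_reads(inputs["reads"])
    plastid = None
    if inputs.get("plastid"):
        if not Path(inputs["plastid"]).exists():
            raise FileNotFoundError(f"plastid FASTA not found: {inputs['plastid']}")
        plastid = next(iter(mio.read_fasta(inputs["plastid"]).values()))
    annotations = inputs.get("annotations")
    if annotations and not Path(annotations).exists():
        raise FileNotFoundError(f"annotation GFF3 not found: {annotations}")
    return dict(seqs=seqs, reads=reads, plastid=plastid, annotations=annotations)


@_stage("repeats")
def _run_repeats(config: PipelineConfig, seqs: dict[str, str], report: SummaryReport):
    params = config.repeats
    thresholds = params.get("ssr_thresholds")
    if thresholds:
        thresholds = {int(k): int(v) for k, v in dict(thresholds).items()}
    pmin, pmax = params.get("tandem_period_range", (15, 27))
    report.ssrs = {
        chrom: find_ssrs(seq, thresholds, chromosome=chrom, circular=True)
        for chrom, seq in seqs.items()
    }
    report.tandems = [
        rec
        for chrom, seq in seqs.items()
        for rec in find_tandem_repeats(
            seq, int(pmin), int(pmax),
            float(params.get("tandem_min_percent", 78.0)),
            chromosome=chrom,
        )
    ]
    report.dispersed = find_dispersed_repeats(
        seqs,
        min_length=int(params.get("min_dispersed_length", 30)),
        orientations=tuple(params.get("orientations", ("forward", "palindromic"))),
        max_mismatch_fraction=float(params.get("max_mismatch_fraction", 0.1)),
        anchor_k=params.get("anchor_k"),
    )
    report.has_repeats = True


def candidate_pairs_from_dispersed(dispersed, min_repeat_length: int) -> list[RepeatPair]:
    """Recombination candidates: long dispersed pairs, longest first, R1.. ids."""
    cands = sorted(
        (p for p in dispersed if p.length >= min_repeat_length),
        key=lambda p: (-p.length, p.chromosome_1, p.start_1),
    )
    return [
        RepeatPair(
            pair_id=f"R{k}",
            length=p.length,
            identity=p.identity,
            orientation="direct" if p.type == "forward" else "inverted",
            placement_1=(p.chromosome_1, p.start_1, p.end_1),
            placement_2=(p.chromosome_2, p.start_2, p.end_2),
            e_value=p.e_value,
        )
        for k, p in enumerate(cands, start=1)
    ]


@_stage("recombination")
def _run_recombination(
    config: PipelineConfig, seqs: dict[str, str], reads, report: SummaryReport, outdir: Path
):
    params = config.recombination
    flank = int(params.get("flank_length", 1000))
    min_anchor = int(params.get("min_anchor", 200))
    min_identity = float(params.get("min_identity", 0.80))
    min_support = int(params.get("min_support", 2))
    max_depth = int(params.get("max_depth", 2))
    pairs = candidate_pairs_from_dispersed(
        report.dispersed, int(params.get("min_repeat_length", 100))
    )
    rows = []
    quartets = {}
    usable: list[RepeatPair] = []
    tdir = outdir / "templates"
    tdir.mkdir(parents=True, exist_ok=True)
    for pair in pairs:
        try:
            quartet = build_templates(seqs, pair, flank)
        except ValueError as exc:
            logger.warning("pair %s skipped: %s", pair.pair_id, exc)
            continue
        if quartet.unresolvable:
            logger.warning(
                "pair %s has identical flanks on both copies; junctions are "
                "unresolvable by spanning reads", pair.pair_id,
            )
            continue
        mio.write_fasta(
            {f"{pair.pair_id}.{n}": t for n, t in quartet.templates().items()},
            tdir / f"{pair.pair_id}.fasta",
        )
        quartets[pair.pair_id] = quartet
        usable.append(pair)
        rows.append(count_spanning_support(reads, quartet, min_anchor, min_identity))
        logger.info(
            "pair %s: support ref=%d swap=%d (uninformative %d, ties %d)",
            pair.pair_id, rows[-1].ref_total, rows[-1].swap_total,
            rows[-1].n_uninformative, rows[-1].n_ties,
        )
    supp = support_table(rows)
    pair_meta = pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "identity_percent": p.identity,
                "length_bp": p.length,
                "position_1": f"{p.placement_1[0]}:{p.placement_1[1]}-{p.placement_1[2]}",
                "position_2": f"{p.placement_2[0]}:{p.placement_2[1]}-{p.placement_2[2]}",
                "e_value": f"{p.e_value:.3g}",
                "type": "forward" if p.orientation == "direct" else "reverse",
            }
            for p in usable
        ]
    )
    report.repeat_pairs = (
        pair_meta.merge(supp, on="pair_id") if len(pair_meta) else pair_meta
    )
    supported = {
        row.pair_id for row in rows if row.swap_total >= min_support
    }
    plans = _parse_event_plans(params.get("event_plan"))
    if plans is None:
        plans = [EventPlan(pid) for pid in sorted(supported)]
    else:
        plans = [p for p in plans if p.pair_id in supported]
    report.conformations = []
    if usable and reads:
        major, segments = segment_genome(seqs, usable)
        confs = enumerate_conformations(major, plans, segments, max_depth)
        cdir = outdir / "conformations"
        cdir.mkdir(parents=True, exist_ok=True)
        for conf in confs:
            circles = realize_conformation(conf, segments)
            mio.write_fasta(
                {f"{conf.label}.circle{k + 1}": c for k, c in enumerate(circles)},
                cdir / f"{conf.label}.fasta",
            )
            report.conformations.append(
                {
                    "label": conf.label,
                    "n_circles": len(conf.circles),
                    "circle_lengths": ",".join(str(len(c)) for c in circles),
                    "event_path": ">".join(
                        f"{e.pair_id}:{e.mode}" for e in conf.event_path
                    ),
                }
            )
    report.has_conformations = True


@_stage("mtpt")
def _run_mtpt(
    config: PipelineConfig, seqs: dict[str, str], plastid: str | None,
    annotations, report: SummaryReport,
):
    if plastid is None:
        logger.warning("no plastid genome supplied; MTPT stage skipped")
        return
    params = config.mtpt
    raw = mtpt_mod.scan_homology(
        seqs, plastid,
        min_length=int(params.get("min_length", 100)),
        min_identity=float(params.get("min_identity", 70.0)),
    )
    frags = mtpt_mod.merge_fragments(raw)
    if annotations:
        frags = mtpt_mod.annotate_transfers(frags, str(annotations))
    report.mtpt_raw_count = len(raw)
    report.mtpt_fragments = frags
    report.mtpt_stats = mtpt_mod.transfer_stats(frags, sum(len(s) for s in seqs.values()))
    report.has_mtpt = True


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """Run the configured stages in order and write reports + artifacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.synthetic is not None:
        data = _run_synthesize(config, outdir)
    else:
        data = _run_load(config)
    seqs = data["seqs"]
    report = SummaryReport()
    report.chromosome_lengths, report.chromosome_gc = genome_stats(seqs)
    if config.stage_enabled("repeats"):
        _run_repeats(config, seqs, report)
    if config.stage_enabled("recombination"):
        if not config.stage_enabled("repeats"):
            # recombination needs the dispersed-repeat candidates
            report.dispersed = find_dispersed_repeats(seqs)
        _run_recombination(config, seqs, data["reads"], report, outdir)
    if config.stage_enabled("mtpt"):
        _run_mtpt(config, seqs, data.get("plastid"), data.get("annotations"), report)
    write_reports(report, outdir)
    return report


# ---------------------------------------------------------------------------
# paper-like demo configuration


def paper_like_config(seed: int = 42, output_dir: str = "mitorecomb_demo") -> PipelineConfig:
    """Two-circle synthetic replica of the published genome topology.

    Chromosome lengths are the published ones scaled by 1/10 (26,176 +
    14,425 bp; GC 44.43%); the four recombination-active repeat pairs keep
    their published lengths and orientations except the longest, which is
    scaled to fit (982 bp).  R1/R3 are direct cross-circle pairs (fusion),
    R4 is a direct same-circle pair (fission; 12 mismatches over 137 bp,
    identity 91.24%), R2 is an inverted cross-circle pair whose inversion
    acts on the fused products.
    """
    return PipelineConfig(
        seed=seed,
        output_dir=output_dir,
        synthetic=dict(
            chromosome_lengths=[26176, 14425],
            gc_content=0.4443,
            repeats=[
                dict(pair_id="R1", length=982, n_mismatches=0, orientation="direct",
                     placement_1=[0, 2001], placement_2=[1, 2001]),
                dict(pair_id="R2", length=360, n_mismatches=0, orientation="inverted",
                     placement_1=[0, 6001], placement_2=[1, 6001]),
                dict(pair_id="R3", length=211, n_mismatches=0, orientation="direct",
                     placement_1=[0, 10001], placement_2=[1, 10001]),
                dict(pair_id="R4", length=137, n_mismatches=12, orientation="direct",
                     placement_1=[0, 14001], placement_2=[0, 20001]),
            ],
            ssrs=[
                dict(motif="A", copies=12, chromosome=0, start=16001),
                dict(motif="TA", copies=7, chromosome=0, start=16501),
                dict(motif="AAG", copies=5, chromosome=0, start=17001),
                dict(motif="A", copies=14, chromosome=1, start=8001),
                dict(motif="TA", copies=6, chromosome=1, start=8501),
            ],
            tandems=[
                dict(unit_length=20, copies=3, n_substitutions=2, chromosome=0, start=18001),
                dict(unit_length=25, copies=3, n_substitutions=3, chromosome=1, start=9001),
            ],
            transfers=[
                dict(mito_chromosome=0, mito_start=22000, mito_end=23577,
                     plastid_start=2001, n_substitutions=0),
                dict(mito_chromosome=0, mito_start=24100, mito_end=24599,
                     plastid_start=5001, n_substitutions=0),
                dict(mito_chromosome=1, mito_start=12000, mito_end=12399,
                     plastid_start=7001, n_substitutions=0),
                dict(mito_chromosome=1, mito_start=13000, mito_end=13299,
                     plastid_start=9001, n_substitutions=0),
            ],
            plastid_length=15590,
        ),
        reads=dict(
            coverage=40.0, read_length_mean=3000.0, read_length_sd=2000.0,
            per_base_error_rate=0.05, major_weight=0.5,
        ),
        recombination=dict(
            flank_length=1000, min_anchor=200, min_identity=0.80,
            min_support=2, max_depth=2, min_repeat_length=100,
            event_plan=[
                dict(pair="R1", mode="fusion", from_major_only=True),
                dict(pair="R3", mode="fusion", from_major_only=True),
                dict(pair="R4", mode="fission", from_major_only=True),
                dict(pair="R2", mode="inversion"),
            ],
        ),
    )
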