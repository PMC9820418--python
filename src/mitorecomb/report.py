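"""Summary report assembly and writers.

Every number in the report is computed from stage outputs held in the
report object itself; the writers only format.  TSV tables mirror the
layouts a mitogenome structure paper would print (repeat pair table, SSR
class table, conformation inventory, MTPT table); the text summary uses
thousands separators for base counts and two decimals for percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .mtpt import MTPTFragment, TransferStats
from .repeats import (
    DispersedRepeatPair,
    SSRRecord,
    TandemRepeatRecord,
    percent,
    ssr_class_counts,
)


@dataclass
class SummaryReport:
    chromosome_lengths: dict[str, int] = field(default_factory=dict)
    chromosome_gc: dict[str, float] = field(default_factory=dict)
    ssrs: dict[str, list[SSRRecord]] = field(default_factory=dict)
    tandems: list[TandemRepeatRecord] = field(default_factory=list)
    dispersed: list[DispersedRepeatPair] = field(default_factory=list)
    repeat_pairs: pd.DataFrame | None = None  # pair table with support counts
    conformations: list[dict] = field(default_factory=list)
    mtpt_fragments: list[MTPTFragment] | None = None
    mtpt_stats: TransferStats | None = None
    mtpt_raw_count: int | None = None
    has_repeats: bool = False
    has_conformations: bool = False
    has_mtpt: bool = False

    @property
    def total_length(self) -> int:
        return sum(self.chromosome_lengths.values())

    @property
    def total_gc_percent(self) -> float:
        total = self.total_length
        if not total:
            return 0.0
        gc = sum(
            self.chromosome_gc[c] * self.chromosome_lengths[c]
            for c in self.chromosome_lengths
        )
        return round(100.0 * gc / total, 2)


def genome_stats(seqs: dict[str, str]) -> tuple[dict[str, int], dict[str, float]]:
    lengths = {name: len(s) for name, s in seqs.items()}
    gc = {
        name: (s.count("G") + s.count("C")) / len(s) if s else 0.0
        for name, s in seqs.items()
    }
    return lengths, gc


def ssr_class_table(ssrs: dict[str, list[SSRRecord]]) -> pd.DataFrame:
    rows = []
    for chrom in sorted(ssrs):
        counts = ssr_class_counts(ssrs[chrom])
        total = sum(counts.values())
        mono = [r for r in ssrs[chrom] if r.motif_class == "mono"]
        a_mono = sum(1 for r in mono if r.motif == "A")
        rows.append(
            {
                "chromosome": chrom,
                **counts,
                "total": total,
                "mono_di_percent": percent(counts["mono"] + counts["di"], total),
                "a_monomer_percent": percent(a_mono, len(mono)),
            }
        )
    cols = ["chromosome", "mono", "di", "tri", "tetra", "penta", "hexa", "total",
            "mono_di_percent", "a_monomer_percent"]
    return pd.DataFrame(rows, columns=cols)


def dispersed_table(pairs: list[DispersedRepeatPair]) -> pd.DataFrame:
    rows = [
        {
            "identity_percent": p.identity,
            "length_bp": p.length,
            "position_1": f"{p.chromosome_1}:{p.start_1}-{p.end_1}",
            "position_2": f"{p.chromosome_2}:{p.start_2}-{p.end_2}",
            "e_value": f"{p.e_value:.3g}",
            "type": p.type,
        }
        for p in pairs
    ]
    cols = ["identity_percent", "length_bp", "position_1", "position_2", "e_value", "type"]
    return pd.DataFrame(rows, columns=cols)


def conformation_table(conformations: list[dict]) -> pd.DataFrame:
    cols = ["label", "n_circles", "circle_lengths", "event_path"]
    return pd.DataFrame(list(conformations), columns=cols)


def mtpt_table(fragments: list[MTPTFragment]) -> pd.DataFrame:
    cols = ["mito_chromosome", "mito_start", "mito_end", "plastid_start",
            "plastid_end", "strand", "identity_percent", "length_bp", "genes"]
    rows = [
        {
            "mito_chromosome": f.mito_chromosome,
            "mito_start": f.mito_start,
            "mito_end": f.mito_end,
            "plastid_start": f.plastid_start,
            "plastid_end": f.plastid_end,
            "strand": f.strand,
            "identity_percent": f.identity,
            "length_bp": f.length,
            "genes": ",".join(f.genes),
        }
        for f in fragments
    ]
    return pd.DataFrame(rows, columns=cols)


def render_text_summary(report: SummaryReport) -> str:
    lines = ["Genome", "------"]
    for chrom in sorted(report.chromosome_lengths):
        lines.append(
            f"  {chrom}: {report.chromosome_lengths[chrom]:,} bp, "
            f"GC {100.0 * report.chromosome_gc[chrom]:.2f}%"
        )
    lines.append(
        f"  total: {report.total_length:,} bp, GC {report.total_gc_percent:.2f}%"
    )
    if report.has_repeats:
        lines += ["", "Repeats", "-------"]
        total_ssrs = sum(len(v) for v in report.ssrs.values())
        lines.append(f"  SSRs: {total_ssrs}")
        for chrom in sorted(report.ssrs):
            counts = ssr_class_counts(report.ssrs[chrom])
            lines.append(
                f"    {chrom}: {len(report.ssrs[chrom])} "
                f"({', '.join(f'{k} {v}' for k, v in counts.items() if v)})"
            )
        lines.append(f"  tandem repeats: {len(report.tandems)}")
        fwd = sum(1 for p in report.dispersed if p.type == "forward")
        pal = sum(1 for p in report.dispersed if p.type == "palindromic")
        lines.append(
            f"  dispersed repeat pairs (>= threshold): {len(report.dispersed)} "
            f"({fwd} forward, {pal} palindromic)"
        )
    if report.has_conformations:
        lines += ["", "Conformations", "-------------"]
        if report.repeat_pairs is not None and len(report.repeat_pairs):
            lines.append(
                f"  recombination-candidate repeat pairs: {len(report.repeat_pairs)}"
            )
        n_minor = sum(1 for c in report.conformations if c["label"] != "major")
        if report.conformations:
            lines.append(f"  1 major conformation and {n_minor} minor conformations")
        for conf in report.conformations:
            path = conf["event_path"] or "-"
            lines.append(
                f"    {conf['label']}: {conf['n_circles']} circle(s), events: {path}"
            )
    if report.has_mtpt and report.mtpt_stats is not None:
        st = report.mtpt_stats
        lines += ["", "MTPT", "----"]
        if report.mtpt_raw_count is not None:
            lines.append(f"  raw homologous matches: {report.mtpt_raw_count}")
        lines.append(
            f"  merged fragments: {st.fragment_count}, total {st.total_length:,} bp "
            f"({st.fraction_percent:.2f}% of the mitogenome)"
        )
        lines.append(
            f"  fragments > 1,000 bp: {st.count_over_1kb}; longest {st.longest:,} bp"
        )
    return "\n".join(lines) + "\n"


def write_reports(
    report: SummaryReport, outdir: str | Path, formats: tuple[str, ...] = ("tsv", "txt")
) -> list[Path]:
    """Write TSV tables and the text summary; returns the files written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    if "tsv" in formats:
        if report.has_repeats:
            _write(ssr_class_table(report.ssrs), "ssr_classes.tsv")
            ssr_rows = [
                {
                    "chromosome": r.chromosome, "motif": r.motif, "copies": r.copies,
                    "start": r.start, "end": r.end, "class": r.motif_class,
                }
                for chrom in sorted(report.ssrs) for r in report.ssrs[chrom]
            ]
            _write(
                pd.DataFrame(
                    ssr_rows,
                    columns=["chromosome", "motif", "copies", "start", "end", "class"],
                ),
                "ssr_records.tsv",
            )
            _write(
                pd.DataFrame(
                    [
                        {
                            "chromosome": t.chromosome, "unit_length": t.unit_length,
                            "copy_number": t.copy_number, "start": t.start,
                            "end": t.end, "percent_matches": t.percent_matches,
                            "consensus": t.unit_consensus,
                        }
                        for t in report.tandems
                    ],
                    columns=["chromosome", "unit_length", "copy_number", "start",
                             "end", "percent_matches", "consensus"],
                ),
                "tandem_repeats.tsv",
            )
            _write(dispersed_table(report.dispersed), "dispersed_repeats.tsv")
        if report.has_conformations:
            if report.repeat_pairs is not None:
                _write(report.repeat_pairs, "repeat_pairs.tsv")
            _write(conformation_table(report.conformations), "conformations.tsv")
        if report.has_mtpt and report.mtpt_fragments is not None:
            _write(mtpt_table(report.mtpt_fragments), "mtpt_fragments.tsv")
    if "txt" in formats:
        path = outdir / "summary.txt"
        path.write_text(render_text_summary(report))
        written.append(path)
    return written
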