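"""Evaluation orchestration and report rendering.

``run_evaluation`` drives the whole method: parse both annotations, join
by gene ID, compute the per-chromosome metrics, and write the report
files — one TXT per reference chromosome (sections i/ii/iii), merged
assembly–reference GFFs, per-chromosome TSVs of divergent adjacencies,
and a machine-readable JSON summary.  Reports contain no timestamps, so
re-running with identical inputs reproduces them byte for byte.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import contiguity as ctg
from .core import (
    ChromosomeReport,
    DEFAULT_DIVERGENCE_THRESHOLD,
    DEFAULT_ORIENTATION_THRESHOLD,
    find_misplacements,
    match_genes,
    ordered_target_seqs,
    summarize_chromosome,
)
from .errors import CollinearityQCError, ConfigError
from .io import parse_gff, write_merged_gff

logger = logging.getLogger("collinearity_qc")


@dataclass
class EvalConfig:
    """Inputs and thresholds of one evaluation run.

    ``divergence_threshold`` (bp, strict) flags adjacent-gene distance
    divergence; ``orientation_threshold`` (inclusive) is the minimum
    fraction of ordered coordinate steps for a forward/reverse call.
    ``exclude_seqids`` drops sequences (typically organelles) from both
    inputs before matching.
    """

    reference_gff: Path
    target_gff: Path
    outdir: Path
    target_fasta: Optional[Path] = None
    orientation_threshold: float = DEFAULT_ORIENTATION_THRESHOLD
    divergence_threshold: int = DEFAULT_DIVERGENCE_THRESHOLD
    id_attribute: str = "ID"
    exclude_seqids: Sequence[str] = field(default_factory=list)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.orientation_threshold <= 1:
            raise ConfigError(
                f"orientation_threshold must be in (0, 1]: {self.orientation_threshold}"
            )
        if self.divergence_threshold < 0:
            raise ConfigError(
                f"divergence_threshold must be >= 0: {self.divergence_threshold}"
            )
        self.reference_gff = Path(self.reference_gff)
        self.target_gff = Path(self.target_gff)
        self.outdir = Path(self.outdir)
        if self.target_fasta is not None:
            self.target_fasta = Path(self.target_fasta)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "EvalConfig":
        """Load a config file; keyword overrides win over file values."""
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _fmt(x: float) -> str:
    return "n/a" if math.isnan(x) else f"{x:.3f}"


def render_chromosome_report(summary: ChromosomeReport) -> str:
    """Render the three-section TXT report for one reference chromosome.

    Target sequences are listed by descending matched-gene count (ties
    lexicographic); fractions are printed to 3 decimals.
    """
    lines = [f"# reference chromosome {summary.ref_chrom}", ""]
    lines.append("## i. corresponding target sequences")
    for seq in ordered_target_seqs(summary.correspondence):
        lines.append(f"{seq}\t{summary.correspondence[seq]} genes")
    lines.append("")
    lines.append("## ii. orientation of target sequences")
    for call in summary.orientations:
        lines.append(
            f"{call.target_seq}\t{call.call}\t"
            f"ascending={_fmt(call.frac_ascending)}\t"
            f"descending={_fmt(call.frac_descending)}\t"
            f"n_genes={call.n_genes}\tn_comparisons={call.n_comparisons}"
        )
    lines.append("")
    lines.append("## iii. adjacent-gene distance coherence")
    lines.append(f"compared_pairs\t{summary.n_compared}")
    lines.append(f"broken_pairs\t{summary.n_broken}")
    lines.append(f"coherent_pairs\t{summary.n_coherent}")
    lines.append(f"coherent_fraction\t{_fmt(summary.coherent_fraction)}")
    lines.append("")
    lines.append(f"misplaced_genes\t{len(summary.misplacements)}")
    for m in summary.misplacements:
        lines.append(
            f"{m.gene_id}\t{m.ref_chrom}\ton={m.target_seq}\t"
            f"dominant={m.dominant_chrom}"
        )
    return "\n".join(lines) + "\n"


def _write_divergent_tsv(summary: ChromosomeReport, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("gene_a\tgene_b\tref_gap\ttgt_gap\tdivergence\n")
        for adj in summary.adjacencies:
            if adj.status == "compared" and not adj.coherent:
                fh.write(
                    f"{adj.gene_a}\t{adj.gene_b}\t{adj.ref_gap}\t"
                    f"{adj.tgt_gap}\t{adj.divergence}\n"
                )


def _json_summary(config: EvalConfig, matched, reports: dict[str, ChromosomeReport]) -> dict:
    table = {
        chrom: rep.correspondence for chrom, rep in reports.items()
    }
    misplacements = find_misplacements(matched)
    n_compared = sum(r.n_compared for r in reports.values())
    n_coherent = sum(r.n_coherent for r in reports.values())
    summary = {
        "thresholds": {
            "orientation": config.orientation_threshold,
            "divergence_bp": config.divergence_threshold,
        },
        "genes": {
            "matched": len(matched),
            "reference_only": len(matched.ref_only),
            "target_only": len(matched.tgt_only),
            "duplicates_dropped": matched.duplicates_dropped,
        },
        "correspondence": table,
        "scaffolds_per_chromosome": {
            chrom: len(row) for chrom, row in table.items()
        },
        "orientation": {
            chrom: {
                call.target_seq: {
                    "call": call.call,
                    "frac_ascending": call.frac_ascending,
                    "frac_descending": call.frac_descending,
                    "n_genes": call.n_genes,
                }
                for call in rep.orientations
            }
            for chrom, rep in reports.items()
        },
        "coherence": {
            "per_chromosome": {
                chrom: {
                    "compared": rep.n_compared,
                    "broken": rep.n_broken,
                    "coherent": rep.n_coherent,
                    "coherent_fraction": None if math.isnan(rep.coherent_fraction)
                    else rep.coherent_fraction,
                }
                for chrom, rep in reports.items()
            },
            "overall_coherent_fraction": None if n_compared == 0
            else n_coherent / n_compared,
        },
        "misplacements": [
            {
                "gene_id": m.gene_id,
                "ref_chrom": m.ref_chrom,
                "target_seq": m.target_seq,
                "dominant_chrom": m.dominant_chrom,
                "dominant_fraction": m.dominant_fraction,
            }
            for m in misplacements
        ],
    }
    return summary


def run_evaluation(config: EvalConfig) -> dict:
    """Run the full evaluation and write all report files under ``outdir``.

    Returns the JSON-summary dict.  On any error, files written during
    this run are removed before the exception propagates.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        ref = parse_gff(
            config.reference_gff, id_attribute=config.id_attribute,
            exclude_seqids=config.exclude_seqids, source_tag="reference",
        )
        tgt = parse_gff(
            config.target_gff, id_attribute=config.id_attribute,
            exclude_seqids=config.exclude_seqids, source_tag="target",
        )
        matched = match_genes(ref, tgt)

        reports: dict[str, ChromosomeReport] = {}
        for chrom in matched.ref_chromosomes():
            rep = summarize_chromosome(
                matched, chrom,
                orientation_threshold=config.orientation_threshold,
                divergence_threshold=config.divergence_threshold,
            )
            reports[chrom] = rep
            txt = config.outdir / f"{chrom}_report.txt"
            txt.write_text(render_chromosome_report(rep))
            written.append(txt)
            tsv = config.outdir / f"{chrom}_divergent.tsv"
            _write_divergent_tsv(rep, tsv)
            written.append(tsv)

        written.extend(
            write_merged_gff(matched, config.outdir / "merged.gff", per_chromosome=True)
        )

        summary = _json_summary(config, matched, reports)
        if config.target_fasta is not None:
            lengths = ctg.read_lengths(config.target_fasta)
            summary["contiguity"] = ctg.contiguity_stats(lengths).as_dict()
            curve = ctg.cumulative_curve(lengths)
            summary["cumulative_curve"] = curve
            curve_tsv = config.outdir / "cumulative_curve.tsv"
            ctg.write_curve_tsv(curve, curve_tsv)
            written.append(curve_tsv)

        json_path = config.outdir / "summary.json"
        with json_path.open("w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(json_path)
        logger.info("evaluation complete: %d files under %s", len(written), config.outdir)
        return summary
    except CollinearityQCError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
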