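"""Gene-level GFF3 reading, filtering, and writing.

The collinearity method operates on gene features only: mRNA, exon and
other child features are discarded at parse time, and each surviving
feature is reduced to a :class:`GeneRecord` keyed by its ``ID`` attribute.
Lift-over tools such as Liftoff copy reference gene IDs into the target
annotation, so the shared ID is what later joins the two genomes.

Coordinates are GFF3-native throughout: 1-based, inclusive on both ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

from .errors import EmptyAnnotationError, InputError, OutputError

logger = logging.getLogger("collinearity_qc")

GFF_HEADER = "##gff-version 3"

#: feature types retained by default; widen via ``feature_types`` to pick up
#: e.g. "pseudogene" or "ncRNA_gene" if the annotation uses them
DEFAULT_FEATURE_TYPES = ("gene",)


@dataclass(frozen=True, order=True)
class GeneRecord:
    """One gene feature: identifier, location, strand and genome of origin.

    ``start``/``end`` are 1-based inclusive base-pair coordinates.
    ``source_tag`` is ``"reference"`` or ``"target"`` and records which
    genome the feature was read from.
    """

    seq_id: str
    start: int
    end: int
    gene_id: str
    strand: str = "."
    source_tag: str = "reference"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid coordinates for {self.gene_id}: "
                f"start={self.start}, end={self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotationSet:
    """A deduplicated, per-sequence-sorted collection of gene records.

    Records are kept sorted by (seq_id, start, end, gene_id); each gene_id
    appears exactly once.  ``duplicates_dropped`` and ``skipped_no_id``
    carry parse-time bookkeeping for downstream reporting.
    """

    genome_label: str
    records: list[GeneRecord] = field(default_factory=list)
    duplicates_dropped: int = 0
    skipped_no_id: int = 0

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records, key=lambda r: (r.seq_id, r.start, r.end, r.gene_id)
        )
        self._by_id = {r.gene_id: r for r in self.records}
        if len(self._by_id) != len(self.records):
            raise ValueError(f"duplicate gene_ids in AnnotationSet {self.genome_label!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def by_id(self) -> Mapping[str, GeneRecord]:
        return self._by_id

    def seq_ids(self) -> list[str]:
        """Distinct sequence names, sorted."""
        return sorted({r.seq_id for r in self.records})

    def on_seq(self, seq_id: str) -> list[GeneRecord]:
        """Records on one sequence, in ascending start order."""
        return [r for r in self.records if r.seq_id == seq_id]


def parse_gff(
    path: str | Path,
    id_attribute: str = "ID",
    exclude_seqids: Iterable[str] = (),
    source_tag: str = "reference",
    feature_types: Sequence[str] = DEFAULT_FEATURE_TYPES,
) -> AnnotationSet:
    """Read a GFF3 file down to its gene features.

    Only features whose type is in ``feature_types`` (default: literal
    ``gene``) are kept; features on sequences named in ``exclude_seqids``
    (e.g. organelles) are dropped.  The gene identifier is taken from
    ``id_attribute`` with any ``gene:`` prefix stripped.  When the same
    gene_id occurs more than once, the first occurrence in file order wins
    and each later copy is logged and counted.

    Raises
    ------
    InputError
        if the file does not exist.
    EmptyAnnotationError
        if no gene feature survives filtering.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    excluded = set(exclude_seqids)
    wanted = set(feature_types)

    records: list[GeneRecord] = []
    seen: set[str] = set()
    n_dup = 0
    n_no_id = 0
    for feat in gffutils.DataIterator(str(path)):
        if feat.featuretype not in wanted:
            continue
        if feat.seqid in excluded:
            continue
        values = feat.attributes.get(id_attribute, [])
        if not values or not values[0]:
            n_no_id += 1
            logger.warning(
                "skipped gene line without %r attribute at %s:%s-%s",
                id_attribute, feat.seqid, feat.start, feat.end,
            )
            continue
        gene_id = values[0].removeprefix("gene:")
        if gene_id in seen:
            n_dup += 1
            logger.warning("duplicate gene_id %r in %s: keeping first occurrence", gene_id, path)
            continue
        seen.add(gene_id)
        records.append(
            GeneRecord(
                seq_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                gene_id=gene_id,
                strand=feat.strand if feat.strand in ("+", "-") else ".",
                source_tag=source_tag,
            )
        )
    if not records:
        raise EmptyAnnotationError(f"no gene features after filtering in {path}")
    logger.info(
        "parsed %s: %d genes, %d duplicates dropped, %d id-less lines skipped",
        path, len(records), n_dup, n_no_id,
    )
    return AnnotationSet(
        genome_label=source_tag,
        records=records,
        duplicates_dropped=n_dup,
        skipped_no_id=n_no_id,
    )


def _gff_line(rec: GeneRecord) -> str:
    return "\t".join(
        (
            rec.seq_id,
            rec.source_tag,
            "gene",
            str(rec.start),
            str(rec.end),
            ".",
            rec.strand,
            ".",
            f"ID={rec.gene_id}",
        )
    )


def write_annotation_gff(annotation: AnnotationSet, path: str | Path) -> Path:
    """Write an AnnotationSet back out as minimal gene-only GFF3."""
    path = Path(path)
    try:
        with path.open("w") as fh:
            fh.write(GFF_HEADER + "\n")
            for rec in annotation.records:
                fh.write(_gff_line(rec) + "\n")
    except OSError as exc:
        raise OutputError(f"cannot write {path}: {exc}") from exc
    return path


def write_merged_gff(matched, out_path: str | Path, per_chromosome: bool = False) -> list[Path]:
    """Write the merged assembly-reference GFF output.

    For every matched gene, two consecutive GFF3 lines are emitted — the
    reference record then the target record — grouped by reference
    chromosome and ordered by reference start.  With ``per_chromosome``,
    one extra file per reference chromosome is written next to the
    whole-genome file (``<stem>_<chrom><suffix>``).  Returns the list of
    written paths, whole-genome file first.
    """
    # imported here to avoid a module cycle: core consumes AnnotationSet
    from .core import MatchedSet

    if not isinstance(matched, MatchedSet) or not matched.pairs:
        raise InputError("write_merged_gff requires a non-empty MatchedSet")

    out_path = Path(out_path)
    ordered = sorted(
        matched.pairs.values(),
        key=lambda p: (p.ref.seq_id, p.ref.start, p.ref.end, p.gene_id),
    )

    def _write(path: Path, pairs) -> Path:
        try:
            with path.open("w") as fh:
                fh.write(GFF_HEADER + "\n")
                for pair in pairs:
                    fh.write(_gff_line(pair.ref) + "\n")
                    fh.write(_gff_line(pair.tgt) + "\n")
        except OSError as exc:
            raise OutputError(f"cannot write {path}: {exc}") from exc
        return path

    written = [_write(out_path, ordered)]
    if per_chromosome:
        for chrom in sorted({p.ref.seq_id for p in ordered}):
            sub = [p for p in ordered if p.ref.seq_id == chrom]
            path = out_path.with_name(f"{out_path.stem}_{chrom}{out_path.suffix}")
            written.append(_write(path, sub))
    return written
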