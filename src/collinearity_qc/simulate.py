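"""Synthetic annotations with known structural ground truth.

The generator builds a multi-chromosome reference gene annotation and a
"lifted-over" target annotation derived from it by the rearrangement
classes that scaffolding can introduce or inherit: chromosome *splits*
(fragmentation into contigs), *fusions* (false joints merging fragments
into one scaffold), *inversions* (fragments laid down in reverse
orientation), *translocations* (single genes moved into another
chromosome's fragment — the misplacement signal), per-gap coordinate
*jitter* (lift-over imprecision), and random gene *drops* (failed
lift-overs).

Rearrangements are applied in a fixed, documented order —
split -> translocate -> fuse -> invert -> jitter -> drop — so that the
accompanying :class:`TruthTable` (expected orientation calls, dominant
chromosomes, misplaced genes, broken adjacencies, per-adjacency
divergences) is well defined.  Every quantity in the truth table is
computed from the generator's own layout bookkeeping, independent of the
metric implementations it is used to test.

Fragments are named ``<chrom>.f<j>`` in left-to-right order (an unsplit
chromosome is its own single fragment ``<chrom>.f1``); target scaffolds
are named ``scaffold_1..k``, fused groups first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .io import AnnotationSet, GeneRecord, write_annotation_gff

ORIENTATION_THRESHOLD = 0.9  # matches the collinearity classifier default


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic rearrangement scenario.

    Defaults emulate a small plant-like genome: 5 chromosomes of 40 genes
    each, gene lengths 0.5–5 kb and intergenic gaps 0.2–4 kb (roughly one
    gene per 4–5 kb, the gene density of a compact plant genome), no
    rearrangements, no jitter, no drops.
    """

    n_chromosomes: int = 5
    genes_per_chromosome: int = 40
    gene_length_range: tuple[int, int] = (500, 5000)
    gap_length_range: tuple[int, int] = (200, 4000)
    #: chromosome -> breakpoint indices; index k breaks after the k-th gene
    split_points: Mapping[str, Sequence[int]] = field(default_factory=dict)
    #: ordered fragment-name groups, each fused into one scaffold
    fusions: Sequence[Sequence[str]] = ()
    #: fragment names laid down in reverse coordinate order
    inversions: frozenset[str] | set[str] = frozenset()
    #: (gene_id, destination fragment, insertion index within the fragment)
    translocations: Sequence[tuple[str, str, int]] = ()
    gap_jitter_sd: float = 0.0
    drop_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name, (lo, hi) in (
            ("gene_length_range", self.gene_length_range),
            ("gap_length_range", self.gap_length_range),
        ):
            if lo < 1 or lo > hi:
                raise ConfigError(f"{name} must satisfy 1 <= min <= max: ({lo}, {hi})")
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ConfigError("need at least 1 chromosome and 1 gene per chromosome")
        if not 0 <= self.drop_fraction < 1:
            raise ConfigError(f"drop_fraction must be in [0, 1): {self.drop_fraction}")
        if self.gap_jitter_sd < 0:
            raise ConfigError(f"gap_jitter_sd must be >= 0: {self.gap_jitter_sd}")
        for chrom, points in self.split_points.items():
            for k in points:
                if not 0 < k < self.genes_per_chromosome:
                    raise ConfigError(
                        f"split point {k} on {chrom} outside (0, "
                        f"{self.genes_per_chromosome})"
                    )


@dataclass
class TruthTable:
    """Ground truth of one scenario, keyed the way the metrics report.

    ``expected_orientation`` maps ``(ref_chrom, scaffold)`` to the call the
    orientation classifier should make; ``expected_dominant`` maps each
    scaffold to its majority source chromosome; ``expected_misplaced`` is
    the set of genes sitting on a scaffold dominated by another
    chromosome; ``expected_broken`` counts reference-adjacent matched
    pairs split across scaffolds; ``expected_divergence`` gives
    |target gap - reference gap| for every same-scaffold adjacency.
    """

    scaffold_sources: dict[str, list[dict]]
    expected_orientation: dict[tuple[str, str], str]
    expected_dominant: dict[str, str]
    expected_misplaced: set[str]
    translocated: set[str]
    dropped: set[str]
    expected_broken: int
    expected_divergence: dict[tuple[str, str], int]

    def to_jsonable(self) -> dict:
        return {
            "scaffold_sources": self.scaffold_sources,
            "expected_orientation": {
                f"{c}|{s}": call for (c, s), call in sorted(self.expected_orientation.items())
            },
            "expected_dominant": self.expected_dominant,
            "expected_misplaced": sorted(self.expected_misplaced),
            "translocated": sorted(self.translocated),
            "dropped": sorted(self.dropped),
            "expected_broken": self.expected_broken,
            "expected_divergence": {
                f"{a}|{b}": d for (a, b), d in sorted(self.expected_divergence.items())
            },
        }


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def _gene_name(chrom: str, idx: int) -> str:
    return f"{chrom}_g{idx + 1:03d}"


def build_reference(config: ScenarioConfig) -> AnnotationSet:
    """Deterministically draw a reference annotation from the scenario.

    Gene lengths and intergenic gaps are uniform over the configured
    ranges; coordinates are strictly increasing and non-overlapping
    within each chromosome.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    records: list[GeneRecord] = []
    for c in range(config.n_chromosomes):
        chrom = _chrom_name(c)
        cur = 1
        for g in range(config.genes_per_chromosome):
            length = int(rng.integers(config.gene_length_range[0],
                                      config.gene_length_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(GeneRecord(
                seq_id=chrom, start=cur, end=cur + length - 1,
                gene_id=_gene_name(chrom, g), strand=strand,
                source_tag="reference",
            ))
            gap = int(rng.integers(config.gap_length_range[0],
                                   config.gap_length_range[1] + 1))
            cur += length + gap
    return AnnotationSet(genome_label="reference", records=records)


@dataclass
class _Fragment:
    name: str
    chrom: str
    index_range: tuple[int, int]  # 0-based inclusive gene-index span at split time
    genes: list[str]
    inverted: bool = False


def _split_fragments(reference: AnnotationSet, config: ScenarioConfig) -> list[_Fragment]:
    fragments: list[_Fragment] = []
    for chrom in reference.seq_ids():
        genes = [r.gene_id for r in reference.on_seq(chrom)]
        points = sorted(config.split_points.get(chrom, ()))
        for k in points:
            if not 0 < k < len(genes):
                raise ConfigError(f"split point {k} on {chrom} outside (0, {len(genes)})")
        bounds = [0, *points, len(genes)]
        for j, (lo, hi) in enumerate(zip(bounds, bounds[1:]), start=1):
            fragments.append(_Fragment(
                name=f"{chrom}.f{j}", chrom=chrom,
                index_range=(lo, hi - 1), genes=genes[lo:hi],
            ))
    return fragments


def rearrange(reference: AnnotationSet, config: ScenarioConfig
              ) -> tuple[AnnotationSet, TruthTable]:
    """Derive the target annotation and its ground truth from a reference.

    The reference must cover every chromosome named in ``split_points``,
    ``fusions`` and ``translocations`` (normally it comes from
    :func:`build_reference` with the same config).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    ref_by_id = reference.by_id

    # reference bookkeeping: per-gene chromosome index and per-adjacency gaps
    ref_index: dict[str, tuple[str, int]] = {}
    for chrom in reference.seq_ids():
        for i, rec in enumerate(reference.on_seq(chrom)):
            ref_index[rec.gene_id] = (chrom, i)

    # 1. split
    fragments = _split_fragments(reference, config)
    frag_by_name = {f.name: f for f in fragments}

    # 2. translocate
    translocated: set[str] = set()
    for gene_id, dest, idx in config.translocations:
        if gene_id not in ref_by_id:
            raise ConfigError(f"translocation references unknown gene {gene_id!r}")
        if dest not in frag_by_name:
            raise ConfigError(f"translocation references unknown fragment {dest!r}")
        source = next((f for f in fragments if gene_id in f.genes), None)
        if source is None:
            raise ConfigError(f"gene {gene_id!r} already moved or missing")
        source.genes.remove(gene_id)
        dest_frag = frag_by_name[dest]
        if not 0 <= idx <= len(dest_frag.genes):
            raise ConfigError(
                f"insertion index {idx} outside [0, {len(dest_frag.genes)}] in {dest!r}"
            )
        dest_frag.genes.insert(idx, gene_id)
        translocated.add(gene_id)

    # 3. fuse -> scaffolds (fused groups first, leftovers in fragment order)
    used: set[str] = set()
    scaffold_frags: list[list[_Fragment]] = []
    for group in config.fusions:
        members = []
        for name in group:
            if name not in frag_by_name:
                raise ConfigError(f"fusion references unknown fragment {name!r}")
            if name in used:
                raise ConfigError(f"fragment {name!r} fused twice")
            used.add(name)
            members.append(frag_by_name[name])
        scaffold_frags.append(members)
    for frag in fragments:
        if frag.name not in used:
            scaffold_frags.append([frag])

    # 4. invert
    unknown = set(config.inversions) - set(frag_by_name)
    if unknown:
        raise ConfigError(f"inversion references unknown fragments: {sorted(unknown)}")
    for frag in fragments:
        if frag.name in config.inversions:
            frag.genes.reverse()
            frag.inverted = True

    # reference gaps between chromosome-adjacent genes, for layout reuse
    def ref_gap_between(u: str, v: str) -> int | None:
        cu, iu = ref_index[u]
        cv, iv = ref_index[v]
        if cu != cv or abs(iu - iv) != 1:
            return None
        first = u if iu < iv else v
        second = v if iu < iv else u
        return ref_by_id[second].start - ref_by_id[first].end - 1

    # 5. lay out coordinates (with jitter), scaffold per scaffold
    def draw_gap() -> int:
        return int(rng.integers(config.gap_length_range[0],
                                config.gap_length_range[1] + 1))

    placement: dict[str, tuple[str, int, int]] = {}  # gene -> (scaffold, start, end)
    scaffold_order: dict[str, list[str]] = {}
    scaffold_names: dict[str, str] = {}  # fragment -> scaffold
    for s, members in enumerate(scaffold_frags, start=1):
        scaffold = f"scaffold_{s}"
        layout = [g for frag in members for g in frag.genes]
        scaffold_order[scaffold] = layout
        for frag in members:
            scaffold_names[frag.name] = scaffold
        cur = 1
        prev: str | None = None
        for gene in layout:
            if prev is not None:
                gap = ref_gap_between(prev, gene)
                if gap is None or gap < 0:
                    gap = draw_gap()  # fusion boundary or translocation seam
                if config.gap_jitter_sd > 0:
                    gap = max(0, gap + round(rng.normal(0.0, config.gap_jitter_sd)))
                cur += gap
            length = ref_by_id[gene].length
            placement[gene] = (scaffold, cur, cur + length - 1)
            cur = cur + length  # end + 1; the next gap is added on top
            prev = gene

    # 6. drop (never a translocated gene, so truth sets stay disjoint)
    all_genes = [g for layout in scaffold_order.values() for g in layout]
    pool = sorted(set(all_genes) - translocated)
    n_drop = int(round(config.drop_fraction * len(all_genes)))
    n_drop = min(n_drop, len(pool))
    dropped = set(rng.choice(pool, size=n_drop, replace=False)) if n_drop else set()
    dropped = {str(g) for g in dropped}

    frag_of_gene = {g: f for f in fragments for g in f.genes}
    records = []
    for gene, (scaffold, start, end) in placement.items():
        if gene in dropped:
            continue
        ref_rec = ref_by_id[gene]
        strand = ref_rec.strand
        if frag_of_gene[gene].inverted and strand in ("+", "-"):
            strand = "-" if strand == "+" else "+"
        records.append(GeneRecord(
            seq_id=scaffold, start=start, end=end, gene_id=gene,
            strand=strand, source_tag="target",
        ))
    target = AnnotationSet(genome_label="target", records=records)

    truth = _ground_truth(
        reference, config, fragments, scaffold_order, scaffold_names,
        placement, translocated, dropped, ref_index,
    )
    return target, truth


def _ground_truth(
    reference: AnnotationSet,
    config: ScenarioConfig,
    fragments: list[_Fragment],
    scaffold_order: dict[str, list[str]],
    scaffold_names: dict[str, str],
    placement: dict[str, tuple[str, int, int]],
    translocated: set[str],
    dropped: set[str],
    ref_index: dict[str, tuple[str, int]],
) -> TruthTable:
    """Brute-force expectations from the generator's layout bookkeeping."""
    ref_by_id = reference.by_id
    kept = lambda g: g not in dropped

    scaffold_sources: dict[str, list[dict]] = {s: [] for s in scaffold_order}
    for frag in fragments:
        scaffold_sources[scaffold_names[frag.name]].append({
            "fragment": frag.name,
            "chrom": frag.chrom,
            "index_range": list(frag.index_range),
            "inverted": frag.inverted,
        })

    # dominant chromosome per scaffold (kept genes; lexicographic tie-break)
    expected_dominant: dict[str, str] = {}
    expected_misplaced: set[str] = set()
    for scaffold, layout in scaffold_order.items():
        genes = [g for g in layout if kept(g)]
        if not genes:
            continue
        counts: dict[str, int] = {}
        for g in genes:
            counts[ref_index[g][0]] = counts.get(ref_index[g][0], 0) + 1
        best = max(counts.values())
        dominant = min(c for c, n in counts.items() if n == best)
        expected_dominant[scaffold] = dominant
        expected_misplaced.update(g for g in genes if ref_index[g][0] != dominant)

    # orientation per (chromosome, scaffold): signs of consecutive layout
    # positions of the chromosome's kept genes, taken in reference order
    expected_orientation: dict[tuple[str, str], str] = {}
    for scaffold, layout in scaffold_order.items():
        pos = {g: i for i, g in enumerate(layout)}
        chroms = sorted({ref_index[g][0] for g in layout if kept(g)})
        for chrom in chroms:
            group = sorted(
                (g for g in layout if kept(g) and ref_index[g][0] == chrom),
                key=lambda g: ref_index[g][1],
            )
            if len(group) < 2:
                expected_orientation[(chrom, scaffold)] = "single"
                continue
            diffs = [pos[b] - pos[a] for a, b in zip(group, group[1:])]
            n_up = sum(1 for d in diffs if d > 0)
            n_down = sum(1 for d in diffs if d < 0)
            frac_up, frac_down = n_up / len(diffs), n_down / len(diffs)
            if frac_up >= ORIENTATION_THRESHOLD:
                call = "forward"
            elif frac_down >= ORIENTATION_THRESHOLD:
                call = "reverse"
            else:
                call = "unclear"
            expected_orientation[(chrom, scaffold)] = call

    # adjacency fate: consecutive kept genes in reference order per chromosome
    expected_broken = 0
    expected_divergence: dict[tuple[str, str], int] = {}
    for chrom in reference.seq_ids():
        genes = [r.gene_id for r in reference.on_seq(chrom) if kept(r.gene_id)]
        for a, b in zip(genes, genes[1:]):
            sa, sb = placement[a][0], placement[b][0]
            if sa != sb:
                expected_broken += 1
                continue
            ref_gap = ref_by_id[b].start - ref_by_id[a].end - 1
            (_, astart, aend), (_, bstart, bend) = placement[a], placement[b]
            if astart <= bstart:
                tgt_gap = bstart - aend - 1
            else:
                tgt_gap = astart - bend - 1
            expected_divergence[(a, b)] = abs(tgt_gap - ref_gap)

    return TruthTable(
        scaffold_sources=scaffold_sources,
        expected_orientation=expected_orientation,
        expected_dominant=expected_dominant,
        expected_misplaced=expected_misplaced,
        translocated=translocated,
        dropped=dropped,
        expected_broken=expected_broken,
        expected_divergence=expected_divergence,
    )


def demo_scenario(seed: int = 0, gap_jitter_sd: float = 0.0,
                  drop_fraction: float = 0.05) -> ScenarioConfig:
    """A scenario exercising every rearrangement class at once.

    chr1 is split into two contigs; two chr3 genes are translocated into
    the chr2 fragment (misplacements); the distal chr3 fragment is fused
    to chr4 (a false joint); chr5 is wholly inverted.
    """
    return ScenarioConfig(
        split_points={"chr1": [20], "chr3": [30]},
        translocations=[
            ("chr3_g005", "chr2.f1", 10),
            ("chr3_g012", "chr2.f1", 25),
        ],
        fusions=[["chr3.f2", "chr4.f1"]],
        inversions={"chr5.f1"},
        gap_jitter_sd=gap_jitter_sd,
        drop_fraction=drop_fraction,
        seed=seed,
    )


def write_scenario(reference: AnnotationSet, target: AnnotationSet,
                   truth: TruthTable, outdir: str | Path) -> dict[str, Path]:
    """Write reference.gff, target.gff and truth.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_gff": write_annotation_gff(reference, outdir / "reference.gff"),
        "target_gff": write_annotation_gff(target, outdir / "target.gff"),
        "truth_json": outdir / "truth.json",
    }
    with paths["truth_json"].open("w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
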