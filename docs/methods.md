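# Methods

## The evaluation model

The package treats structural correctness of an assembly as a property of
the *gene collinearity relation* between two annotations: the reference
GFF3 and a target GFF3 produced by lifting the reference annotation onto
the assembly. Because lift-over tools such as Liftoff carry reference
gene IDs into their output, the shared ID is a reliable join key; the
method never aligns sequence. Only features of type `gene` are used —
transcript and exon children add no positional information at the scale
of interest and are discarded at parse time (the retained type list is
configurable for annotations that use `pseudogene` etc.). Coordinates are
GFF3-native (1-based, inclusive) end to end; no conversion means no
off-by-one risk.

After the join, four metrics are computed on the matched genes. All
adjacency and ordering is defined **on the reference among matched genes
only**: a gene the lift-over dropped shortens the chain instead of
breaking it, because failed lift-overs are common and are not structural
errors of the assembly.

**Correspondence.** For each reference chromosome, the matched-gene count
on every target sequence. The number of corresponding sequences per
chromosome is the fragmentation/fusion statistic.

**Orientation.** Genes of one (reference chromosome, target sequence)
group are sorted by reference start (start is the conventional anchor
coordinate; ties broken by end, then ID) and the signs of consecutive
target-start differences are counted. Measuring over consecutive steps
rather than over genes makes the statistic locally sensitive to
inversions; equal target starts are excluded from both numerator and
denominator since they carry no order information. The call is *forward*
when the ascending fraction is ≥ 0.9 (inclusive — "at least 90%"),
*reverse* symmetrically, *single* when fewer than two comparable genes
remain, else *unclear*.

**Distance coherence.** The intergenic gap is `next.start − prev.end − 1`,
signed, so overlapping genes stay well defined (negative gap). For a
reference-adjacent pair on a single target sequence, the target gap is
measured between the two genes ordered by target start; divergence is the
absolute difference of the signed gaps, and the pair is coherent when
divergence is **strictly** below the threshold (default 500 bp — roughly
the scale of indel noise a lift-over tolerates, and small relative to
typical intergenic distances). A pair whose genes lift to different
target sequences is *broken*: broken pairs count fragmentation events and
are excluded from the coherent fraction's denominator. Swapping the roles
of the two genomes leaves every compared pair's divergence unchanged.

**Misplacement.** Each target sequence's dominant chromosome is the
reference chromosome contributing the most matched genes (ties broken by
lexicographically smallest name and logged; real data essentially never
ties). Any matched gene whose chromosome differs from its sequence's
dominant chromosome is reported, with the dominant fraction as context.
The method flags candidates only — whether a flagged gene is an assembly
error or a true translocation needs independent evidence.

## Contiguity

Nx/Lx use the standard definition: with lengths sorted descending, Lx is
the smallest k whose top-k sum reaches x·total, and Nx is the k-th
length. Equality counts as reached, and the threshold is formed exactly
(via rational arithmetic on the decimal value of x) because the float
product `0.9 * total` can overshoot an integer boundary by one ulp and
shift k. Nx/Lx are invariant to the ordering of tied lengths by
construction.

## The scenario generator

`build_reference` draws a multi-chromosome annotation with uniform gene
lengths and intergenic gaps; the defaults (5 chromosomes × 40 genes,
genes 0.5–5 kb, gaps 0.2–4 kb) emulate the gene density of a compact
plant genome at a size where every test and the acceptance script run in
seconds. `rearrange` then applies, in a fixed order that makes the ground
truth well defined:

1. **split** — chromosomes cut between genes into fragments
   (`chrN.fj`);
2. **translocate** — single genes moved into another fragment at a given
   index (the misplacement signal);
3. **fuse** — ordered fragment groups merged into one scaffold (false
   joints); remaining fragments become their own scaffolds, all named
   `scaffold_1..k` in fusion-first order;
4. **invert** — named fragments laid down in reverse gene order with
   strands flipped (reversal preserves pairwise gaps, so a pure inversion
   is fully coherent);
5. **jitter** — each target gap perturbed by rounded zero-mean Gaussian
   noise (sd in bp), clipped at 0 so coordinates stay valid;
6. **drop** — a fraction of genes removed from the target *after* layout,
   emulating failed lift-overs. Because removal does not shift the
   surviving coordinates and adjacency is defined among matched genes,
   drops alone leave every compared pair's divergence at zero.
   Translocated genes are never dropped, keeping the truth sets disjoint.

The accompanying truth table (expected orientation call per (chromosome,
scaffold) group, dominant chromosome per scaffold, misplaced/dropped gene
sets, broken-adjacency count, per-adjacency divergence) is computed by
brute force from the generator's own layout bookkeeping — gene index
positions and assigned coordinates — not by calling the metric code it is
used to test. The expected broken-adjacency count is derived from the
layout (reference-adjacent kept pairs whose scaffolds differ) rather than
from a split/fusion bookkeeping formula, because a split that is later
re-fused into the same scaffold severs nothing, and a fusion of two whole
chromosomes crosses no reference adjacency.

What the generator does **not** emulate: sequence-level error (there are
no bases, only coordinates), partial/duplicated lift-over mappings,
nested or overlapping gene models, and inversions smaller than the gene
spacing. Passing the recovery suite therefore shows the metrics are
correct on the rearrangement classes modelled, not that lift-over
artifacts on real data are handled beyond the drop/duplicate rules
stated above.

## Numerical and design choices

- Duplicate gene IDs within one file: first occurrence in file order
  wins, each loss logged and counted — deterministic and consistent with
  plain-join semantics.
- Orientation groups are keyed by (reference chromosome, target
  sequence), so a fusion scaffold gets one call per source chromosome.
- Orientation threshold inclusive (≥), coherence threshold strict (<);
  both boundary behaviours are pinned by tests.
- `coherent_fraction` is NaN (rendered `n/a`, JSON `null`) when a
  chromosome has no compared pair.
- Report files are timestamp-free and ordering is fully specified
  (target sequences by descending gene count, ties lexicographic;
  fractions to 3 decimals), so reruns are byte-identical and diffable.
- On any evaluation error, files written during the run are removed so a
  failed run cannot be mistaken for a complete one.
- The JSON summary is an addition for machine consumption beyond the TXT
  and TSV reports; its totals reconcile by construction
  (matched + reference-only = reference gene count).

## Problem sizes

Tests and the acceptance script use the generator defaults (200 genes,
≥ 20 scenarios) and 1000 random length multisets for the Nx/Lx oracle;
the whole suite runs in a few seconds on one CPU.

## Known limitations

- Matching is by ID only; if a lift-over renames genes the join is empty
  and the run aborts with a diagnostic rather than guessing a
  coordinate-based match.
- Strand-field concordance is not checked; orientation is inferred purely
  from coordinate order.
- Misplacement detection needs a meaningful majority; sequences carrying
  very few genes give unstable dominant calls (the dominant fraction in
  each record is the guard).
- Organelle exclusion is by explicit sequence-name list; no detection
  heuristic is attempted.
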