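# Methods

## Scope and model

`beemeta` identifies bee genera in pooled-tissue amplicon samples. The
observational unit is the *composite vial*: one leg from every bee of one
size class (intertegular distance above or below 3 mm) captured at one site
visit. The locus is the Folmer CO1 barcode (~658 bp between LCO1490 and
HCO2198). The core inferential rule is a windowed lowest-common-ancestor
(LCA) assignment: a read cluster is assigned to the deepest taxon ancestral
to every reference that scores within 3% of the best score, and the
assignment is then demoted when its mean identity says the barcode cannot
support the rank. The package also implements the comparison of molecular
detections against per-vial morphological composition, and a bee-level
concordance classifier for single-specimen barcode vs morphology records.

## Taxonomy

Taxonomy is a parent-pointer tree keyed by integer taxid with ranks
{phylum, class, order, family, genus, species, subspecies, no_rank}.
`no_rank` nodes are transparent to rank queries; subspecies collapse to
their species for every comparison, since assignments are reported at
species resolution at best. LCA is the intersection of root-ward paths,
which is exact for trees and O(depth) per query at the sizes used here
(tens of nodes for the packaged regional fixture, ≤50 in the simulator).

The packaged regional fixture mixes real NCBI taxids (where a record
carries one) with synthetic ids ≥900000 for nodes that have none; the tree
structure, not the id values, carries all the information used.

## Alignment and scoring

All pairwise comparisons run on edlib alignments. Two statistics are
derived from the extended CIGAR of the optimal alignment:

* **matched bases** — identical aligned columns; the score used for
  reference matching (floor 100), summed over the forward and reverse
  segments of a scaffolded template, each aligned semi-globally so
  reference bases outside the sequenced window carry no penalty;
* **identity** — matched columns over alignment columns; used for the 98%
  clustering threshold, the 95% contaminant screen, and the 96%/92%
  demotion thresholds.

Columns where either sequence holds an N are excluded from both statistics,
which removes the 15-N scaffold linker from every comparison. Because an
edit-style alignment of an unrelated sequence still "matches" roughly half
its bases by chance (a local aligner would simply report no alignment), a
match must additionally reach 70% overall identity to enter a match list;
this is the one numerical guard that has no analogue in a bit-score
pipeline, and it is exposed as `min_match_identity`.

Clustering uses an exact-arithmetic shortcut: for edit distance d and
linker-free length L, identity is bounded within [1 − d/L, 1 − d/(L + d)],
so only alignments whose bound straddles the threshold need the full column
walk.

## Pipeline thresholds

All defaults live in `RunConfig` and are the values the workflow was
designed around:

| parameter | default | meaning |
|---|---|---|
| cluster identity | 0.98 | greedy centroid threshold |
| graft distance | 1 edit | rare-variant grafting radius |
| crosstalk floor | 10 reads | clusters below are censored within a vial |
| min overlap / max diff | 80 bp / 7.5% | pair merging (short loci only) |
| quality floor | Phred 10 | 3′-end trimming |
| primer seed | 11-mer | IUPAC-aware binning/anchoring |
| score floor | 100 matched bases | minimum reportable match |
| LCA window | 3% | of the best score, boundary ties included |
| demotion | <96% → genus, <92% → family | on mean window identity |
| contaminant screen | 95% identity | vs the endosymbiont reference |
| off-phylum screen | 0.8 support | fraction of window matches in Arthropoda |
| linker | 15 N | scaffold joint |
| DB length floors | 250 / 400 bp | inclusive / curated modes |
| ambiguity ceiling | 4% | reference curation |

Grafting precedes censoring by default (`graft_before_censor`), so reads in
rare exact variants count toward their parent cluster before the size floor
is applied; the opposite order is available. Grafting absorbs the smallest
graftable cluster first into its largest in-range neighbor and iterates to
a fixed point, so chains of variants collapse onto the abundant centroid.

Chimera flagging is a two-parent crossover test, not a reimplementation of
UCHIME's score: a representative with ≤95% full-length identity to every
reference is chimeric if some prefix is ≥99% identical to one reference and
some equal-or-later suffix ≥99% identical to a different one. Prefix and
suffix split points may differ, which is what lets a coarse 8-point
breakpoint grid catch crossovers that fall between grid points; the
full-length single-parent guard prevents clean reads of closely related
species from tripping the relaxed rule. All screens set flags and never
delete, so cluster counts and read totals reconcile at every stage.

## Concordance classification

For a bee with both a single-specimen barcode (Sanger) assignment and a
morphological identification (subspecies collapsed first):

* no sequence → amplification failure;
* barcode resolved only above genus → family-level;
* both at species rank → species agreement if equal, otherwise
  disagreement (a within-genus species conflict is a conflict);
* exactly one at species rank with matching genera → genus agreement,
  flagged *sanger-refined* when the species call is the barcode's;
* otherwise agreement or disagreement on the genus itself.

Vial-level comparison drops vials with no amplification, counts genera
found by both methods and by exactly one, and reports the fraction of vials
whose genus sets match exactly. Detection-frequency differences use a
two-sided paired t-test on per-genus detection counts (metabarcoding minus
morphology, so undercounting gives negative t). The tissue-proportion
effect uses a two-sided Wilcoxon rank-sum test on per-(vial, genus) leg
proportions grouped by detection outcome; W is reported as the
Mann-Whitney U of the detected group, the convention of R's `wilcox.test`.

## The simulator

`synthetic.make_references` builds a reference set with controlled
divergence: genus ancestors mutated independently from a common root
(pairwise identity ≤0.90 enforced), species diverged 2.5–4% from their
genus ancestor (pairwise ~5–8%, comfortably outside the 3% window), two
accessions per species (exact + 0.5% variant). A `barcode_gap_off` flag
generates a genus whose species differ by <1% — inside the window — which
reproduces the situation where a locus cannot separate congeners and every
assignment lands at genus rank, as happens for bumble bees at this locus.
A random unrelated sequence on a bacterial lineage serves as the
endosymbiont-like contaminant and as the off-phylum decoy.

`synthetic.simulate_vials` emulates the field design: site visits each
yielding a large and a small vial; legs per vial 1 + negative binomial,
mean ~14, capped at 73; bees drawn from a 10-genus pool shaped like a
midwestern grassland community (dominant bumble-bee-like genus, abundant
small sweat bees, a managed honey-bee-like taxon with a 4× amplification
boost, a rare kleptoparasite). Reads per bee are negative binomial
(mean 15 per leg, size 10) scaled by a per-species log-normal amplification
factor (σ = 1.5). Sequencing error is 0.5% per base (90% substitutions,
10% indels), chimeras are two-parent splices at 1% of reads, 0.5% of reads
hop to a random other vial, and 2% of a vial's reads come from the
contaminant. Morphology resolves 65% of bees to species (85% in the focal
genus) and always gets the genus right.

The depth and bias defaults were chosen to land the cohort in the detection
regime the method is known for — frequent misses of low-proportion genera,
roughly a third of vials with a genus seen by only one method — rather than
at a detection ceiling where tissue proportion would not matter. Reads per
vial (~200) are far below a real MiSeq run; depth only matters here through
the size-10 censoring floor, and the scaled-down depth preserves that
interaction while keeping a 200-vial cohort tractable on one CPU.

What the simulator does not model: quality-by-cycle error profiles,
PCR-cycle-dependent chimera formation, primer-template mismatch dropout,
morphological misidentification (only resolution loss), and real barcode
phylogenies (divergences are controlled, not estimated). Passing the
synthetic recovery tests therefore shows the pipeline's logic is correct
under the stated statistical structure, not that real-data accuracy will
match.

## Problem sizes used in validation

The validation suite runs the full pipeline on a 200-vial cohort
(~100k read pairs) for the proportion-detection analysis, a 12-vial
error-free cohort for exact genus-set recovery, and a 24-vial two-genus
cohort for the barcode-gap behavior; the concordance classifier runs on the
packaged 66-record fixture. These sizes were chosen to give stable
statistics (hundreds of (vial, genus) detection outcomes) at desk scale.

## Known limitations

* Greedy clustering is order-dependent by design (abundance, then id);
  it matches the fielded tools' behavior but is not a global optimum.
* The chimera test detects clean two-parent crossovers; low-identity or
  multi-parent chimeras pass through (they are typically censored by size
  or demoted by identity instead).
* The off-phylum screen inherits the reference set's composition: with a
  single decoy lineage it can only distinguish "arthropod-like" from
  "decoy-like or unmatched".
* Checklist filtering trusts the source taxonomy; conflicting taxonomies
  for the same barcode are kept and logged, not reconciled.
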