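"""Morphology vs molecular concordance: bee-level and vial-level comparisons.

Two comparisons are implemented.  At the bee level, single-specimen barcode
(Sanger) assignments are compared with image-based morphological
identifications and classified into agreement categories (species
agreement, genus agreement, disagreement, family-level assignment, or
amplification failure).  At the vial level, the genus set recovered by
metabarcoding a composite sample is compared with the genus composition
known from morphology, with paired t and Wilcoxon rank-sum statistics on
detection frequency and tissue proportion.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import stats

from .taxonomy import TaxonomyTree

ND = "ND"

CAT_SPECIES_AGREEMENT = "species_agreement"
CAT_GENUS_AGREEMENT = "genus_agreement"
CAT_DISAGREEMENT = "disagreement"
CAT_FAMILY_LEVEL = "family_level"
CAT_AMPLIFICATION_FAILED = "amplification_failed"

CATEGORIES = (CAT_SPECIES_AGREEMENT, CAT_GENUS_AGREEMENT, CAT_DISAGREEMENT,
              CAT_FAMILY_LEVEL, CAT_AMPLIFICATION_FAILED)


@dataclass(frozen=True)
class BeeComparison:
    bee_id: str
    sanger_taxid: int | None  # None encodes ND (no amplification)
    morph_taxid: int
    metabarcode_detected: bool
    category: str
    sanger_refined: bool  # Sanger gave species where morphology gave genus


@dataclass
class VialRecord:
    """One composite sample: morphological composition vs molecular detections."""

    vial_id: str  # month letter + site + size-class letter, e.g. J-391-L
    size_class: str  # large (ITD > 3 mm) or small
    morph_genera: dict[str, int]  # genus name -> leg count
    detected_genera: set[str] = field(default_factory=set)
    excluded: bool = False  # no amplification in the vial

    @property
    def total_legs(self) -> int:
        return sum(self.morph_genera.values())


# -- bee-level classification ----------------------------------------------

def classify_bee(bee_id: str, sanger_taxid: int | None, morph_taxid: int,
                 tree: TaxonomyTree, metabarcode_detected: bool = False) -> BeeComparison:
    """Classify one specimen's Sanger vs morphology comparison.

    Rules (subspecies collapse to species throughout):

    * no Sanger sequence (ND) -> amplification_failed;
    * Sanger resolved only above genus (family) -> family_level;
    * both at species rank: equal -> species_agreement, otherwise
      disagreement (even within one genus — a species conflict is a
      conflict);
    * exactly one at species rank with the genera matching ->
      genus_agreement, flagged sanger_refined when the species call is the
      Sanger one;
    * otherwise agreement or disagreement on the genus itself.
    """
    morph_taxid = tree.effective_taxid(morph_taxid)
    if sanger_taxid is None:
        return BeeComparison(bee_id, None, morph_taxid, metabarcode_detected,
                             CAT_AMPLIFICATION_FAILED, False)
    sanger_taxid = tree.effective_taxid(sanger_taxid)
    sanger_rank = tree.rank_of(sanger_taxid)
    morph_rank = tree.rank_of(morph_taxid)
    if sanger_rank not in ("species", "genus"):
        return BeeComparison(bee_id, sanger_taxid, morph_taxid,
                             metabarcode_detected, CAT_FAMILY_LEVEL, False)

    sanger_genus = tree.ancestor_at_rank(sanger_taxid, "genus")
    morph_genus = tree.ancestor_at_rank(morph_taxid, "genus")
    same_genus = (sanger_genus is not None and morph_genus is not None
                  and sanger_genus.taxid == morph_genus.taxid)

    if sanger_rank == "species" and morph_rank == "species":
        if sanger_taxid == morph_taxid:
            category = CAT_SPECIES_AGREEMENT
        else:
            category = CAT_DISAGREEMENT
        refined = False
    elif same_genus:
        category = CAT_GENUS_AGREEMENT
        refined = sanger_rank == "species" and morph_rank == "genus"
    else:
        category = CAT_DISAGREEMENT
        refined = False
    return BeeComparison(bee_id, sanger_taxid, morph_taxid,
                         metabarcode_detected, category, refined)


def summarize_table1(records: list[BeeComparison]) -> dict[str, int]:
    """Category counts plus derived totals for a bee-comparison set.

    ``assigned_genus_or_species`` counts specimens whose Sanger assignment
    resolved to genus rank or below (everything except failures and
    family-level rows).
    """
    counts = Counter(r.category for r in records)
    summary = {cat: counts.get(cat, 0) for cat in CATEGORIES}
    summary["sanger_refined"] = sum(1 for r in records if r.sanger_refined)
    summary["assigned_genus_or_species"] = (
        len(records) - summary[CAT_AMPLIFICATION_FAILED] - summary[CAT_FAMILY_LEVEL])
    summary["total"] = len(records)
    return summary


# -- packaged single-specimen validation fixture ----------------------------

def load_table1(tree: TaxonomyTree, path: str | Path | None = None
                ) -> list[BeeComparison]:
    """Load and classify the packaged single-specimen validation records.

    The fixture is a TSV with columns bee_id, sanger_taxid (or ND),
    morph_taxid, metabarcode_detected (Y/N); taxids resolve against the
    packaged regional taxonomy.
    """
    if path is None:
        source = resources.files("beemeta.data").joinpath("table1.tsv")
    else:
        source = Path(path)
    records = []
    with source.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            sanger = None if row["sanger_taxid"] == ND else int(row["sanger_taxid"])
            records.append(classify_bee(
                row["bee_id"], sanger, int(row["morph_taxid"]), tree,
                metabarcode_detected=row["metabarcode_detected"] == "Y"))
    return records


def load_packaged_taxonomy() -> TaxonomyTree:
    """The packaged regional taxonomy (genera of the checklist plus the
    validation-fixture species)."""
    with resources.as_file(resources.files("beemeta.data").joinpath("taxonomy.tsv")) as p:
        return TaxonomyTree.from_tsv(p)


# -- vial-level comparison --------------------------------------------------

@dataclass(frozen=True)
class VialAgreement:
    vial_id: str
    richness_difference: int  # morphology minus metabarcoding
    concordant: int  # genera found by both methods
    misaligned: int  # genera found by exactly one method
    exact_match: bool


def vial_agreement(records: list[VialRecord]) -> tuple[list[VialAgreement], dict]:
    """Per-vial genus-set comparison and aggregate agreement statistics.

    Vials flagged ``excluded`` (no amplification) are dropped first, as the
    study protocol prescribes.  Misalignments count genera present in
    exactly one method's set: |morph ∪ detected| − |morph ∩ detected|.
    """
    usable = [r for r in records if not r.excluded]
    per_vial = []
    for rec in usable:
        morph = set(rec.morph_genera)
        both = morph & rec.detected_genera
        either = morph | rec.detected_genera
        per_vial.append(VialAgreement(
            vial_id=rec.vial_id,
            richness_difference=len(morph) - len(rec.detected_genera),
            concordant=len(both),
            misaligned=len(either) - len(both),
            exact_match=morph == rec.detected_genera,
        ))
    n = len(per_vial)
    aggregate = {
        "n_vials": n,
        "fraction_exact": (sum(v.exact_match for v in per_vial) / n) if n else 0.0,
        "mean_richness_difference": (
            float(np.mean([v.richness_difference for v in per_vial])) if n else 0.0),
        "total_concordant": sum(v.concordant for v in per_vial),
        "total_misaligned": sum(v.misaligned for v in per_vial),
    }
    return per_vial, aggregate


def paired_detection_ttest(morph_counts, metabarcode_counts) -> tuple[float, float]:
    """Two-sided paired t on per-genus detection counts (metabarcode - morph)."""
    if len(morph_counts) != len(metabarcode_counts) or len(morph_counts) < 2:
        raise ValueError("paired t-test needs >= 2 equal-length paired counts")
    t, p = stats.ttest_rel(metabarcode_counts, morph_counts)
    return float(t), float(p)


def detection_frequency_test(records: list[VialRecord]) -> dict:
    """Paired t-test on per-genus detection counts, morphology vs metabarcoding.

    For each genus seen by either method, counts the number of vials where
    it was identified morphologically and where it was detected molecularly;
    the two paired vectors feed a two-sided paired-sample t-test (difference
    taken as metabarcoding minus morphology, so an undercounting molecular
    method gives a negative t).
    """
    usable = [r for r in records if not r.excluded]
    genera = sorted({g for r in usable for g in r.morph_genera}
                    | {g for r in usable for g in r.detected_genera})
    if len(genera) < 2:
        raise ValueError("paired t-test needs at least 2 genera")
    morph_counts = [sum(1 for r in usable if g in r.morph_genera) for g in genera]
    meta_counts = [sum(1 for r in usable if g in r.detected_genera) for g in genera]
    t, p = paired_detection_ttest(morph_counts, meta_counts)
    return {"t": float(t), "p": float(p), "n_genera": len(genera),
            "genera": genera, "morph_counts": morph_counts,
            "metabarcode_counts": meta_counts}


def proportion_detection_test(records: list[VialRecord]) -> dict:
    """Wilcoxon rank-sum test: does tissue proportion drive detection?

    Each (vial, genus) pair contributes the genus's leg proportion in the
    vial and whether metabarcoding detected the genus there.  Proportions
    are grouped by detection outcome and compared with a two-sided
    rank-sum test (W reported as the Mann-Whitney U of detected vs not,
    matching R's ``wilcox.test`` convention).  Group means are reported,
    not asserted — they are data-dependent.
    """
    detected, missed = [], []
    for rec in records:
        if rec.excluded or rec.total_legs == 0:
            continue
        for genus, legs in rec.morph_genera.items():
            proportion = legs / rec.total_legs
            if genus in rec.detected_genera:
                detected.append(proportion)
            else:
                missed.append(proportion)
    if not detected or not missed:
        raise ValueError("both detection outcome groups must be nonempty")
    res = stats.mannwhitneyu(detected, missed, alternative="two-sided")
    return {"W": float(res.statistic), "p": float(res.pvalue),
            "n_detected": len(detected), "n_missed": len(missed),
            "mean_proportion_detected": float(np.mean(detected)),
            "mean_proportion_missed": float(np.mean(missed))}
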