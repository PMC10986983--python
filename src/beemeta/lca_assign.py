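"""Windowed lowest-common-ancestor taxonomic assignment with rank demotion.

Each cluster representative is scored against every reference as the count
of matched bases (segments of a scaffolded template are scored separately
against the same reference and summed).  References scoring within a
fractional window (default 3%) of the best score form the *window set*;
the cluster is assigned to the LCA of their taxa.  To guard against
assignments that outrun the information in the barcode, species calls whose
mean identity over the window falls below 96% demote to genus, and genus
calls below 92% demote to family.

Aggregation sums cluster sizes per (vial, genus); assignments above genus
rank land in an ``above_genus`` column so row sums always reconcile with
the assignable read count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .alignment import align_stats, split_on_linker
from .read_processing import Template
from .reference_db import CuratedDB
from .taxonomy import TaxonomyTree, rank_more_specific

STATUS_ASSIGNED = "assigned"
STATUS_UNASSIGNED = "unassigned"
STATUS_FILTERED = "filtered"

ABOVE_GENUS = "above_genus"


@dataclass(frozen=True)
class MatchScore:
    accession: str
    taxid: int
    score: int  # matched bases, summed over segments
    identity: float  # matches / aligned columns, linker excluded
    per_segment: tuple[int, ...] = ()


@dataclass(frozen=True)
class Assignment:
    cluster_id: str
    taxid: int | None
    rank: str | None
    window: tuple[MatchScore, ...]
    mean_identity: float
    demoted_from: str | None = None
    status: str = STATUS_ASSIGNED


def score_against_db(template: Template | str, db: CuratedDB,
                     score_floor: int = 100,
                     min_match_identity: float = 0.70) -> list[MatchScore]:
    """Score a template against every reference; keep scores >= the floor.

    Alignment is semi-global (free end gaps on the reference) so reference
    bases outside the sequenced window never penalize.  For scaffolded
    templates each linker-delimited segment is scored independently against
    the same reference and the matched-base counts are summed.

    Besides the matched-bases floor, a match must reach ``min_match_identity``
    overall: a local aligner only reports alignments that actually extend,
    whereas an edit-style alignment of an unrelated query still "matches"
    roughly half its bases by chance, so a plain score floor cannot reject
    junk on its own.
    """
    if not db.sequences:
        raise ValueError("reference database is empty")
    seq = template.sequence if isinstance(template, Template) else template
    segments = split_on_linker(seq)
    matches_out = []
    for ref in db.sequences:
        per_segment = []
        total_matches = total_columns = 0
        for segment in segments:
            m, c = align_stats(segment, ref.sequence, mode="HW")
            per_segment.append(m)
            total_matches += m
            total_columns += c
        if (total_matches >= score_floor and total_columns
                and total_matches / total_columns >= min_match_identity):
            matches_out.append(MatchScore(
                accession=ref.accession,
                taxid=ref.taxid,
                score=total_matches,
                identity=total_matches / total_columns if total_columns else 0.0,
                per_segment=tuple(per_segment),
            ))
    return matches_out


def lca_window(matches: list[MatchScore], tree: TaxonomyTree,
               window: float = 0.03, cluster_id: str = "") -> Assignment:
    """Assign to the LCA of all references scoring within the window.

    The window set is every match with score >= (1 - window) * best score
    (boundary ties included).  Mean identity averages over window members
    only — the accessions that determined the assignment.  No matches at
    all yields an unassigned record.
    """
    if not matches:
        return Assignment(cluster_id, None, None, (), 0.0,
                          status=STATUS_UNASSIGNED)
    top = max(m.score for m in matches)
    cutoff = (1.0 - window) * top
    in_window = tuple(m for m in matches if m.score >= cutoff)
    taxids = {tree.effective_taxid(m.taxid) for m in in_window}
    node = tree.lca(taxids)
    mean_identity = sum(m.identity for m in in_window) / len(in_window)
    return Assignment(cluster_id, node.taxid, node.rank, in_window,
                      mean_identity, status=STATUS_ASSIGNED)


def demote(assignment: Assignment, tree: TaxonomyTree,
           species_min_id: float = 0.96,
           genus_min_id: float = 0.92) -> Assignment:
    """Coarsen over-specific assignments by mean identity.

    Species below ``species_min_id`` demote to genus; genus (whether
    original or just demoted) below ``genus_min_id`` demotes to family.
    Ranks above family never demote.  When the lineage lacks the target
    rank, the nearest available coarser ancestor is used.
    """
    if assignment.status != STATUS_ASSIGNED:
        return assignment
    out = assignment
    if out.rank in ("species", "subspecies") and out.mean_identity < species_min_id:
        out = _demote_to(out, tree, "genus", demoted_from="species")
    if out.rank == "genus" and out.mean_identity < genus_min_id:
        original = assignment.rank if assignment.rank != out.rank else "genus"
        out = _demote_to(out, tree, "family", demoted_from=original)
    return out


def _demote_to(assignment: Assignment, tree: TaxonomyTree, rank: str,
               demoted_from: str) -> Assignment:
    target = tree.ancestor_at_rank(assignment.taxid, rank)
    if target is None:
        # lineage lacks the rank: fall back to the nearest coarser ancestor
        for fallback in ("family", "order", "class", "phylum"):
            if not rank_more_specific(rank, fallback) and rank != fallback:
                continue
            target = tree.ancestor_at_rank(assignment.taxid, fallback)
            if target is not None:
                break
    if target is None:
        return assignment
    return replace(assignment, taxid=target.taxid, rank=target.rank,
                   demoted_from=demoted_from)


def assign_cluster(template: Template | str, db: CuratedDB, tree: TaxonomyTree,
                   score_floor: int = 100, window: float = 0.03,
                   species_min_id: float = 0.96, genus_min_id: float = 0.92,
                   cluster_id: str = "") -> Assignment:
    """Full scoring -> windowed LCA -> demotion path for one template."""
    matches = score_against_db(template, db, score_floor=score_floor)
    assignment = lca_window(matches, tree, window=window, cluster_id=cluster_id)
    return demote(assignment, tree,
                  species_min_id=species_min_id, genus_min_id=genus_min_id)


def assign_sanger(seq: str, db: CuratedDB, tree: TaxonomyTree,
                  score_floor: int = 100, window: float = 0.03,
                  species_min_id: float = 0.96,
                  genus_min_id: float = 0.92) -> Assignment:
    """Assign one finished single-read sequence (no pairing or scaffolding).

    Identical scoring/LCA/demotion path as for metabarcode clusters, with a
    single-segment score.
    """
    return assign_cluster(seq, db, tree, score_floor=score_floor, window=window,
                          species_min_id=species_min_id, genus_min_id=genus_min_id,
                          cluster_id="sanger")


def counts_table(assignments: dict[str, list[tuple[Assignment, int]]],
                 tree: TaxonomyTree) -> pd.DataFrame:
    """Genus-level counts table: vial rows x genus columns (read counts).

    ``assignments`` maps vial id -> [(assignment, cluster size), ...] for
    unflagged clusters only.  Clusters with the same genus assignment sum
    within a vial; assignments above genus rank are tallied in the
    ``above_genus`` column so row totals equal assignable reads per vial.
    """
    rows: dict[str, dict[str, int]] = {}
    for vial, items in assignments.items():
        row = rows.setdefault(vial, {})
        for assignment, size in items:
            if assignment.status != STATUS_ASSIGNED:
                continue
            genus = tree.ancestor_at_rank(assignment.taxid, "genus")
            col = genus.name if genus is not None else ABOVE_GENUS
            row[col] = row.get(col, 0) + size
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    table.index.name = "vial"
    return table.sort_index().sort_index(axis=1)
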