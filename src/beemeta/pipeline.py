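"""End-to-end wiring: read pairs per vial -> genus-level counts table.

One RunConfig object carries every threshold of the workflow; the defaults
are the values the method was designed around (98% clustering identity,
size-10 crosstalk floor, 3% LCA window, 96%/92% demotion, 95% contaminant
identity, score floor of 100 matched bases, 15-N scaffold linker).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import pandas as pd

from . import clustering, lca_assign, read_processing
from .clustering import ReadCluster
from .concordance import VialRecord
from .lca_assign import ABOVE_GENUS, Assignment
from .read_processing import ReadPair, Template
from .reference_db import CuratedDB, RefSeq
from .taxonomy import TaxonomyTree


@dataclass
class RunConfig:
    cluster_identity: float = 0.98
    min_cluster_size: int = 10
    graft_d: int = 1
    min_overlap: int = 80
    max_overlap_diff: float = 0.075
    min_phred: int = 10
    primer_kmer: int = 11
    score_floor: int = 100
    lca_window: float = 0.03
    species_min_id: float = 0.96
    genus_min_id: float = 0.92
    contaminant_min_id: float = 0.95
    off_phylum_min_conf: float = 0.8
    linker_n: int = 15
    db_min_length_inclusive: int = 250
    db_min_length_curated: int = 400
    max_ambiguous_fraction: float = 0.04
    itd_size_threshold_mm: float = 3.0
    pair_strategy: str = "scaffold"  # scaffold | merge | forward_only
    graft_before_censor: bool = True
    apply_score_floor: bool = True
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class VialResult:
    vial: str
    n_reads: int
    n_templates: int
    clusters: list[ReadCluster]
    assignments: list[tuple[Assignment, int]]  # unflagged clusters only
    excluded: bool  # nothing assignable survived (failed amplification)


@dataclass
class PipelineResult:
    vials: dict[str, VialResult]
    counts: pd.DataFrame  # vial x genus read counts

    def detected_genera(self, vial: str) -> set[str]:
        if vial not in self.counts.index:
            return set()
        row = self.counts.loc[vial]
        return {g for g in row.index if g != ABOVE_GENUS and row[g] > 0}


def make_templates(pairs: list[ReadPair], fwd_primer: str, rev_primer: str,
                   config: RunConfig) -> list[Template]:
    """Trim and pair-assemble one vial's binned reads into templates.

    Pairs whose trimmed mate is empty are dropped (flagged in the counts the
    caller keeps).  The Folmer amplicon exceeds the combined read length, so
    the default strategy scaffolds; merging is available for short loci.
    """
    templates = []
    for pair in pairs:
        trimmed = read_processing.trim(pair, fwd_primer, rev_primer,
                                       min_phred=config.min_phred,
                                       kmer=config.primer_kmer)
        if not trimmed.fwd:
            continue
        if config.pair_strategy == "forward_only":
            templates.append(read_processing.forward_only(trimmed))
            continue
        if not trimmed.rev:
            continue
        if config.pair_strategy == "merge":
            merged = read_processing.merge_pair(
                trimmed, min_overlap=config.min_overlap,
                max_diff=config.max_overlap_diff)
            if merged is not None:
                templates.append(merged)
        else:
            templates.append(read_processing.scaffold(trimmed,
                                                      linker_n=config.linker_n))
    return templates


def process_vial(vial: str, pairs: list[ReadPair], db: CuratedDB,
                 screen_db: CuratedDB, tree: TaxonomyTree,
                 fwd_primer: str, rev_primer: str,
                 config: RunConfig,
                 contaminant_ref: RefSeq | None = None) -> VialResult:
    """Run one vial through trimming, clustering, screening, and assignment."""
    templates = make_templates(pairs, fwd_primer, rev_primer, config)
    if not templates:
        return VialResult(vial, len(pairs), 0, [], [], excluded=True)
    clusters = clustering.cluster_greedy(templates,
                                         identity=config.cluster_identity)
    if config.graft_before_censor:
        clusters = clustering.graft_rare(clusters, d=config.graft_d)
        clusters = clustering.censor_small(clusters,
                                           min_size=config.min_cluster_size)
    else:
        clusters = clustering.censor_small(clusters,
                                           min_size=config.min_cluster_size)
        clusters = clustering.graft_rare(clusters, d=config.graft_d)
    if contaminant_ref is not None:
        clusters = clustering.screen_contaminant(
            clusters, contaminant_ref, min_identity=config.contaminant_min_id)
    clusters = clustering.screen_off_phylum(
        clusters, screen_db, min_conf=config.off_phylum_min_conf,
        score_floor=config.score_floor if config.apply_score_floor else 1,
        window=config.lca_window)
    clusters = clustering.flag_chimeras(clusters, screen_db)

    assignments = []
    for i, cl in enumerate(cl for cl in clusters if cl.usable):
        assignment = lca_assign.assign_cluster(
            cl.representative, db, tree,
            score_floor=config.score_floor if config.apply_score_floor else 1,
            window=config.lca_window,
            species_min_id=config.species_min_id,
            genus_min_id=config.genus_min_id,
            cluster_id=f"{vial}.c{i}")
        if assignment.status == lca_assign.STATUS_ASSIGNED:
            assignments.append((assignment, cl.size))
    excluded = not assignments
    return VialResult(vial, len(pairs), len(templates), clusters,
                      assignments, excluded)


def run_pipeline(reads: dict[str, list[ReadPair]], db: CuratedDB,
                 screen_db: CuratedDB, tree: TaxonomyTree,
                 config: RunConfig | None = None,
                 fwd_primer: str | None = None,
                 rev_primer: str | None = None,
                 contaminant_ref: RefSeq | None = None) -> PipelineResult:
    """Process every vial and aggregate a genus-level counts table."""
    from .synthetic import FOLMER_FWD, FOLMER_REV

    config = config or RunConfig()
    fwd_primer = fwd_primer or FOLMER_FWD
    rev_primer = rev_primer or FOLMER_REV
    vials = {}
    for vial in sorted(reads):
        vials[vial] = process_vial(vial, reads[vial], db, screen_db, tree,
                                   fwd_primer, rev_primer, config,
                                   contaminant_ref=contaminant_ref)
    counts = lca_assign.counts_table(
        {v: r.assignments for v, r in vials.items() if not r.excluded}, tree)
    return PipelineResult(vials=vials, counts=counts)


def attach_detections(records: list[VialRecord], result: PipelineResult) -> None:
    """Fill each vial record's molecular detections; mark failed vials excluded."""
    for rec in records:
        vial_result = result.vials.get(rec.vial_id)
        if vial_result is None or vial_result.excluded:
            rec.excluded = True
            rec.detected_genera = set()
        else:
            rec.detected_genera = result.detected_genera(rec.vial_id)
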