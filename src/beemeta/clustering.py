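"""Per-vial template clustering and the censoring / screening filters.

Templates from one composite vial are greedily clustered at 98% identity
(edit-distance style, linker columns excluded), rare exact variants are
grafted onto nearby abundant clusters, clusters below the crosstalk size
floor are censored, and the survivors pass contaminant, off-phylum, and
chimera screens.  Filters only ever set flags; no cluster is removed from
the record, so every report reconciles with the raw read count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import align_stats, edit_distance, segment_identity, split_on_linker
from .read_processing import Template
from .reference_db import CuratedDB, RefSeq

FLAG_CENSORED = "censored"
FLAG_CHIMERA = "chimera"
FLAG_CONTAMINANT = "contaminant"
FLAG_NON_ARTHROPOD = "non_arthropod"


@dataclass
class ReadCluster:
    representative: Template
    size: int
    vial: str
    flags: set[str] = field(default_factory=set)

    @property
    def usable(self) -> bool:
        return not self.flags


def cluster_greedy(templates: list[Template], identity: float = 0.98) -> list[ReadCluster]:
    """Greedy centroid clustering at an identity threshold.

    Exact duplicates are collapsed first (abundance = duplicate count), then
    unique sequences are processed by decreasing abundance (ties broken by
    lexicographic id): each joins the first existing centroid it matches at
    >= ``identity``, else founds a new cluster.  Identity is matches over
    alignment columns of a global alignment, with N-linker columns excluded.
    """
    if not templates:
        raise ValueError("cluster_greedy requires at least one template")
    vial = templates[0].vial
    # exact dereplication: sequence -> (count, first template by id)
    groups: dict[str, list[Template]] = {}
    for t in templates:
        groups.setdefault(t.sequence, []).append(t)
    uniques = []
    for seq, members in groups.items():
        rep = min(members, key=lambda t: t.id)
        uniques.append((len(members), rep))
    uniques.sort(key=lambda x: (-x[0], x[1].id))

    clusters: list[ReadCluster] = []
    for count, tmpl in uniques:
        joined = False
        for cl in clusters:
            if _fast_identity_at_least(tmpl.sequence, cl.representative.sequence, identity):
                cl.size += count
                joined = True
                break
        if not joined:
            clusters.append(ReadCluster(representative=tmpl, size=count, vial=vial))
    clusters.sort(key=lambda c: (-c.size, c.representative.id))
    return clusters


def _fast_identity_at_least(a: str, b: str, threshold: float) -> bool:
    """Identity >= threshold test with a cheap edit-distance prefilter.

    Every edit costs at least one matched column, so identity <= 1 - d/L
    with L the longer (linker-free) length; sequences failing that bound
    are rejected without the exact column walk.
    """
    la = len(a) - a.count("N")
    lb = len(b) - b.count("N")
    lmax = max(la, lb, 1)
    # identity >= t forces d <= (1-t)/t * columns <= (1-t)/t * (lmax + d)
    k = int((1.0 - threshold) / threshold * (lmax + 40)) + 2
    d = edit_distance(a, b, k=k)
    if d == -1:
        return False
    if (lmax - d) / (lmax + d) >= threshold:  # safe lower bound on identity
        return True
    return segment_identity(a, b) >= threshold


def graft_rare(clusters: list[ReadCluster], d: int = 1) -> list[ReadCluster]:
    """Graft rare clusters onto nearby abundant ones (amplicon-variant style).

    A cluster whose representative is within edit distance ``d`` of the
    representative of a strictly larger cluster merges into it (sizes add).
    Iterates to a fixed point deterministically: the smallest graftable
    cluster is absorbed first into the largest in-range target (ties by
    lexicographic representative id), so chains of rare variants collapse
    step by step toward the abundant centroid.
    """
    clusters = [ReadCluster(c.representative, c.size, c.vial, set(c.flags))
                for c in clusters]
    changed = True
    while changed:
        changed = False
        # absorb the smallest graftable cluster first so chains of rare
        # variants collapse step by step toward the abundant centroid
        clusters.sort(key=lambda c: (c.size, c.representative.id))
        for i, small in enumerate(clusters):
            targets = [t for t in clusters
                       if t.size > small.size
                       and edit_distance(small.representative.sequence,
                                         t.representative.sequence, k=d) != -1]
            if targets:
                target = min(targets, key=lambda t: (-t.size, t.representative.id))
                target.size += small.size
                target.flags |= small.flags
                del clusters[i]
                changed = True
                break
    clusters.sort(key=lambda c: (-c.size, c.representative.id))
    return clusters


def censor_small(clusters: list[ReadCluster], min_size: int = 10) -> list[ReadCluster]:
    """Flag clusters below the crosstalk size floor (default 10 reads).

    Index-hopping misassigns small numbers of reads across samples; censoring
    sub-floor clusters within each vial mitigates it.  Clusters are flagged,
    never removed.
    """
    for cl in clusters:
        if cl.size < min_size:
            cl.flags.add(FLAG_CENSORED)
    return clusters


def screen_contaminant(clusters: list[ReadCluster], screen_ref: RefSeq,
                       min_identity: float = 0.95) -> list[ReadCluster]:
    """Flag clusters aligning to a known off-target reference at >= 95% identity.

    Models the endosymbiont (Wolbachia-type) screen: the most frequently
    matched contaminant accession serves as the screen reference.
    """
    for cl in clusters:
        if _template_ref_identity(cl.representative.sequence, screen_ref.sequence) >= min_identity:
            cl.flags.add(FLAG_CONTAMINANT)
    return clusters


def _template_ref_identity(template_seq: str, ref_seq: str) -> float:
    """Identity of a (possibly scaffolded) template against one reference.

    Each linker-delimited segment is aligned semi-globally so reference
    bases outside the sequenced window do not penalize; matches and columns
    pool across segments.
    """
    matches = columns = 0
    for segment in split_on_linker(template_seq):
        m, c = align_stats(segment, ref_seq, mode="HW")
        matches += m
        columns += c
    return matches / columns if columns else 0.0


def screen_off_phylum(clusters: list[ReadCluster], db: CuratedDB,
                      min_conf: float = 0.8, score_floor: int = 100,
                      window: float = 0.03,
                      target_phylum: str = "Arthropoda") -> list[ReadCluster]:
    """Flag clusters whose best-supported phylum is not the target phylum.

    The database must include at least one non-target decoy lineage.
    Support is the fraction of top-window matches whose lineage lies in the
    target phylum; clusters with no match above the score floor are flagged
    (conservative default).
    """
    from .lca_assign import score_against_db

    phyla = {entry[2] for ref in db.sequences for entry in [ref.lineage.at_rank("phylum")]
             if entry is not None}
    if phyla <= {target_phylum}:
        raise ValueError("off-phylum screen requires at least one decoy lineage")
    for cl in clusters:
        if not cl.usable:
            continue  # already excluded from assignment
        matches = score_against_db(cl.representative, db, score_floor=score_floor)
        if not matches:
            cl.flags.add(FLAG_NON_ARTHROPOD)
            continue
        top = max(m.score for m in matches)
        in_window = [m for m in matches if m.score >= (1.0 - window) * top]
        by_acc = {ref.accession: ref for ref in db.sequences}
        support = 0
        for m in in_window:
            phylum = by_acc[m.accession].lineage.at_rank("phylum")
            if phylum is not None and phylum[2] == target_phylum:
                support += 1
        if support / len(in_window) < min_conf:
            cl.flags.add(FLAG_NON_ARTHROPOD)
    return clusters


def flag_chimeras(clusters: list[ReadCluster], db: CuratedDB,
                  segment_identity_min: float = 0.99,
                  full_identity_max: float = 0.95,
                  n_breakpoints: int = 8) -> list[ReadCluster]:
    """Flag two-parent crossover artifacts against a reference database.

    A representative is chimeric when a prefix (up to some split point) is
    >= 99% identical to one reference and a suffix (from the same or a later
    split point) is >= 99% identical to a *different* reference, while its
    full-length identity to every single reference is <= 95% (a clean read
    would have one good full-length parent, so it never reaches the
    crossover search).  Letting the prefix and suffix end points differ
    keeps a coarse breakpoint grid sufficient: a crossover between two grid
    points still leaves a pure-parent prefix before it and a pure-parent
    suffix after it.  This is a crossover test in the uchime_ref spirit,
    not a reimplementation of its scoring; it only sets flags.
    """
    if not db.sequences:
        raise ValueError("chimera reference database is empty")
    for cl in clusters:
        if not cl.usable:
            continue  # already excluded from assignment
        seq = cl.representative.sequence
        best_full = 0.0
        for ref in db.sequences:
            ident = _template_ref_identity(seq, ref.sequence)
            best_full = max(best_full, ident)
            if best_full > full_identity_max:
                break
        if best_full > full_identity_max:
            continue  # has a plausible single parent
        core = seq.replace("N", "")
        if len(core) < 60:
            continue
        splits = [int(len(seq) * (i + 1) / (n_breakpoints + 1))
                  for i in range(n_breakpoints)]
        left_parents = [(s, _best_parent(seq[:s], db, segment_identity_min))
                        for s in splits]
        right_parents = [(s, _best_parent(seq[s:], db, segment_identity_min))
                         for s in splits]
        for s1, left_parent in left_parents:
            if left_parent is None:
                continue
            for s2, right_parent in right_parents:
                if s2 < s1 or right_parent is None:
                    continue
                if (left_parent.accession != right_parent.accession
                        and left_parent.sequence != right_parent.sequence):
                    cl.flags.add(FLAG_CHIMERA)
                    break
            if FLAG_CHIMERA in cl.flags:
                break
    return clusters


def _best_parent(segment: str, db: CuratedDB, min_identity: float) -> RefSeq | None:
    segment = segment.replace("N", "")
    if len(segment) < 30:
        return None
    best, best_id = None, min_identity
    for ref in db.sequences:
        m, c = align_stats(segment, ref.sequence, mode="HW")
        ident = m / c if c else 0.0
        if ident >= best_id:
            best, best_id = ref, ident
    return best
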