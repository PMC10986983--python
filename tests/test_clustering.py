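"""Greedy clustering, grafting, censoring, and the screening filters."""

import random

import pytest

from beemeta.clustering import (
    FLAG_CENSORED,
    FLAG_CHIMERA,
    FLAG_CONTAMINANT,
    FLAG_NON_ARTHROPOD,
    censor_small,
    cluster_greedy,
    flag_chimeras,
    graft_rare,
    screen_contaminant,
    screen_off_phylum,
)
from beemeta.alignment import segment_identity
from beemeta.read_processing import Template
from beemeta.reference_db import CuratedDB, RefSeq


def tmpl(seq, tid="t0", vial="v1"):
    return Template(id=tid, vial=vial, kind="merged", sequence=seq,
                    fwd_len=len(seq), rev_len=0)


def random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate(rng, seq, n_subs):
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    out = list(seq)
    for pos in rng.sample(range(len(seq)), n_subs):
        out[pos] = flip[out[pos]]
    return "".join(out)


class TestClusterGreedy:
    def test_identical_templates_one_cluster(self):
        rng = random.Random(0)
        seq = random_dna(rng, 200)
        clusters = cluster_greedy([tmpl(seq, f"t{i}") for i in range(10)])
        assert len(clusters) == 1 and clusters[0].size == 10

    def test_97_percent_pair_splits_at_098(self):
        rng = random.Random(1)
        a = random_dna(rng, 100)
        b = mutate(rng, a, 3)  # 97% identity by the edit-distance oracle
        assert segment_identity(a, b) == pytest.approx(0.97)
        clusters = cluster_greedy([tmpl(a, "ta"), tmpl(b, "tb")], identity=0.98)
        assert len(clusters) == 2

    def test_same_pair_joins_at_096(self):
        rng = random.Random(1)
        a = random_dna(rng, 100)
        b = mutate(rng, a, 3)
        clusters = cluster_greedy([tmpl(a, "ta"), tmpl(b, "tb")], identity=0.96)
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_size_conservation(self):
        rng = random.Random(2)
        base = random_dna(rng, 150)
        templates = [tmpl(mutate(rng, base, rng.randint(0, 20)), f"t{i}")
                     for i in range(60)]
        clusters = cluster_greedy(templates)
        assert sum(c.size for c in clusters) == len(templates)

    def test_identity_one_equals_hash_grouping(self):
        rng = random.Random(3)
        seqs = [random_dna(rng, 80) for _ in range(5)]
        templates = [tmpl(rng.choice(seqs), f"t{i}") for i in range(40)]
        clusters = cluster_greedy(templates, identity=1.0)
        by_hash = {}
        for t in templates:
            by_hash[t.sequence] = by_hash.get(t.sequence, 0) + 1
        assert sorted(c.size for c in clusters) == sorted(by_hash.values())
        assert {c.representative.sequence for c in clusters} == set(by_hash)

    def test_centroid_separation_property(self):
        rng = random.Random(4)
        base = random_dna(rng, 200)
        templates = [tmpl(mutate(rng, base, rng.randint(0, 30)), f"t{i}")
                     for i in range(40)]
        clusters = cluster_greedy(templates, identity=0.98)
        reps = [c.representative.sequence for c in clusters]
        for i, a in enumerate(reps):
            for b in reps[i + 1:]:
                assert segment_identity(a, b) < 0.98

    def test_linker_columns_ignored(self):
        rng = random.Random(5)
        fwd, rev = random_dna(rng, 100), random_dna(rng, 100)
        a = fwd + "N" * 15 + rev
        b = fwd + "N" * 15 + mutate(rng, rev, 1)  # 199/200 non-linker identity
        clusters = cluster_greedy(
            [Template("a", "v", "scaffolded", a, 100, 100),
             Template("b", "v", "scaffolded", b, 100, 100)], identity=0.99)
        assert len(clusters) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_greedy([])


class TestGraftRare:
    def test_one_edit_apart_merges(self):
        rng = random.Random(6)
        seq = random_dna(rng, 150)
        near = mutate(rng, seq, 1)
        clusters = cluster_greedy([tmpl(seq, f"a{i}") for i in range(100)]
                                  + [tmpl(near, f"b{i}") for i in range(3)],
                                  identity=0.999)
        assert len(clusters) == 2
        grafted = graft_rare(clusters, d=1)
        assert len(grafted) == 1 and grafted[0].size == 103

    def test_distant_pair_unchanged(self):
        rng = random.Random(7)
        seq = random_dna(rng, 150)
        far = mutate(rng, seq, 5)
        clusters = cluster_greedy([tmpl(seq, f"a{i}") for i in range(100)]
                                  + [tmpl(far, f"b{i}") for i in range(3)],
                                  identity=0.999)
        grafted = graft_rare(clusters, d=1)
        assert sorted(c.size for c in grafted) == [3, 100]

    def test_chain_collapses_to_fixed_point(self):
        # 100 --(1 edit)-- 3 --(1 edit)-- 2: iterating must absorb the chain
        rng = random.Random(8)
        seq = random_dna(rng, 150)
        mid = mutate(rng, seq, 1)
        rng2 = random.Random(9)
        far = mutate(rng2, mid, 1)
        if far == seq:  # ensure a genuine 2-step chain
            far = mutate(random.Random(10), mid, 1)
        templates = ([tmpl(seq, f"a{i}") for i in range(100)]
                     + [tmpl(mid, f"b{i}") for i in range(3)]
                     + [tmpl(far, f"c{i}") for i in range(2)])
        clusters = cluster_greedy(templates, identity=0.999)
        assert len(clusters) == 3
        grafted = graft_rare(clusters, d=1)
        assert len(grafted) == 1 and grafted[0].size == 105

    def test_size_conserved(self):
        rng = random.Random(11)
        base = random_dna(rng, 120)
        templates = [tmpl(mutate(rng, base, rng.randint(0, 3)), f"t{i}")
                     for i in range(50)]
        clusters = cluster_greedy(templates, identity=0.995)
        total = sum(c.size for c in clusters)
        grafted = graft_rare(clusters)
        assert sum(c.size for c in grafted) == total == 50


class TestCensorSmall:
    @pytest.mark.parametrize("size,censored", [(9, True), (10, False)])
    def test_size_floor_boundary(self, size, censored):
        rng = random.Random(12)
        cl = cluster_greedy([tmpl(random_dna(rng, 100), f"t{i}")
                             for i in range(1)])
        cl[0].size = size
        out = censor_small(cl, min_size=10)
        assert (FLAG_CENSORED in out[0].flags) == censored

    def test_all_small_vial_yields_nothing_assignable(self):
        rng = random.Random(13)
        clusters = cluster_greedy([tmpl(random_dna(rng, 100), "t0")])
        clusters += cluster_greedy([tmpl(random_dna(rng, 100), "t1")])
        out = censor_small(clusters, min_size=10)
        assert len(out) == 2 and all(not c.usable for c in out)


def make_screen_db(rng, tree_seed=0):
    """Tiny DB: two arthropod references + one bacterial decoy."""
    from beemeta.taxonomy import TaxonomyTree

    rows = [(1, "root", "no_rank", 1),
            (2, "Arthropoda", "phylum", 1),
            (3, "Proteobacteria", "phylum", 1),
            (4, "Insecta", "class", 2),
            (5, "Hymenoptera", "order", 4),
            (6, "Apidae", "family", 5),
            (7, "Bombus", "genus", 6),
            (8, "Bombus sp1", "species", 7),
            (9, "Bombus sp2", "species", 7),
            (10, "Wolbachia-like", "genus", 3),
            (11, "Wolbachia-like sp", "species", 10)]
    tree = TaxonomyTree.build(rows)
    s1 = random_dna(rng, 400)
    s2 = mutate(rng, s1, 20)  # 95% to s1
    decoy = random_dna(rng, 400)
    db = CuratedDB([
        RefSeq("R1", 8, tree.lineage(8), s1),
        RefSeq("R2", 9, tree.lineage(9), s2),
        RefSeq("D1", 11, tree.lineage(11), decoy),
    ], mode="inclusive", min_length=250)
    return tree, db, s1, s2, decoy


class TestScreenContaminant:
    def test_identical_flagged(self):
        rng = random.Random(14)
        tree, db, s1, s2, decoy = make_screen_db(rng)
        ref = db.sequences[2]
        clusters = cluster_greedy([tmpl(decoy, "t0")])
        out = screen_contaminant(clusters, ref)
        assert FLAG_CONTAMINANT in out[0].flags

    def test_90_percent_kept(self):
        rng = random.Random(15)
        tree, db, s1, s2, decoy = make_screen_db(rng)
        ref = db.sequences[2]
        distant = mutate(rng, decoy, 40)  # ~90% identity
        assert segment_identity(distant, decoy) < 0.95
        clusters = cluster_greedy([tmpl(distant, "t0")])
        out = screen_contaminant(clusters, ref)
        assert FLAG_CONTAMINANT not in out[0].flags

    def test_empty_list(self):
        rng = random.Random(16)
        tree, db, s1, s2, decoy = make_screen_db(rng)
        assert screen_contaminant([], db.sequences[2]) == []


class TestScreenOffPhylum:
    def test_bee_cluster_kept(self):
        rng = random.Random(17)
        tree, db, s1, s2, decoy = make_screen_db(rng)
        clusters = cluster_greedy([tmpl(s1, "t0")])
        out = screen_off_phylum(clusters, db)
        assert FLAG_NON_ARTHROPOD not in out[0].flags

    def test_decoy_cluster_flagged(self):
        rng = random.Random(18)
        tree, db, s1, s2, decoy = make_screen_db(rng)
        clusters = cluster_greedy([tmpl(decoy, "t0")])
        out = screen_off_phylum(clusters, db)
        assert FLAG_NON_ARTHROPOD in out[0].flags

    def test_no_match_above_floor_flagged(self):
        rng = random.Random(19)
        tree, db, s1, s2, decoy = make_screen_db(rng)
        clusters = cluster_greedy([tmpl(random_dna(rng, 60), "t0")])
        out = screen_off_phylum(clusters, db, score_floor=100)
        assert FLAG_NON_ARTHROPOD in out[0].flags

    def test_requires_decoy(self):
        rng = random.Random(20)
        tree, db, s1, s2, decoy = make_screen_db(rng)
        no_decoy = CuratedDB(db.sequences[:2], mode="inclusive")
        with pytest.raises(ValueError, match="decoy"):
            screen_off_phylum([], no_decoy)


class TestFlagChimeras:
    def _db(self, rng):
        from beemeta.taxonomy import TaxonomyTree

        rows = [(1, "root", "no_rank", 1), (2, "Arthropoda", "phylum", 1),
                (3, "Insecta", "class", 2), (4, "Hymenoptera", "order", 3),
                (5, "Apidae", "family", 4), (6, "Bombus", "genus", 5),
                (7, "Bombus sp1", "species", 6), (8, "Halictus", "genus", 5),
                (9, "Halictus sp1", "species", 8)]
        tree = TaxonomyTree.build(rows)
        a = random_dna(rng, 400)
        b = mutate(rng, a, 80)  # 80% identity: clearly distinct parents
        db = CuratedDB([RefSeq("A", 7, tree.lineage(7), a),
                        RefSeq("B", 9, tree.lineage(9), b)],
                       mode="inclusive", min_length=250)
        return db, a, b

    def test_constructed_splice_flagged(self):
        rng = random.Random(21)
        db, a, b = self._db(rng)
        splice = a[:200] + b[200:]
        clusters = cluster_greedy([tmpl(splice, "t0")])
        out = flag_chimeras(clusters, db)
        assert FLAG_CHIMERA in out[0].flags

    def test_clean_copy_not_flagged(self):
        rng = random.Random(22)
        db, a, b = self._db(rng)
        clusters = cluster_greedy([tmpl(a, "t0")])
        out = flag_chimeras(clusters, db)
        assert FLAG_CHIMERA not in out[0].flags

    def test_splice_of_identical_parents_not_flagged(self):
        rng = random.Random(23)
        from beemeta.taxonomy import TaxonomyTree

        rows = [(1, "root", "no_rank", 1), (2, "Arthropoda", "phylum", 1),
                (3, "Insecta", "class", 2), (4, "Hymenoptera", "order", 3),
                (5, "Apidae", "family", 4), (6, "Bombus", "genus", 5),
                (7, "Bombus sp1", "species", 6), (8, "Bombus sp2", "species", 6)]
        tree = TaxonomyTree.build(rows)
        a = random_dna(rng, 400)
        db = CuratedDB([RefSeq("A", 7, tree.lineage(7), a),
                        RefSeq("B", 8, tree.lineage(8), a)],
                       mode="inclusive", min_length=250)
        splice = a[:200] + a[200:]  # "splice" of two identical sequences
        out = flag_chimeras(cluster_greedy([tmpl(splice, "t0")]), db)
        assert FLAG_CHIMERA not in out[0].flags

    def test_filters_conserve_cluster_count(self):
        rng = random.Random(24)
        db, a, b = self._db(rng)
        templates = [tmpl(a, f"a{i}") for i in range(12)] + [tmpl(b, "b0")]
        clusters = cluster_greedy(templates)
        n = len(clusters)
        clusters = censor_small(clusters)
        clusters = flag_chimeras(clusters, db)
        assert len(clusters) == n
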