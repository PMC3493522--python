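import itertools
import random

import pytest

from taxlca import (
    AlignmentHit,
    ClassifierError,
    ClassifierParams,
    QueryHits,
    Rank,
    Status,
    classify_all,
    classify_query,
    lca_assign,
    select_hits,
    similarity_filter,
    simulate_hits,
)


def hit(qid, sid, bitscore, identity=98.0, length=500):
    return AlignmentHit(qid, sid, bitscore, identity, length)


@pytest.fixture(scope="module")
def refmap(linear_taxonomy):
    """Accession -> node map over the hand-built taxonomy."""
    t = linear_taxonomy
    return {
        "ECOLI": t.node("Escherichia coli"),
        "ESCH1": t.node("Escherichia"),
        "SALM1": t.node("Salmonella"),
        "VIBR1": t.node("Vibrio"),
        "LACT1": t.node("Lactobacillus"),
        "THAU1": t.node("Thaumarchaeota"),
    }


class TestSelectHits:
    def test_two_percent_window_below_best(self):
        q = QueryHits(
            "q", [hit("q", f"r{i}", score) for i, score in enumerate([1000, 990, 980, 979, 500])]
        )
        selected = select_hits(q, ClassifierParams())
        assert [h.bitscore for h in selected] == [1000, 990, 980]

    def test_best_below_minimum_score_signals_unclassified(self):
        q = QueryHits("q", [hit("q", "r", 150.0)])
        assert select_hits(q, ClassifierParams()) is None
        # boundary is inclusive: exactly 155 is eligible
        q = QueryHits("q", [hit("q", "r", 155.0)])
        assert select_hits(q, ClassifierParams()) is not None

    def test_zero_range_keeps_only_ties(self):
        q = QueryHits(
            "q",
            [hit("q", "r1", 1000.0), hit("q", "r2", 1000.0, 97.0), hit("q", "r3", 999.0)],
        )
        selected = select_hits(q, ClassifierParams(lca_range_percent=0.0))
        assert {h.subject_accession for h in selected} == {"r1", "r2"}

    def test_subset_always_contains_best_hit(self):
        q = QueryHits("q", [hit("q", "r1", 800.0), hit("q", "r2", 640.0)])
        for x in (0.0, 1.0, 5.0, 50.0):
            selected = select_hits(q, ClassifierParams(lca_range_percent=x))
            assert selected[0].bitscore == 800.0


class TestLcaAssign:
    def test_unanimous_genus(self, refmap):
        sel = [hit("q", "ESCH1", 1000), hit("q", "ESCH1", 990)]
        assert lca_assign(sel, refmap).name == "Escherichia"

    def test_two_genera_one_family(self, refmap):
        sel = [hit("q", "ESCH1", 1000), hit("q", "SALM1", 995)]
        assert lca_assign(sel, refmap).name == "Enterobacteriaceae"

    def test_hits_spanning_two_domains_give_root(self, refmap):
        sel = [hit("q", "ESCH1", 1000), hit("q", "THAU1", 995)]
        assert lca_assign(sel, refmap).name == "root"

    def test_unknown_accession_named_in_error(self, refmap):
        with pytest.raises(ClassifierError, match="MISSING"):
            lca_assign([hit("q", "MISSING", 1000)], refmap)


class TestSimilarityFilter:
    @pytest.mark.parametrize(
        "start,identity,expected,demoted",
        [
            ("Escherichia", 96.5, "Enterobacteriaceae", True),  # fails genus 97, passes family 95
            ("Escherichia", 100.0, "Escherichia", False),
            ("Escherichia", 79.0, "Bacteria", True),  # fails every threshold incl. phylum 80
            ("Escherichia coli", 99.0, "Escherichia coli", False),  # species needs >= 99
            ("Escherichia coli", 98.9, "Escherichia", True),
            ("Escherichia", 97.0, "Escherichia", False),  # inclusive boundary
            ("Enterobacterales", 90.0, "Enterobacterales", False),
            ("Enterobacterales", 89.9, "Gammaproteobacteria", True),
            ("Proteobacteria", 80.0, "Proteobacteria", False),
            ("Bacteria", 10.0, "Bacteria", False),  # rootward of phylum: always allowed
        ],
    )
    def test_demotion_walks_to_deepest_allowed_rank(
        self, linear_taxonomy, start, identity, expected, demoted
    ):
        node, was_demoted = similarity_filter(
            linear_taxonomy.node(start), identity, ClassifierParams()
        )
        assert node.name == expected
        assert was_demoted is demoted

    def test_norank_node_inherits_nearest_ranked_ancestor_threshold(self):
        from taxlca import Taxonomy

        t = Taxonomy.create("root")
        d = t.add("Bacteria", t.root, Rank.DOMAIN)
        p = t.add("Acidobacteria", d, Rank.PHYLUM)
        clade = t.add("Subgroup 2", p)  # norank below phylum: threshold 80
        node, demoted = similarity_filter(clade, 81.0, ClassifierParams())
        assert node is clade and not demoted
        node, demoted = similarity_filter(clade, 79.0, ClassifierParams())
        assert node is d and demoted


class TestClassifyQuery:
    def test_single_perfect_hit_assigns_to_genus(self, refmap):
        q = QueryHits("q", [hit("q", "ESCH1", 400.0, 100.0)])
        r = classify_query(q, refmap)
        assert r.status is Status.ASSIGNED
        assert r.assigned_node.name == "Escherichia"

    def test_family_lca_retained_at_family(self, refmap):
        # hand-trace: both hits selected (985 >= 980), LCA = family,
        # best identity 98.1 >= 95 so the family placement stands
        q = QueryHits(
            "q",
            [hit("q", "ESCH1", 1000.0, 98.1), hit("q", "SALM1", 985.0, 97.0)],
        )
        r = classify_query(q, refmap)
        assert r.status is Status.ASSIGNED
        assert r.assigned_node.name == "Enterobacteriaceae"
        assert r.pre_filter_node.name == "Enterobacteriaceae"

    def test_low_identity_demotes_with_unknown_flag(self, refmap):
        # 90% fails genus (97) and family (95), passes order (90, inclusive)
        q = QueryHits("q", [hit("q", "ESCH1", 1000.0, 90.0)])
        r = classify_query(q, refmap)
        assert r.status is Status.UNKNOWN_DEMOTED
        assert r.assigned_node.name == "Enterobacterales"
        assert r.pre_filter_node.name == "Escherichia"

    def test_below_min_score_unclassified(self, refmap):
        q = QueryHits("q", [hit("q", "ESCH1", 120.0, 100.0)])
        r = classify_query(q, refmap)
        assert r.status is Status.UNCLASSIFIED_LOW_SCORE
        assert r.assigned_node is None

    def test_no_hits_unclassified(self, refmap):
        r = classify_query(None, refmap)
        assert r.status is Status.UNCLASSIFIED_NO_HITS

    def test_assignment_invariant_under_hit_permutation(self, refmap):
        hits = [
            hit("q", "ESCH1", 1000.0, 98.0),
            hit("q", "SALM1", 990.0, 97.5),
            hit("q", "VIBR1", 985.0, 96.0),
            hit("q", "LACT1", 700.0, 85.0),
        ]
        names = set()
        for perm in itertools.permutations(hits):
            r = classify_query(QueryHits("q", perm), refmap)
            names.add((r.assigned_node.name, r.status))
        assert len(names) == 1

    def test_assigned_node_is_ancestor_of_pre_filter_lca(self, refmap):
        rng = random.Random(2)
        accs = list(refmap)
        for _ in range(200):
            chosen = rng.sample(accs, rng.randint(1, 4))
            hits = [
                hit("q", acc, rng.uniform(200, 1000), rng.uniform(75, 100))
                for acc in chosen
            ]
            r = classify_query(QueryHits("q", hits), refmap)
            if r.assigned_node is not None:
                assert r.assigned_node.is_ancestor_or_self_of(r.pre_filter_node)


class TestMonotonicity:
    X_GRID = [0.0, 0.5, 1.0, 2.0, 5.0, 10.0]

    def test_wider_lca_range_never_deepens_assignment(self, default_db):
        rng = random.Random(9)
        accs = rng.sample(default_db.accessions, 12)
        for acc in accs:
            query = default_db.sequences[acc]
            qh = simulate_hits(acc, query, default_db)
            depths = []
            for x in self.X_GRID:
                r = classify_query(
                    qh, default_db.assignments, ClassifierParams(lca_range_percent=x)
                )
                assert r.assigned_node is not None
                depths.append(r.assigned_node.depth)
            assert depths == sorted(depths, reverse=True)

    def test_lower_identity_never_deepens_post_filter_assignment(self, linear_taxonomy):
        node = linear_taxonomy.node("Escherichia coli")
        params = ClassifierParams()
        depths = [
            similarity_filter(node, identity, params)[0].depth
            for identity in [100, 99, 98, 96, 94, 89, 84, 79]
        ]
        assert depths == sorted(depths, reverse=True)

    def test_defaults_beat_disabled_filters_on_noisy_fixture(self, default_db):
        # parameter recovery, direction only: with identity noise, the default
        # range + thresholds yield higher genus precision than x=0 and no filter
        from taxlca import Rank, make_amplicon_dataset, score_at_rank

        queries, truth = make_amplicon_dataset(
            default_db, n_queries=80, seed=21, noise_percent=3.5
        )
        permissive = ClassifierParams(
            lca_range_percent=0.0,
            rank_thresholds={
                Rank.SPECIES: 5.0, Rank.GENUS: 4.0, Rank.FAMILY: 3.0,
                Rank.ORDER: 2.0, Rank.CLASS: 1.0, Rank.PHYLUM: 0.5,
            },
        )
        def genus_precision(params):
            tp = fp = 0
            for name, seq in queries:
                base = name.rsplit("_", 1)[0]
                qh = simulate_hits(name, seq, default_db)
                r = classify_query(qh, default_db.assignments, params)
                truth_node = default_db.taxonomy.node(truth[base])
                outcome = score_at_rank(truth_node, r, Rank.GENUS)
                tp += outcome == "TP"
                fp += outcome == "FP"
            return tp / (tp + fp) if (tp + fp) else 1.0

        assert genus_precision(ClassifierParams()) >= genus_precision(permissive)


class TestClassifyAll:
    def test_empty_input(self, refmap):
        assert classify_all([], [], refmap) == []

    def test_missing_hit_sets_reported_no_hits(self, refmap):
        qids = [f"q{i}" for i in range(10)]
        hit_sets = [
            QueryHits(qid, [hit(qid, "ESCH1", 900.0)]) for qid in qids[:7]
        ]
        results = classify_all(qids, hit_sets, refmap)
        assert [r.query_id for r in results] == qids
        assert sum(r.status is Status.UNCLASSIFIED_NO_HITS for r in results) == 3

    def test_batch_equals_per_query(self, refmap):
        qids = ["a", "b"]
        hs = [
            QueryHits("a", [hit("a", "ESCH1", 900.0)]),
            QueryHits("b", [hit("b", "VIBR1", 850.0, 91.0)]),
        ]
        batch = classify_all(qids, hs, refmap)
        single = [classify_query(h, refmap) for h in hs]
        for b, s in zip(batch, single):
            assert (b.assigned_node, b.status) == (s.assigned_node, s.status)

    def test_duplicate_query_ids_rejected(self, refmap):
        with pytest.raises(ClassifierError, match="duplicate"):
            classify_all(["a", "a"], [], refmap)


class TestParams:
    def test_negative_range_rejected(self):
        with pytest.raises(ClassifierError):
            ClassifierParams(lca_range_percent=-1)

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ClassifierError):
            ClassifierParams(rank_thresholds={Rank.GENUS: 95.0, Rank.FAMILY: 96.0})
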