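"""Mild/strict filtering, cluster pairing, family construction, overlap."""

import dataclasses

import numpy as np
import pytest

from rippscout.clusters import GeneCluster
from rippscout.families import (MILD, STRICT, ClusterPairEdge,
                                antismash_overlap, apply_filter,
                                build_families, pair_clusters)
from rippscout.genome_io import GeneModel


def make_cluster(cid="c", mean_cog=0.1, n_genes=4, biosynthetic=2,
                 transporter=1, regulator=1, peptidase=1, domains=(),
                 precursor_seq="MKCSTCSTCSTAAGGCSTCST", start=0):
    genes = [GeneModel(f"{cid}_g{i}", "ctg", start + i * 200,
                       start + i * 200 + 150, "+",
                       precursor_seq if i == 0 else "M" * 40)
             for i in range(n_genes)]
    cluster = GeneCluster(cid, "gen", "ctg", "+", genes,
                          precursor_ids=[f"{cid}_g0"], mean_cog=mean_cog)
    cluster.category_counts = {"biosynthetic": biosynthetic,
                               "transporter": 0, "regulator": 0,
                               "peptidase": 0}
    cluster.flank_category_counts = {"transporter": transporter,
                                     "regulator": regulator,
                                     "peptidase": peptidase,
                                     "biosynthetic": 0}
    cluster.domains = set(domains)
    return cluster


class TestApplyFilter:
    def test_cog_score_boundary(self):
        assert apply_filter(make_cluster(mean_cog=0.25), MILD).passed
        report = apply_filter(make_cluster(mean_cog=0.26), MILD)
        assert not report.passed
        failing = [c.name for c in report.criteria if not c.passed]
        assert failing == ["mean_cog"]

    def test_two_gene_cluster_fails_min_genes(self):
        assert not apply_filter(make_cluster(n_genes=2), MILD).passed

    def test_strict_requires_regulator_and_peptidase(self):
        cluster = make_cluster(mean_cog=0.05, regulator=0)
        assert apply_filter(cluster, MILD).passed
        assert not apply_filter(cluster, STRICT).passed

    def test_scope_cluster_only_ignores_flanks(self):
        spec = dataclasses.replace(MILD, search_scope="cluster_only")
        cluster = make_cluster()  # transporter only in flanks
        assert not apply_filter(cluster, spec).passed

    @pytest.mark.parametrize("seed", range(10))
    def test_strict_pass_implies_mild_pass(self, seed):
        rng = np.random.default_rng(seed)
        cluster = make_cluster(
            mean_cog=float(rng.uniform(0, 0.4)),
            n_genes=int(rng.integers(2, 7)),
            biosynthetic=int(rng.integers(0, 4)),
            transporter=int(rng.integers(0, 2)),
            regulator=int(rng.integers(0, 2)),
            peptidase=int(rng.integers(0, 2)))
        if apply_filter(cluster, STRICT).passed:
            assert apply_filter(cluster, MILD).passed

    @pytest.mark.parametrize("seed", range(10))
    def test_tightening_any_field_never_enlarges_pass_set(self, seed):
        rng = np.random.default_rng(100 + seed)
        clusters = [make_cluster(
            cid=f"c{i}", mean_cog=float(rng.uniform(0, 0.4)),
            n_genes=int(rng.integers(2, 7)),
            biosynthetic=int(rng.integers(0, 4)),
            transporter=int(rng.integers(0, 2)),
            regulator=int(rng.integers(0, 2)),
            peptidase=int(rng.integers(0, 2))) for i in range(12)]
        base = MILD
        tighter_specs = [
            dataclasses.replace(base, max_mean_cog=base.max_mean_cog / 2),
            dataclasses.replace(base, min_genes=base.min_genes + 1),
            dataclasses.replace(base, min_biosynthetic=base.min_biosynthetic + 1),
            dataclasses.replace(base, require_regulator=True),
            dataclasses.replace(base, require_peptidase=True),
        ]
        base_pass = {c.id for c in clusters if apply_filter(c, base).passed}
        for spec in tighter_specs:
            tight_pass = {c.id for c in clusters
                          if apply_filter(c, spec).passed}
            assert tight_pass <= base_pass


PRECURSOR_A = "MGGCSSTTCCGGSSTTCCAAWWGGCSSTTCC"
PRECURSOR_B = "MKELVDYIRNQPEWFKHLDAIRMNPQ"


class TestPairClusters:
    def test_identical_clusters_pair_with_distance_one(self):
        a = make_cluster("a", domains={"D1", "D2"},
                         precursor_seq=PRECURSOR_A)
        b = make_cluster("b", domains={"D1", "D2"},
                         precursor_seq=PRECURSOR_A)
        edge = pair_clusters(a, b)
        assert edge is not None
        assert edge.jaccard == pytest.approx(1.0)
        assert edge.precursor_identity == pytest.approx(1.0)
        assert edge.distance == pytest.approx(1.0)

    def test_low_jaccard_rejected_despite_similar_precursors(self):
        a = make_cluster("a", domains={"D1", "D2", "D3", "D4", "D5"},
                         precursor_seq=PRECURSOR_A)
        b = make_cluster("b", domains={"D1", "D2", "D6", "D7", "D8"},
                         precursor_seq=PRECURSOR_A)
        assert pair_clusters(a, b) is None  # jaccard 2/8 = 0.25

    def test_low_precursor_bitscore_rejected_despite_jaccard(self):
        a = make_cluster("a", domains={"D1", "D2"}, precursor_seq=PRECURSOR_A)
        b = make_cluster("b", domains={"D1", "D2"}, precursor_seq=PRECURSOR_B)
        assert pair_clusters(a, b) is None

    def test_symmetric(self):
        a = make_cluster("a", domains={"D1", "D2"}, precursor_seq=PRECURSOR_A)
        b = make_cluster("b", domains={"D1", "D2", "D3"},
                         precursor_seq=PRECURSOR_A)
        ab, ba = pair_clusters(a, b), pair_clusters(b, a)
        assert ab is not None and ba is not None
        assert ab.jaccard == pytest.approx(ba.jaccard)
        assert ab.precursor_identity == pytest.approx(ba.precursor_identity)


class TestBuildFamilies:
    def _edge(self, a, b, jac=0.9, ident=0.9):
        return ClusterPairEdge(a, b, jac, ident)

    def test_triangle_forms_family_of_three(self):
        edges = [self._edge("a", "b"), self._edge("b", "c"),
                 self._edge("a", "c")]
        families, ungrouped = build_families(edges)
        assert [sorted(f.members) for f in families] == [["a", "b", "c"]]
        assert ungrouped == []

    def test_pair_below_min_size_is_ungrouped(self):
        families, ungrouped = build_families([self._edge("a", "b")])
        assert families == []
        assert ungrouped == ["a", "b"]

    def test_disconnected_planted_families_stay_separate(self):
        edges = ([self._edge(f"x{i}", f"x{j}") for i in range(4)
                  for j in range(i + 1, 4)]
                 + [self._edge(f"y{i}", f"y{j}") for i in range(3)
                    for j in range(i + 1, 3)])
        families, _ = build_families(edges)
        got = {frozenset(f.members) for f in families}
        assert got == {frozenset({f"x{i}" for i in range(4)}),
                       frozenset({f"y{i}" for i in range(3)})}

    def test_recovers_planted_partition_of_twenty_clusters(self):
        # 4 planted families of 5: intra-family Jaccard >= 0.7,
        # inter-family <= 0.2
        rng = np.random.default_rng(5)
        clusters = {}
        for fam_i in range(4):
            base = {f"F{fam_i}_D{k}" for k in range(8)}
            shared = {"COMMON1"}  # small cross-family overlap
            for m in range(5):
                cid = f"f{fam_i}_m{m}"
                drop = set(rng.choice(sorted(base), size=1))
                clusters[cid] = make_cluster(
                    cid, domains=(base - drop) | shared,
                    precursor_seq=PRECURSOR_A)
        edges = []
        ids = sorted(clusters)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                edge = pair_clusters(clusters[a], clusters[b])
                if edge:
                    edges.append(edge)
        families, ungrouped = build_families(edges)
        got = {frozenset(f.members) for f in families}
        expected = {frozenset(f"f{k}_m{m}" for m in range(5))
                    for k in range(4)}
        assert got == expected
        assert ungrouped == []


class TestAntismashOverlap:
    def _family(self, members):
        from rippscout.families import ClusterFamily
        return ClusterFamily(list(members))

    def test_cluster_inside_region_is_flagged(self):
        cluster = make_cluster("a", start=1000)
        flags, _r, _d = antismash_overlap(
            [cluster], [], [("ctg", 500, 5000, "nrps")])
        assert flags["a"] == "non_ripp"

    def test_family_with_three_quarters_overlap_discarded(self):
        clusters = [make_cluster(f"m{i}", start=i * 10_000) for i in range(4)]
        regions = [("ctg", i * 10_000, i * 10_000 + 500, "t1pks")
                   for i in range(3)]
        fam = self._family([c.id for c in clusters])
        _f, retained, discarded = antismash_overlap(clusters, [fam], regions)
        assert discarded == [fam] and retained == []
        assert fam.antismash_overlap_fraction == pytest.approx(0.75)

    def test_exactly_half_overlap_retained(self):
        clusters = [make_cluster(f"m{i}", start=i * 10_000) for i in range(4)]
        regions = [("ctg", i * 10_000, i * 10_000 + 500, "terpene")
                   for i in range(2)]
        fam = self._family([c.id for c in clusters])
        _f, retained, discarded = antismash_overlap(clusters, [fam], regions)
        assert retained == [fam] and discarded == []

    def test_ripp_regions_do_not_trigger_discard(self):
        clusters = [make_cluster(f"m{i}", start=i * 10_000) for i in range(3)]
        regions = [("ctg", i * 10_000, i * 10_000 + 500, "lanthipeptide")
                   for i in range(3)]
        fam = self._family([c.id for c in clusters])
        flags, retained, _d = antismash_overlap(clusters, [fam], regions)
        assert all(flags[c.id] == "ripp" for c in clusters)
        assert retained == [fam]

    def test_missing_regions_marks_unknown_and_keeps_all(self):
        clusters = [make_cluster("a")]
        fam = self._family(["a"])
        flags, retained, discarded = antismash_overlap(clusters, [fam], None)
        assert flags == {"a": "unknown"}
        assert retained == [fam] and discarded == []
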