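"""BBH graph, trueCOG detection, identity cutoffs, COG scores, subgrouping."""

import itertools

import numpy as np
import pytest

from rippscout.align import HomologyHit, PrecomputedHitsEngine
from rippscout.genome_io import Contig, GeneModel, GenomeRecord
from rippscout.pangenome import (SubgroupingRequired, build_bbh_graph,
                                 build_cog_table, find_truecogs,
                                 pairwise_cutoffs, partition_genomes)


def _hit(q, s, identity, bits=100.0):
    return HomologyHit(q, s, identity, bits, 1.0)


def _engine(hits):
    return PrecomputedHitsEngine(hits)


class TestBbhGraph:
    def test_single_mutual_best_pair(self):
        prot = {"A": {"a1": "M"}, "B": {"b1": "M"}}
        graph = build_bbh_graph(prot, _engine([_hit("a1", "b1", 80),
                                               _hit("b1", "a1", 80)]))
        assert graph.has_edge("a1", "b1")
        assert graph.edges["a1", "b1"]["identity"] == pytest.approx(80)

    def test_identity_below_60_is_rejected(self):
        prot = {"A": {"a1": "M"}, "B": {"b1": "M"}}
        graph = build_bbh_graph(prot, _engine([_hit("a1", "b1", 59.9),
                                               _hit("b1", "a1", 59.9)]))
        assert graph.number_of_edges() == 0

    def test_asymmetric_best_hits_give_no_edge(self):
        # a1's best is b1, but b1's best is a2 (paralog triangle)
        prot = {"A": {"a1": "M", "a2": "M"}, "B": {"b1": "M"}}
        hits = [_hit("a1", "b1", 90, bits=100),
                _hit("a2", "b1", 88, bits=90),
                _hit("b1", "a2", 95, bits=200),
                _hit("b1", "a1", 90, bits=100)]
        graph = build_bbh_graph(prot, _engine(hits))
        assert not graph.has_edge("a1", "b1")
        # the mutual pair is (a2, b1): each is the other's best hit
        assert graph.has_edge("a2", "b1")
        assert graph.number_of_edges() == 1

    def test_empty_proteome_raises(self):
        with pytest.raises(ValueError, match="empty proteome"):
            build_bbh_graph({"A": {}, "B": {"b1": "M"}}, _engine([]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_best_hit_oracle(self, seed):
        rng = np.random.default_rng(seed)
        prot = {g: {f"{g}{i}": "M" for i in range(rng.integers(2, 6))}
                for g in "AB"}
        hits = []
        for q in prot["A"]:
            for s in prot["B"]:
                for a, b in ((q, s), (s, q)):
                    if rng.random() < 0.8:
                        hits.append(_hit(a, b, float(rng.uniform(40, 100)),
                                         bits=float(rng.uniform(50, 300))))
        graph = build_bbh_graph(prot, _engine(hits), min_identity=60.0)
        # oracle: exhaustive mutual-best computation
        def best(frm, to):
            out = {}
            for h in hits:
                if h.query_gene in prot[frm] and h.subject_gene in prot[to]:
                    cur = out.get(h.query_gene)
                    if cur is None or (h.bitscore, h.percent_identity,
                                       h.subject_gene) > (
                            cur.bitscore, cur.percent_identity,
                            cur.subject_gene):
                        out[h.query_gene] = h
            return out
        fwd, rev = best("A", "B"), best("B", "A")
        expected = set()
        for q, h in fwd.items():
            back = rev.get(h.subject_gene)
            if back and back.subject_gene == q:
                ident = (h.percent_identity + back.percent_identity) / 2
                if ident >= 60.0:
                    expected.add(frozenset((q, h.subject_gene)))
        assert {frozenset(e) for e in graph.edges} == expected

    def test_min_identity_monotonicity(self):
        prot = {"A": {"a1": "M", "a2": "M"}, "B": {"b1": "M", "b2": "M"}}
        hits = [_hit("a1", "b1", 70), _hit("b1", "a1", 70),
                _hit("a2", "b2", 90), _hit("b2", "a2", 90)]
        lo = build_bbh_graph(prot, _engine(hits), min_identity=60.0)
        hi = build_bbh_graph(prot, _engine(hits), min_identity=80.0)
        assert set(hi.edges) <= set(lo.edges)


def _synteny_genomes(gene_orders):
    """Genomes with the given per-genome gene-id orders, dummy sequences."""
    genomes = []
    for gid, order in gene_orders.items():
        genes = []
        for i, gene_id in enumerate(order):
            genes.append(GeneModel(gene_id, f"{gid}_c", i * 200,
                                   i * 200 + 150, "+", "M" * 40))
        genomes.append(GenomeRecord(
            gid, [Contig(f"{gid}_c", "A" * (len(order) * 200 + 10))], genes))
    return genomes


def _full_bbh(gene_orders, identity=90.0, skip_pairs=()):
    """BBH graph linking genes with the same suffix across genomes."""
    import networkx as nx
    graph = nx.Graph()
    for gid, order in gene_orders.items():
        for gene in order:
            graph.add_node(gene, genome=gid)
    names = {}
    for gid, order in gene_orders.items():
        for gene in order:
            suffix = gene.split("_", 1)[1]
            names.setdefault(suffix, []).append(gene)
    for suffix, members in names.items():
        for a, b in itertools.combinations(members, 2):
            if frozenset((a, b)) in skip_pairs:
                continue
            graph.add_edge(a, b, identity=identity, bitscore=200.0)
    return graph


class TestTrueCogs:
    ORDERS3 = {"g1": ["g1_x", "g1_y", "g1_z", "g1_q"],
               "g2": ["g2_x", "g2_y", "g2_z", "g2_q"],
               "g3": ["g3_x", "g3_y", "g3_z", "g3_q"]}

    def test_conserved_triplet_center_is_truecog(self):
        genomes = _synteny_genomes(self.ORDERS3)
        truecogs = find_truecogs(genomes, _full_bbh(self.ORDERS3))
        groups = {frozenset(g) for g in truecogs.groups}
        assert frozenset(("g1_y", "g2_y", "g3_y")) in groups

    def test_missing_flank_homolog_breaks_truecog(self):
        orders = {"g1": ["g1_x", "g1_y", "g1_z", "g1_q"],
                  "g2": ["g2_x", "g2_y", "g2_z", "g2_q"],
                  "g3": ["g3_x", "g3_y", "g3_w", "g3_q"]}  # g3 lacks z
        genomes = _synteny_genomes(orders)
        truecogs = find_truecogs(genomes, _full_bbh(orders))
        assert all("g1_y" not in g for g in truecogs.groups)

    def test_contig_edge_genes_never_truecogs(self):
        genomes = _synteny_genomes(self.ORDERS3)
        truecogs = find_truecogs(genomes, _full_bbh(self.ORDERS3))
        for group in truecogs.groups:
            assert not any(g.endswith("_x") or g.endswith("_q")
                           for g in group)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_over_triplets(self, seed):
        rng = np.random.default_rng(seed)
        suffixes = [f"s{i}" for i in range(8)]
        orders = {}
        for gid in ("g1", "g2", "g3", "g4"):
            perm = list(suffixes)
            if rng.random() < 0.5:  # permute a random block
                i = int(rng.integers(0, 6))
                perm[i], perm[i + 1] = perm[i + 1], perm[i]
            orders[gid] = [f"{gid}_{s}" for s in perm]
        bbh = _full_bbh(orders)
        genomes = _synteny_genomes(orders)
        got = {frozenset(g) for g in find_truecogs(genomes, bbh).groups}
        # brute force: for every suffix, check all cross-genome pairs are
        # BBH with flank correspondence
        expected = set()
        for s in suffixes:
            members = [f"{gid}_{s}" for gid in orders]
            neighbors = {}
            edge = False
            for gid, order in orders.items():
                i = order.index(f"{gid}_{s}")
                if i == 0 or i == len(order) - 1:
                    edge = True
                    break
                neighbors[gid] = (order[i - 1], order[i + 1])
            if edge:
                continue
            ok = True
            for ga, gb in itertools.combinations(orders, 2):
                a, b = f"{ga}_{s}", f"{gb}_{s}"
                if not bbh.has_edge(a, b):
                    ok = False
                    break
                (ap, an), (bp, bn) = neighbors[ga], neighbors[gb]
                direct = bbh.has_edge(ap, bp) and bbh.has_edge(an, bn)
                inverted = bbh.has_edge(ap, bn) and bbh.has_edge(an, bp)
                if not (direct or inverted):
                    ok = False
                    break
            if ok:
                expected.add(frozenset(members))
        assert got == expected


class TestPairwiseCutoffs:
    def test_zero_spread_gives_cutoff_at_mean(self, pangenome_analysis):
        pa = pangenome_analysis
        for cut in pairwise_cutoffs(pa.truecogs, pa.bbh):
            if cut.sd_identity == 0:
                assert cut.cutoff == pytest.approx(cut.mean_identity)

    def test_mean_minus_three_sd(self):
        orders = {"g1": ["g1_x", "g1_y", "g1_z"],
                  "g2": ["g2_x", "g2_y", "g2_z"]}
        bbh = _full_bbh(orders, identity=85.0)
        genomes = _synteny_genomes(orders)
        truecogs = find_truecogs(genomes, bbh)
        (cut,) = pairwise_cutoffs(truecogs, bbh)
        assert cut.cutoff == pytest.approx(85.0)  # single value, sd 0

    def test_recount_oracle(self, pangenome_analysis):
        pa = pangenome_analysis
        cuts = pairwise_cutoffs(pa.truecogs, pa.bbh)
        for cut in cuts:
            idents = []
            for group in pa.truecogs.groups:
                pair = [g for g in group
                        if pa.genome_of[g] in (cut.genome_a, cut.genome_b)]
                idents.append(pa.bbh.edges[pair[0], pair[1]]["identity"])
            assert cut.mean_identity == pytest.approx(np.mean(idents))
            assert cut.sd_identity == pytest.approx(np.std(idents))
            assert cut.cutoff == pytest.approx(
                max(0.0, np.mean(idents) - 3 * np.std(idents)), abs=1e-9)

    def test_no_truecogs_signals_subgrouping(self):
        from rippscout.pangenome import TrueCogSet
        with pytest.raises(SubgroupingRequired):
            pairwise_cutoffs(TrueCogSet([], ["g1", "g2"]), None)


class TestCogTable:
    def _cutoffs(self, genomes, cutoff=50.0):
        from rippscout.pangenome import PairCutoff
        return [PairCutoff(a, b, cutoff, 0.0, 1)
                for a, b in itertools.combinations(genomes, 2)]

    def test_universal_gene_scores_one(self):
        genome_of = {f"g{i}_u": f"g{i}" for i in range(1, 5)}
        hits = [_hit(a, b, 90) for a, b in
                itertools.permutations(genome_of, 2)]
        table = build_cog_table(hits, self._cutoffs([f"g{i}" for i in
                                                     range(1, 5)]),
                                genome_of)
        assert all(table.score_of(g) == pytest.approx(1.0) for g in genome_of)

    def test_singleton_scores_one_over_n(self):
        genome_of = {f"g{i}_x{i}": f"g{i}" for i in range(1, 11)}
        table = build_cog_table([], self._cutoffs([f"g{i}" for i in
                                                   range(1, 11)]),
                                genome_of, genes=list(genome_of))
        assert table.score_of("g1_x1") == pytest.approx(0.1)

    def test_paralogs_counted_by_distinct_genome(self):
        # g1 carries two in-paralogs of a gene universal in 3 genomes
        genome_of = {"g1_a": "g1", "g1_b": "g1", "g2_a": "g2", "g3_a": "g3"}
        hits = []
        for a, b in itertools.permutations(genome_of, 2):
            if genome_of[a] != genome_of[b]:
                hits.append(_hit(a, b, 95))
        table = build_cog_table(hits, self._cutoffs(["g1", "g2", "g3"]),
                                genome_of)
        assert table.score_of("g1_a") == pytest.approx(1.0)
        assert table.score_of("g1_b") == pytest.approx(1.0)

    def test_scores_invariant_to_genome_input_order(self, pangenome_analysis):
        pa = pangenome_analysis
        reordered_hits = list(reversed(pa.hits))
        table = build_cog_table(reordered_hits, pa.cutoffs, pa.genome_of,
                                [g for p in pa.proteomes.values() for g in p])
        assert {g: s for g, (_c, s) in table.assignments.items()} == \
               {g: s for g, (_c, s) in pa.cog.assignments.items()}


class TestPlantedRecovery:
    def test_core_genes_score_one(self, pangenome_analysis):
        pa = pangenome_analysis
        for gene, role in pa.truth.roles.items():
            if role == "core":
                assert pa.cog.score_of(gene) == pytest.approx(1.0)

    def test_planted_frequency_recovered_exactly(self, pangenome_analysis):
        pa = pangenome_analysis
        n = len(pa.genomes)
        for gene, role in pa.truth.roles.items():
            anc = pa.truth.ancestor_of[gene]
            expected = pa.truth.presence[anc] / n
            assert pa.cog.score_of(gene) == pytest.approx(expected), \
                (gene, role)

    def test_bimodal_structure(self, pangenome_analysis):
        pa = pangenome_analysis
        scores = [pa.cog.score_of(g) for g in pa.truth.roles]
        assert (np.array(scores) == 1.0).mean() > 0.5
        assert min(scores) < 0.5


class TestPartitionGenomes:
    def test_homogeneous_set_yields_single_group(self, pangenome_analysis):
        pa = pangenome_analysis
        groups = partition_genomes(pa.genomes, pa.bbh, min_truecogs=10)
        assert sorted(groups, key=len)[-1] == sorted(g.id for g in pa.genomes)

    def test_two_divergent_clades_split(self):
        orders = {}
        for gid in ("a1", "a2", "a3"):
            orders[gid] = [f"{gid}_p{i}" for i in range(6)]
        for gid in ("b1", "b2", "b3"):
            orders[gid] = [f"{gid}_q{i}" for i in range(6)]
        genomes = _synteny_genomes(orders)
        bbh = _full_bbh(orders)  # suffixes p*/q* never cross clades
        groups = partition_genomes(genomes, bbh, min_truecogs=2)
        tops = {frozenset(g) for g in groups if len(g) > 1}
        assert frozenset(("a1", "a2", "a3")) in tops
        assert frozenset(("b1", "b2", "b3")) in tops
        covered = {g for grp in groups for g in grp}
        assert covered == set(orders)

    def test_isolated_genome_becomes_own_subgroup(self):
        orders = {"a1": [f"a1_p{i}" for i in range(6)],
                  "a2": [f"a2_p{i}" for i in range(6)],
                  "z1": [f"z1_r{i}" for i in range(6)]}
        genomes = _synteny_genomes(orders)
        bbh = _full_bbh(orders)
        with pytest.warns(UserWarning, match="no trueCOGs"):
            groups = partition_genomes(genomes, bbh, min_truecogs=2)
        assert ["z1"] in groups
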