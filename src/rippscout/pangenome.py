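"""Core/accessory conservation scoring across a genome set.

The conservation signal used to separate candidate BGCs (accessory genome)
from housekeeping context (core genome) is the COG score: for each gene, the
fraction of query genomes containing a member of its group of close homologs.
The procedure is:

1. All-vs-all protein comparison; bidirectional best hits (BBHs) at >= 60%
   identity between every genome pair.
2. trueCOGs: synteny-anchored high-confidence orthologs — groups with exactly
   one member per genome where all cross-genome pairs are BBHs and both
   flanking genes are BBHs in correspondence.
3. Per genome pair, an identity cutoff mu - 3*sigma over that pair's trueCOG
   identities; gene pairs above the cutoff are linked.
4. Markov clustering of the linked pairs into COGs; per-gene score =
   (distinct genomes containing a COG member) / n_genomes.  Genes in no kept
   pair are singletons scoring 1/n.

When fewer than a minimum number of trueCOGs exist across the whole set, the
genomes are rearranged into overlapping subgroups that each support enough
trueCOGs (:func:`partition_genomes`).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from rippscout.align import HomologyHit
from rippscout.genome_io import GenomeRecord
from rippscout.mcl import markov_cluster

logger = logging.getLogger(__name__)


class SubgroupingRequired(RuntimeError):
    """Raised when no trueCOGs exist, so per-pair cutoffs cannot be set."""


@dataclass(frozen=True)
class PairCutoff:
    """Identity cutoff mu - 3*sigma for one unordered genome pair."""

    genome_a: str
    genome_b: str
    mean_identity: float
    sd_identity: float
    n_truecogs: int

    @property
    def cutoff(self) -> float:
        return max(0.0, self.mean_identity - 3.0 * self.sd_identity)

    def key(self) -> frozenset:
        return frozenset((self.genome_a, self.genome_b))


@dataclass
class TrueCogSet:
    """Synteny-anchored ortholog groups, one gene per genome per group."""

    groups: list[frozenset]
    genomes: list[str]

    def __len__(self) -> int:
        return len(self.groups)


@dataclass
class CogTable:
    """gene id -> (COG id, conservation score in [0, 1])."""

    assignments: dict[str, tuple[str, float]]
    n_genomes: int

    def score_of(self, gene_id: str) -> float:
        """Score of a gene; genes absent from the table are singletons."""
        if gene_id in self.assignments:
            return self.assignments[gene_id][1]
        return 1.0 / self.n_genomes

    def cog_of(self, gene_id: str) -> str | None:
        entry = self.assignments.get(gene_id)
        return entry[0] if entry else None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tcog\tscore\n")
            for gene in sorted(self.assignments):
                cog, score = self.assignments[gene]
                fh.write(f"{gene}\t{cog}\t{score:.6g}\n")


# ---------------------------------------------------------------------------
# BBH graph


def _best_hits(hits: list[HomologyHit]) -> dict[str, HomologyHit]:
    """Best hit per query by bitscore (ties: identity, then subject id)."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        cur = best.get(h.query_gene)
        if cur is None or (h.bitscore, h.percent_identity, h.subject_gene) > (
                cur.bitscore, cur.percent_identity, cur.subject_gene):
            best[h.query_gene] = h
    return best


def build_bbh_graph(proteomes: dict[str, dict[str, str]], engine,
                    min_identity: float = 60.0) -> nx.Graph:
    """Bidirectional-best-hit graph over a set of proteomes.

    Nodes are gene ids with a ``genome`` attribute; an edge joins two genes
    iff each is the other's best hit within its genome and their identity is
    at least ``min_identity`` percent.  Edge attributes: ``identity`` (mean of
    the two directed identities) and ``bitscore``.
    """
    for gid, prots in proteomes.items():
        if not prots:
            raise ValueError(f"genome {gid!r} has an empty proteome")
    graph = nx.Graph()
    for gid, prots in proteomes.items():
        for gene in prots:
            graph.add_node(gene, genome=gid)
    for ga, gb in itertools.combinations(sorted(proteomes), 2):
        fwd = _best_hits(engine.search(proteomes[ga], proteomes[gb]))
        rev = _best_hits(engine.search(proteomes[gb], proteomes[ga]))
        for qa, hit in fwd.items():
            back = rev.get(hit.subject_gene)
            if back is None or back.subject_gene != qa:
                continue
            identity = (hit.percent_identity + back.percent_identity) / 2.0
            if identity >= min_identity:
                graph.add_edge(qa, hit.subject_gene, identity=identity,
                               bitscore=max(hit.bitscore, back.bitscore))
    return graph


# ---------------------------------------------------------------------------
# trueCOGs


def _neighbors(genome: GenomeRecord) -> dict[str, tuple[str | None, str | None]]:
    """Flanking gene ids (previous, next) per gene, per contig order."""
    out: dict[str, tuple[str | None, str | None]] = {}
    for contig in genome.contigs:
        genes = genome.genes_on(contig.id)
        for i, g in enumerate(genes):
            prev = genes[i - 1].id if i > 0 else None
            nxt = genes[i + 1].id if i < len(genes) - 1 else None
            out[g.id] = (prev, nxt)
    return out


def _syntenic_pair_graph(genomes: list[GenomeRecord], bbh: nx.Graph) -> nx.Graph:
    """Graph of BBH pairs whose two flanking genes are also BBHs.

    Flank correspondence may be direct (prev-prev / next-next) or inverted
    (prev-next / next-prev) to tolerate locally inverted synteny blocks.
    Genes at contig edges, partial genes, and genes with partial flanks never
    participate.
    """
    neighbors: dict[str, tuple[str | None, str | None]] = {}
    partial = set()
    for genome in genomes:
        neighbors.update(_neighbors(genome))
        partial.update(g.id for g in genome.genes if g.partial)

    def anchorable(gene: str) -> bool:
        prev, nxt = neighbors.get(gene, (None, None))
        return (gene not in partial and prev is not None and nxt is not None
                and prev not in partial and nxt not in partial)

    pair_graph = nx.Graph()
    for a, b in bbh.edges:
        if not (anchorable(a) and anchorable(b)):
            continue
        ap, an = neighbors[a]
        bp, bn = neighbors[b]
        direct = bbh.has_edge(ap, bp) and bbh.has_edge(an, bn)
        inverted = bbh.has_edge(ap, bn) and bbh.has_edge(an, bp)
        if direct or inverted:
            pair_graph.add_edge(a, b)
    return pair_graph


def find_truecogs(genomes: list[GenomeRecord], bbh: nx.Graph) -> TrueCogSet:
    """Groups of genes that are synteny-anchored BBHs across *all* genomes.

    A group qualifies iff it has exactly one member per genome and every
    cross-genome pair of members is a flank-conserved BBH (clique).
    """
    genome_ids = [g.id for g in genomes]
    genome_of = {gene: data["genome"] for gene, data in bbh.nodes(data=True)}
    pair_graph = _syntenic_pair_graph(genomes, bbh)
    groups = []
    for comp in nx.connected_components(pair_graph):
        members = sorted(comp)
        by_genome: dict[str, list[str]] = {}
        for gene in members:
            by_genome.setdefault(genome_of[gene], []).append(gene)
        if set(by_genome) != set(genome_ids):
            continue
        if any(len(v) != 1 for v in by_genome.values()):
            continue
        if all(pair_graph.has_edge(a, b)
               for a, b in itertools.combinations(members, 2)):
            groups.append(frozenset(members))
    groups.sort(key=lambda g: sorted(g))
    return TrueCogSet(groups, genome_ids)


def pairwise_cutoffs(truecogs: TrueCogSet, bbh: nx.Graph) -> list[PairCutoff]:
    """mu - 3*sigma identity cutoff per unordered genome pair.

    The standard deviation is the population SD of that pair's trueCOG
    identities (0 for a single trueCOG).
    """
    if not truecogs.groups:
        raise SubgroupingRequired(
            "no trueCOGs found across the genome set; rearrange the genomes "
            "into smaller subgroups (partition_genomes)")
    genome_of = {gene: data["genome"] for gene, data in bbh.nodes(data=True)}
    per_pair: dict[frozenset, list[float]] = {}
    for group in truecogs.groups:
        for a, b in itertools.combinations(sorted(group), 2):
            key = frozenset((genome_of[a], genome_of[b]))
            per_pair.setdefault(key, []).append(bbh.edges[a, b]["identity"])
    out = []
    for ga, gb in itertools.combinations(sorted(truecogs.genomes), 2):
        idents = per_pair.get(frozenset((ga, gb)), [])
        if not idents:
            continue
        mean = float(np.mean(idents))
        sd = float(np.std(idents))  # population SD
        out.append(PairCutoff(ga, gb, mean, sd, len(idents)))
    return out


# ---------------------------------------------------------------------------
# COG table


def build_cog_table(hits: list[HomologyHit], cutoffs: list[PairCutoff],
                    genome_of: dict[str, str], genes: list[str] | None = None,
                    mcl_inflation: float = 2.0) -> CogTable:
    """Cluster above-cutoff gene pairs into COGs and score conservation.

    ``hits`` are directed all-vs-all hits; a gene pair is kept iff its
    identity exceeds the cutoff for its genome pair (intra-genome pairs are
    never linked directly, but paralogs end up in one COG through shared
    cross-genome partners).  Kept pairs are clustered with MCL; each gene's
    score is the number of distinct genomes represented in its COG divided by
    the total genome count, so paralogs do not inflate the score and the
    range stays within (0, 1].  ``genes`` lists all gene ids so that genes
    with no kept pair become singleton COGs.
    """
    cutoff_by_pair = {c.key(): c.cutoff for c in cutoffs}
    n_genomes = len({g for g in genome_of.values()})
    pair_best: dict[frozenset, float] = {}
    for h in hits:
        ga = genome_of.get(h.query_gene)
        gb = genome_of.get(h.subject_gene)
        if ga is None or gb is None or ga == gb:
            continue
        key = frozenset((h.query_gene, h.subject_gene))
        pair_best[key] = max(pair_best.get(key, 0.0), h.percent_identity)
    edges = []
    for key, identity in sorted(pair_best.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(key)
        cut = cutoff_by_pair.get(frozenset((genome_of[a], genome_of[b])))
        if cut is not None and identity > cut:
            edges.append((a, b, identity))
    all_genes = sorted(genes if genes is not None else genome_of)
    clusters = markov_cluster(edges, nodes=all_genes, inflation=mcl_inflation)
    assignments: dict[str, tuple[str, float]] = {}
    for i, cluster in enumerate(clusters):
        cog_id = f"cog_{i + 1:05d}"
        score = len({genome_of[g] for g in cluster}) / n_genomes
        for gene in cluster:
            assignments[gene] = (cog_id, score)
    return CogTable(assignments, n_genomes)


# ---------------------------------------------------------------------------
# Genome subgrouping


def _truecog_count(subset: list[str], pair_graph: nx.Graph,
                   genome_of: dict[str, str],
                   anchor_genes: dict[str, list[str]]) -> int:
    """Number of trueCOG groups within a genome subset."""
    if len(subset) < 2:
        return 0
    ref, others = subset[0], subset[1:]
    count = 0
    for gene in anchor_genes.get(ref, []):
        partners = [gene]
        ok = True
        for other in others:
            cands = [n for n in pair_graph.neighbors(gene)
                     if genome_of[n] == other]
            if len(cands) != 1:
                ok = False
                break
            partners.append(cands[0])
        if not ok:
            continue
        if all(pair_graph.has_edge(a, b)
               for a, b in itertools.combinations(partners, 2)):
            count += 1
    return count


def partition_genomes(genomes: list[GenomeRecord], bbh: nx.Graph,
                      min_truecogs: int = 10,
                      max_stalled: int = 3) -> list[list[str]]:
    """Rearrange genomes into overlapping subgroups each supporting at least
    ``min_truecogs`` trueCOGs.

    Seeding starts from the genome pair with the most trueCOGs; genomes are
    added greedily (largest remaining joint trueCOG count first) until the
    joint count would drop below the minimum.  Further subgroups are seeded
    from uncovered genomes, then from genomes linked to the fewest others,
    until the number of cross-genome links stops increasing for
    ``max_stalled`` successive iterations.  A genome sharing no trueCOGs with
    any other becomes its own subgroup, with a warning.
    """
    genome_ids = [g.id for g in genomes]
    genome_of = {gene: data["genome"] for gene, data in bbh.nodes(data=True)}
    pair_graph = _syntenic_pair_graph(genomes, bbh)
    anchor_genes: dict[str, list[str]] = {gid: [] for gid in genome_ids}
    for gene in pair_graph.nodes:
        anchor_genes[genome_of[gene]].append(gene)
    for genes_ in anchor_genes.values():
        genes_.sort()

    def joint(subset: list[str]) -> int:
        return _truecog_count(sorted(subset), pair_graph, genome_of, anchor_genes)

    pair_counts = {
        frozenset((a, b)): joint([a, b])
        for a, b in itertools.combinations(genome_ids, 2)
    }
    isolated = [g for g in genome_ids
                if all(pair_counts[frozenset((g, o))] == 0
                       for o in genome_ids if o != g)]
    for g in isolated:
        warnings.warn(f"genome {g} shares no trueCOGs with any other genome; "
                      "emitting it as its own subgroup")
    groups: list[list[str]] = [[g] for g in isolated]
    candidates = [g for g in genome_ids if g not in isolated]
    links: set[frozenset] = set()
    stalled = 0

    def grow(seed: list[str]) -> list[str]:
        current = list(seed)
        while True:
            remaining = [g for g in candidates if g not in current]
            best, best_count = None, -1
            for g in remaining:
                c = joint(current + [g])
                if c > best_count:
                    best, best_count = g, c
            if best is None or best_count < min_truecogs:
                return current
            current.append(best)

    while candidates:
        covered = {g for grp in groups for g in grp}
        uncovered = [g for g in candidates if g not in covered]
        if uncovered:
            seed_genome = uncovered[0]
        else:
            seed_genome = min(
                candidates,
                key=lambda g: (sum(1 for l in links if g in l), g))
        partners = sorted(
            (o for o in candidates if o != seed_genome),
            key=lambda o: (-pair_counts[frozenset((seed_genome, o))], o))
        if not partners or pair_counts[frozenset((seed_genome, partners[0]))] < min_truecogs:
            if seed_genome not in covered:
                groups.append([seed_genome])
            stalled += 1
            if stalled >= max_stalled:
                break
            continue
        group = grow([seed_genome, partners[0]])
        new_links = {frozenset((a, b))
                     for a, b in itertools.combinations(group, 2)}
        if new_links - links:
            links |= new_links
            stalled = 0
            groups.append(sorted(group))
        else:
            stalled += 1
        if stalled >= max_stalled:
            break
        if len(links) == len(candidates) * (len(candidates) - 1) // 2:
            break
    # every genome must belong to at least one subgroup
    covered = {g for grp in groups for g in grp}
    for g in genome_ids:
        if g not in covered:
            groups.append([g])
    return groups
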