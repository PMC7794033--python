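"""Operon-like gene cluster formation around candidate precursor genes.

Two strategies are provided.  The *simple* method extends over consecutive
same-strand genes while the intergenic gap stays within a distance cutoff
(default 750 nt, at which known BGC core sections are fully covered).  The
*island* method first groups nearly adjacent same-strand genes (gaps <= 50 nt)
into islands and then fuses neighboring islands whose mean conservation (COG
score) is similar — |mean_A - mean_B| <= 0.1 + sd_A + sd_B — allowing up to
two "outlier" genes (e.g. a well-conserved transporter inside a BGC) to be
excluded from the statistics when that enables further fusion.  The island
method trims well-conserved flanking context that the simple method would
absorb, producing slightly smaller clusters on average.

Finally, clusters that overlap or lie within 50 nt of one another on the same
strand are fused.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from rippscout.classifier import CandidatePrecursor
from rippscout.genome_io import GeneModel, GenomeRecord
from rippscout.pangenome import CogTable


def _stats(scores: list[float]) -> tuple[float, float]:
    if not scores:
        return 0.0, 0.0
    return float(np.mean(scores)), float(np.std(scores))


@dataclass
class Island:
    """Run of same-strand genes with intergenic gaps <= the island gap."""

    genes: list[GeneModel]
    mean_cog: float
    sd_cog: float

    @property
    def start(self) -> int:
        return self.genes[0].start

    @property
    def end(self) -> int:
        return self.genes[-1].end


@dataclass
class GeneCluster:
    """A candidate BGC: same-strand gene run around one or more precursors."""

    id: str
    genome_id: str
    contig_id: str
    strand: str
    genes: list[GeneModel]
    precursor_ids: list[str]
    mean_cog: float = 0.0
    sd_cog: float = 0.0
    flank_genes: list[GeneModel] = field(default_factory=list)
    category_counts: dict[str, int] = field(default_factory=dict)
    flank_category_counts: dict[str, int] = field(default_factory=dict)
    domains: set[str] = field(default_factory=set)
    outlier_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.precursor_ids:
            raise ValueError(f"cluster {self.id!r} contains no precursor")
        self.genes.sort(key=lambda g: g.start)

    @property
    def span(self) -> tuple[int, int]:
        return self.genes[0].start, self.genes[-1].end

    @property
    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    @property
    def outliers_used(self) -> int:
        return len(self.outlier_ids)


def _make_cluster(cluster_id: str, genome: GenomeRecord, genes: list[GeneModel],
                  precursor_ids: list[str], cog: CogTable,
                  outlier_ids: frozenset = frozenset()) -> GeneCluster:
    genes = sorted(genes, key=lambda g: g.start)
    scores = [cog.score_of(g.id) for g in genes if g.id not in outlier_ids]
    mean, sd = _stats(scores)
    return GeneCluster(cluster_id, genome.id, genes[0].contig_id,
                       genes[0].strand, genes, list(precursor_ids),
                       mean_cog=mean, sd_cog=sd, outlier_ids=outlier_ids)


def _same_strand_genes(genome: GenomeRecord, precursor_gene: GeneModel
                       ) -> list[GeneModel]:
    return [g for g in genome.genes_on(precursor_gene.contig_id)
            if g.strand == precursor_gene.strand]


# ---------------------------------------------------------------------------
# Simple method


def simple_method(genome: GenomeRecord, precursor: CandidatePrecursor,
                  cog: CogTable, max_gap: int = 750) -> GeneCluster:
    """Extend over consecutive same-strand genes with gaps <= ``max_gap``.

    Opposite-strand genes are never members, but their footprint naturally
    counts toward the measured gap between same-strand neighbors.
    """
    pg = precursor.gene
    strand_genes = _same_strand_genes(genome, pg)
    idx = next(i for i, g in enumerate(strand_genes) if g.id == pg.id)
    lo = idx
    while lo > 0 and strand_genes[lo].start - strand_genes[lo - 1].end <= max_gap:
        lo -= 1
    hi = idx
    while (hi < len(strand_genes) - 1
           and strand_genes[hi + 1].start - strand_genes[hi].end <= max_gap):
        hi += 1
    genes = strand_genes[lo:hi + 1]
    return _make_cluster(f"{genome.id}_{pg.id}_simple", genome, genes,
                         [pg.id], cog)


# ---------------------------------------------------------------------------
# Island method


def build_islands(genome: GenomeRecord, precursor_gene: GeneModel,
                  cog: CogTable, island_gap: int = 50) -> list[Island]:
    """Group same-strand genes on the precursor's contig into islands."""
    strand_genes = _same_strand_genes(genome, precursor_gene)
    islands: list[Island] = []
    run: list[GeneModel] = []
    for g in strand_genes:
        if run and g.start - run[-1].end > island_gap:
            islands.append(_finish_island(run, cog))
            run = []
        run.append(g)
    if run:
        islands.append(_finish_island(run, cog))
    return islands


def _finish_island(genes: list[GeneModel], cog: CogTable) -> Island:
    mean, sd = _stats([cog.score_of(g.id) for g in genes])
    return Island(list(genes), mean, sd)


def _fusable(scores_a: list[float], scores_b: list[float], margin: float) -> bool:
    mean_a, sd_a = _stats(scores_a)
    mean_b, sd_b = _stats(scores_b)
    return abs(mean_a - mean_b) <= margin + sd_a + sd_b


def _try_fuse(cluster_genes: list[GeneModel], island: Island, cog: CogTable,
              outliers: frozenset, budget: int, margin: float
              ) -> frozenset | None:
    """COG-similarity fusion test, spending outlier budget only if needed.

    Returns the (possibly enlarged) outlier set on success, ``None`` on
    failure.  Outliers may come from either side; the smallest workable
    outlier set is chosen, ties broken by genomic position.
    """
    def scores(genes: list[GeneModel], excluded: frozenset) -> list[float]:
        return [cog.score_of(g.id) for g in genes if g.id not in excluded]

    if _fusable(scores(cluster_genes, outliers), scores(island.genes, outliers),
                margin):
        return outliers
    pool = sorted(cluster_genes + island.genes, key=lambda g: g.start)
    pool_ids = [g.id for g in pool if g.id not in outliers]
    for k in range(1, budget + 1):
        for extra in itertools.combinations(pool_ids, k):
            candidate = outliers | frozenset(extra)
            a = scores(cluster_genes, candidate)
            b = scores(island.genes, candidate)
            if a and b and _fusable(a, b, margin):
                return candidate
    return None


def island_method(genome: GenomeRecord, precursor: CandidatePrecursor,
                  cog: CogTable, island_gap: int = 50, reach: int = 750,
                  margin: float = 0.1, max_outliers: int = 2) -> GeneCluster:
    """COG-aware cluster formation: fuse islands of similar conservation.

    Starting from the island containing the precursor, the nearest unfused
    same-strand island within ``reach`` nt on either side is repeatedly
    tested for fusion; sides alternate starting with the closer one.  When
    the nearest island fails the similarity test it may still be absorbed
    wholesale as outliers (genes kept as members but excluded from the
    statistics, total outlier budget ``max_outliers``) provided that doing
    so lets the island beyond it fuse — the situation of a well-conserved
    transporter sitting inside a BGC.  Otherwise a failed nearest island
    blocks its side: fusion never hops over it.
    """
    pg = precursor.gene
    islands = build_islands(genome, pg, cog, island_gap)
    seed_idx = next(i for i, isl in enumerate(islands)
                    if any(g.id == pg.id for g in isl.genes))
    genes = list(islands[seed_idx].genes)
    left = seed_idx - 1
    right = seed_idx + 1
    outliers: frozenset = frozenset()

    def gap_left() -> int | None:
        if left < 0:
            return None
        return genes[0].start - islands[left].end

    def gap_right() -> int | None:
        if right >= len(islands):
            return None
        return islands[right].start - genes[-1].end

    blocked = {"left": False, "right": False}

    def absorb(side: str, island: Island) -> tuple[frozenset, list] | None:
        """Failed nearest island: absorb it wholesale as outliers iff that
        enables fusing the island beyond it on the same side."""
        budget = max_outliers - len(outliers)
        if len(island.genes) > budget:
            return None
        tentative = outliers | frozenset(g.id for g in island.genes)
        beyond_idx = left - 1 if side == "left" else right + 1
        if not 0 <= beyond_idx < len(islands):
            return None
        beyond = islands[beyond_idx]
        if side == "left":
            gap = island.start - beyond.end
        else:
            gap = beyond.start - island.end
        if gap > reach:
            return None
        merged = sorted(genes + island.genes, key=lambda g: g.start)
        result = _try_fuse(merged, beyond, cog, tentative,
                           max_outliers - len(tentative), margin)
        if result is None:
            return None
        return result, sorted(merged + beyond.genes, key=lambda g: g.start)

    while True:
        options = []
        gl, gr = gap_left(), gap_right()
        if not blocked["left"] and gl is not None and gl <= reach:
            options.append((gl, 0, "left"))
        if not blocked["right"] and gr is not None and gr <= reach:
            options.append((gr, 1, "right"))
        if not options:
            break
        options.sort()  # closer side first; tie-break toward the right
        fused = False
        for _gap, _tie, side in options:
            island = islands[left if side == "left" else right]
            budget = max_outliers - len(outliers)
            result = _try_fuse(genes, island, cog, outliers, budget, margin)
            if result is not None:
                outliers = result
                genes = sorted(genes + island.genes, key=lambda g: g.start)
                if side == "left":
                    left -= 1
                else:
                    right += 1
                fused = True
                break
            absorbed = absorb(side, island)
            if absorbed is not None:
                outliers, genes = absorbed
                if side == "left":
                    left -= 2
                else:
                    right += 2
                fused = True
                break
            blocked[side] = True
        if not fused:
            break
    return _make_cluster(f"{genome.id}_{pg.id}_island", genome, genes,
                         [pg.id], cog, outlier_ids=outliers)


# ---------------------------------------------------------------------------
# Cluster fusion


def fuse_clusters(clusters: list[GeneCluster], cog: CogTable,
                  genome: GenomeRecord, within: int = 50) -> list[GeneCluster]:
    """Fuse clusters that overlap or lie within ``within`` nt of one another
    (same contig and strand); transitive closure via union-find."""
    if not clusters:
        return []
    parent = list(range(len(clusters)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(clusters)), 2):
        a, b = clusters[i], clusters[j]
        if a.contig_id != b.contig_id or a.strand != b.strand:
            continue
        (s1, e1), (s2, e2) = a.span, b.span
        if max(s1, s2) - min(e1, e2) <= within:
            parent[find(i)] = find(j)

    merged: dict[int, list[GeneCluster]] = {}
    for i in range(len(clusters)):
        merged.setdefault(find(i), []).append(clusters[i])
    out = []
    for group in merged.values():
        if len(group) == 1:
            out.append(group[0])
            continue
        gene_by_id = {g.id: g for c in group for g in c.genes}
        precursors = sorted({p for c in group for p in c.precursor_ids})
        outliers = frozenset().union(*(c.outlier_ids for c in group))
        cid = "+".join(sorted(c.id for c in group))
        out.append(_make_cluster(cid, genome, list(gene_by_id.values()),
                                 precursors, cog, outlier_ids=outliers))
    out.sort(key=lambda c: (c.contig_id, c.span))
    return out
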