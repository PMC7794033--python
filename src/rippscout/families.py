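"""Cluster filtering, pairwise similarity networking, and family construction.

Candidate clusters are screened with preset filters of increasing
stringency.  The *mild* preset requires a cluster-level COG score of at most
0.25, at least 3 genes of which at least 2 are biosynthetic, and a transporter
in or around the cluster.  The *strict* preset lowers the COG bound to 0.10
and additionally requires a regulator and a peptidase.  "In or around" is
interpreted as the cluster core plus its 5-gene annotation flanks.

Surviving clusters are paired when their protein-domain content is similar
(Jaccard index >= 0.5) *and* at least one precursor pair aligns with a
bitscore of >= 30; the edge weight is the average of the Jaccard index and
the identity fraction of the best-scoring precursor pair.  Markov clustering
of the resulting network yields candidate RiPP families; families with fewer
than 3 members are set aside as ungrouped, and families in which more than
half of the members overlap antiSMASH-detected non-RiPP BGCs are discarded
as likely known non-RiPP pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from rippscout.align import align_pair, make_protein_aligner
from rippscout.clusters import GeneCluster
from rippscout.mcl import markov_cluster

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    max_mean_cog: float
    min_genes: int
    min_biosynthetic: int
    require_transporter: bool
    require_regulator: bool
    require_peptidase: bool
    search_scope: str = "cluster_plus_flanks"  # or "cluster_only"

    def __post_init__(self) -> None:
        if self.search_scope not in ("cluster_only", "cluster_plus_flanks"):
            raise ValueError(f"bad search_scope {self.search_scope!r}")


MILD = FilterSpec(0.25, 3, 2, require_transporter=True, require_regulator=False,
                  require_peptidase=False)
STRICT = FilterSpec(0.10, 3, 2, require_transporter=True, require_regulator=True,
                    require_peptidase=True)


@dataclass(frozen=True)
class CriterionReport:
    name: str
    value: float
    threshold: float
    passed: bool


@dataclass(frozen=True)
class FilterReport:
    passed: bool
    criteria: tuple[CriterionReport, ...]


def apply_filter(cluster: GeneCluster, spec: FilterSpec) -> FilterReport:
    """Evaluate a cluster against a filter, reporting every criterion.

    Gene and biosynthetic counts use core genes only; the presence
    requirements for transporter/regulator/peptidase use core plus flanks
    when the scope is ``cluster_plus_flanks``.
    """
    def scoped(category: str) -> int:
        n = cluster.category_counts.get(category, 0)
        if spec.search_scope == "cluster_plus_flanks":
            n += cluster.flank_category_counts.get(category, 0)
        return n

    criteria = [
        CriterionReport("mean_cog", cluster.mean_cog, spec.max_mean_cog,
                        cluster.mean_cog <= spec.max_mean_cog),
        CriterionReport("n_genes", len(cluster.genes), spec.min_genes,
                        len(cluster.genes) >= spec.min_genes),
        CriterionReport("n_biosynthetic",
                        cluster.category_counts.get("biosynthetic", 0),
                        spec.min_biosynthetic,
                        cluster.category_counts.get("biosynthetic", 0)
                        >= spec.min_biosynthetic),
    ]
    for category, required in (("transporter", spec.require_transporter),
                               ("regulator", spec.require_regulator),
                               ("peptidase", spec.require_peptidase)):
        if required:
            n = scoped(category)
            criteria.append(CriterionReport(f"n_{category}", n, 1, n >= 1))
    return FilterReport(all(c.passed for c in criteria), tuple(criteria))


# ---------------------------------------------------------------------------
# Pairing and families


@dataclass(frozen=True)
class ClusterPairEdge:
    cluster_a: str
    cluster_b: str
    jaccard: float
    precursor_identity: float  # 0-1 fraction

    @property
    def distance(self) -> float:
        """Average of domain Jaccard and precursor identity fraction."""
        return (self.jaccard + self.precursor_identity) / 2.0


def _precursor_seqs(cluster: GeneCluster) -> list[str]:
    by_id = {g.id: g for g in cluster.genes}
    return [by_id[pid].product_seq for pid in cluster.precursor_ids
            if pid in by_id]


def pair_clusters(a: GeneCluster, b: GeneCluster, aligner=None,
                  min_jaccard: float = 0.5, min_bitscore: float = 30.0
                  ) -> ClusterPairEdge | None:
    """Link two clusters when domain content and a precursor both match.

    Returns ``None`` unless the domain Jaccard index reaches ``min_jaccard``
    and the best precursor-pair alignment reaches ``min_bitscore`` bits.  The
    edge's precursor identity is the identity fraction (over aligned columns)
    of the best-bitscore precursor pair.
    """
    union = a.domains | b.domains
    if not union:
        return None
    jaccard = len(a.domains & b.domains) / len(union)
    if jaccard < min_jaccard:
        return None
    aligner = aligner or make_protein_aligner()
    best_bits, best_ident = 0.0, 0.0
    for pa in _precursor_seqs(a):
        for pb in _precursor_seqs(b):
            pident, bits, _cov = align_pair(pa, pb, aligner)
            if bits > best_bits:
                best_bits, best_ident = bits, pident / 100.0
    if best_bits < min_bitscore:
        return None
    return ClusterPairEdge(a.id, b.id, jaccard, best_ident)


@dataclass
class ClusterFamily:
    members: list[str]
    antismash_overlap_fraction: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def build_families(edges: list[ClusterPairEdge], min_size: int = 3,
                   mcl_inflation: float = 2.0
                   ) -> tuple[list[ClusterFamily], list[str]]:
    """Markov-cluster the pair network into families.

    Communities smaller than ``min_size`` go to the ungrouped list.
    """
    triples = [(e.cluster_a, e.cluster_b, max(e.distance, 1e-9)) for e in edges]
    communities = markov_cluster(triples, inflation=mcl_inflation)
    families, ungrouped = [], []
    for community in communities:
        members = sorted(community)
        if len(members) >= min_size:
            families.append(ClusterFamily(members))
        else:
            ungrouped.extend(members)
    return families, sorted(ungrouped)


# ---------------------------------------------------------------------------
# antiSMASH overlap


#: antiSMASH product classes counted as RiPP; everything else is "non-RiPP".
RIPP_CLASSES = {
    "ripp", "lanthipeptide", "lantipeptide", "lassopeptide", "thiopeptide",
    "sactipeptide", "ranthipeptide", "lap", "linaridin", "cyanobactin",
    "glycocin", "bottromycin", "microcin", "bacteriocin", "proteusin",
    "microviridin", "head_to_tail", "epipeptide", "guanidinotides",
    "fungal-ripp", "thioamitides", "lipolanthine", "ripp-like",
}


def is_ripp_class(product_class: str) -> bool:
    return product_class.strip().lower() in RIPP_CLASSES


def read_regions_tsv(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read antiSMASH-style region coordinates: contig, start, end, class."""
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        contig, start, end, product_class = line.rstrip("\n").split("\t")[:4]
        regions.append((contig, int(start), int(end), product_class))
    return regions


def antismash_overlap(clusters: list[GeneCluster],
                      families: list[ClusterFamily],
                      regions: list[tuple[str, int, int, str]] | None
                      ) -> tuple[dict[str, str], list[ClusterFamily],
                                 list[ClusterFamily]]:
    """Flag cluster overlap with antiSMASH regions and apply the family
    discard rule.

    A cluster overlaps a region when their spans share at least 1 bp on the
    same contig.  A family is discarded iff strictly more than half of its
    members overlap *non-RiPP* regions.  With ``regions=None`` the stage is
    skipped: all flags are "unknown" and every family is retained.

    Returns ``(per-cluster flags, retained families, discarded families)``;
    flags are "ripp", "non_ripp", "none", or "unknown".
    """
    if regions is None:
        logger.warning("no antiSMASH regions supplied; overlap stage skipped")
        flags = {c.id: "unknown" for c in clusters}
        for fam in families:
            fam.antismash_overlap_fraction = None
        return flags, list(families), []
    flags: dict[str, str] = {}
    for c in clusters:
        start, end = c.span
        flag = "none"
        for contig, rs, re_, product_class in regions:
            if contig != c.contig_id or min(end, re_) <= max(start, rs):
                continue
            if is_ripp_class(product_class):
                if flag == "none":
                    flag = "ripp"
            else:
                flag = "non_ripp"
        flags[c.id] = flag
    retained, discarded = [], []
    for fam in families:
        n_bad = sum(1 for m in fam.members if flags.get(m) == "non_ripp")
        fam.antismash_overlap_fraction = n_bad / fam.size
        (discarded if fam.antismash_overlap_fraction > 0.5 else retained).append(fam)
    return flags, retained, discarded
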