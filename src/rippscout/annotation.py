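"""Protein-domain annotation and functional categorization of cluster genes.

Each gene cluster is extended with up to five flanking genes per side (any
strand) for annotation purposes; the flanks never contribute to the cluster's
conservation statistics.  Domain hits (Pfam/TIGRFAM-style accessions) are then
matched against precompiled category lists and every protein is marked as a
regulator, peptidase, transporter, or biosynthetic enzyme — resolved in that
fixed priority order when a protein carries domains from several lists.

Domain scanning itself is pluggable: production runs parse HMMER domtblout
output from an external profile search, while tests use a toy scanner keyed
by exact sequence motifs, so no profile database download is needed to
exercise the logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from rippscout.clusters import GeneCluster
from rippscout.genome_io import GenomeRecord

logger = logging.getLogger(__name__)

#: Priority order for category resolution.
CATEGORY_ORDER = ("regulator", "peptidase", "transporter", "biosynthetic")

DEFAULT_MAX_EVALUE = 1e-5


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain_accession: str
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class CategoryLists:
    """Domain accession sets per functional category.

    Sets may overlap; :data:`CATEGORY_ORDER` resolves conflicts.
    """

    regulator: set[str] = field(default_factory=set)
    peptidase: set[str] = field(default_factory=set)
    transporter: set[str] = field(default_factory=set)
    biosynthetic: set[str] = field(default_factory=set)

    def category_sets(self) -> list[tuple[str, set[str]]]:
        return [(name, getattr(self, name)) for name in CATEGORY_ORDER]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CategoryLists":
        """Read a two-column (accession, category) TSV."""
        lists = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            accession, category = line.rstrip("\n").split("\t")[:2]
            if category not in CATEGORY_ORDER:
                raise ValueError(f"unknown category {category!r} in {path}")
            getattr(lists, category).add(accession)
        return lists

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, accs in self.category_sets():
                for acc in sorted(accs):
                    fh.write(f"{acc}\t{name}\n")


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse HMMER3 ``--domtblout`` output (hmmsearch layout: target =
    protein, query = profile).  Uses the per-target full-sequence E-value and
    score."""
    hits = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split()
        if len(cols) < 13:
            raise ValueError(f"{path}: short domtblout line: {line.strip()!r}")
        protein_id = cols[0]
        profile_acc = cols[4] if cols[4] != "-" else cols[3]
        evalue = float(cols[6])
        score = float(cols[7])
        key = (protein_id, profile_acc)
        if key in seen:
            continue
        seen.add(key)
        hits.append(DomainHit(protein_id, profile_acc, score, evalue))
    return hits


class MotifDomainScanner:
    """Toy domain scanner: assigns an accession when a protein contains an
    exact amino-acid motif.  Stands in for an external HMMER profile search
    in tests and synthetic benchmarks."""

    def __init__(self, motif_table: dict[str, str]):
        #: motif substring -> domain accession
        self.motif_table = dict(motif_table)

    def scan(self, proteins: dict[str, str]) -> list[DomainHit]:
        hits = []
        for pid, seq in proteins.items():
            for motif, accession in sorted(self.motif_table.items()):
                if motif in seq:
                    hits.append(DomainHit(pid, accession, 100.0, 1e-30))
        return hits


# ---------------------------------------------------------------------------
# Operations


def extend_flanks(cluster: GeneCluster, genome: GenomeRecord,
                  n: int = 5) -> GeneCluster:
    """Fill ``cluster.flank_genes`` with up to ``n`` genes per side.

    Flanks are taken in contig order regardless of strand, truncated at
    contig edges, and never include cluster members.
    """
    contig_genes = genome.genes_on(cluster.contig_id)
    member_ids = set(cluster.gene_ids)
    positions = [i for i, g in enumerate(contig_genes) if g.id in member_ids]
    lo, hi = min(positions), max(positions)
    left = [g for g in contig_genes[max(0, lo - n):lo] if g.id not in member_ids]
    right = [g for g in contig_genes[hi + 1:hi + 1 + n] if g.id not in member_ids]
    cluster.flank_genes = left + right
    return cluster


def categorize_proteins(hits: list[DomainHit], lists: CategoryLists,
                        max_evalue: float = DEFAULT_MAX_EVALUE
                        ) -> dict[str, str | None]:
    """Assign each protein its first matching category in priority order.

    Hits above the E-value threshold are ignored; accessions on no list are
    logged at debug level and skipped.  Proteins with no listed domain map to
    ``None``.
    """
    known = {acc for _name, accs in lists.category_sets() for acc in accs}
    domains_by_protein: dict[str, set[str]] = {}
    for h in hits:
        if h.evalue > max_evalue:
            continue
        if h.domain_accession not in known:
            logger.debug("unlisted domain accession %s on %s",
                         h.domain_accession, h.protein_id)
            continue
        domains_by_protein.setdefault(h.protein_id, set()).add(h.domain_accession)
    out: dict[str, str | None] = {}
    for protein, accs in domains_by_protein.items():
        out[protein] = next(
            (name for name, listed in lists.category_sets() if accs & listed),
            None)
    return out


def domains_by_protein(hits: list[DomainHit],
                       max_evalue: float = DEFAULT_MAX_EVALUE
                       ) -> dict[str, set[str]]:
    """All domain accessions per protein, E-value filtered."""
    out: dict[str, set[str]] = {}
    for h in hits:
        if h.evalue <= max_evalue:
            out.setdefault(h.protein_id, set()).add(h.domain_accession)
    return out


def annotate_cluster(cluster: GeneCluster, hits: list[DomainHit],
                     lists: CategoryLists,
                     max_evalue: float = DEFAULT_MAX_EVALUE) -> GeneCluster:
    """Fill a cluster's category counts and domain set from domain hits.

    ``category_counts`` covers core genes only; ``flank_category_counts``
    covers the extended flanks; ``domains`` is the union of core-gene domain
    accessions (the set used for family-level Jaccard comparison).
    """
    categories = categorize_proteins(hits, lists, max_evalue)
    per_protein = domains_by_protein(hits, max_evalue)
    core_ids = set(cluster.gene_ids)
    flank_ids = {g.id for g in cluster.flank_genes}
    counts = {name: 0 for name in CATEGORY_ORDER}
    flank_counts = {name: 0 for name in CATEGORY_ORDER}
    for pid, cat in categories.items():
        if cat is None:
            continue
        if pid in core_ids:
            counts[cat] += 1
        elif pid in flank_ids:
            flank_counts[cat] += 1
    cluster.category_counts = counts
    cluster.flank_category_counts = flank_counts
    cluster.domains = set().union(
        *(per_protein.get(gid, set()) for gid in core_ids)) if core_ids else set()
    return cluster
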