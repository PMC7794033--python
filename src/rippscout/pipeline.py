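"""End-to-end pipeline orchestration.

Stages run in a fixed order — genome parsing and intergenic ORF calling,
precursor scoring, pan-genome COG scoring, cluster formation, annotation,
filtering, family construction — with every intermediate written as TSV to
the output directory, a JSON run report echoing the configuration and seed,
and a minimal single-page HTML summary.  The pan-genome stage, which
dominates runtime, is cached on disk keyed by a content hash of its inputs
and parameters, so reruns with an unchanged genome set resume from the cached
COG table.  Rerunning with the same configuration and seed reproduces
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib

from rippscout import annotation as ann
from rippscout import families as fam
from rippscout.align import SmithWatermanEngine
from rippscout.classifier import (CandidatePrecursor, ClassifierEnsemble,
                                  TrainingSet, deduplicate_hits, score_peptides,
                                  train_ensemble)
from rippscout.clusters import (GeneCluster, fuse_clusters, island_method,
                                simple_method)
from rippscout.fixtures import TOY_CATEGORY_TABLE, TOY_MOTIF_TABLE
from rippscout.genome_io import GenomeRecord, find_intergenic_orfs, read_genome
from rippscout.pangenome import (CogTable, build_bbh_graph, build_cog_table,
                                 find_truecogs, pairwise_cutoffs,
                                 partition_genomes)

logger = logging.getLogger(__name__)

STAGES = ("scan", "cog", "cluster", "annotate", "filter", "families")


@dataclass
class RunConfig:
    genome_paths: list[str] = field(default_factory=list)
    model_path: str | None = None
    training_data_path: str | None = None
    svm_cutoff: float = 0.9
    max_precursor_len: int = 100
    min_truecogs: int = 10
    bbh_min_identity: float = 60.0
    cluster_method: str = "island"  # or "simple"
    cluster_max_gap: int = 750
    island_gap: int = 50
    island_margin: float = 0.1
    island_max_outliers: int = 2
    fuse_within: int = 50
    filter_preset: str = "mild"  # none / mild / strict
    family_min_jaccard: float = 0.5
    family_min_bitscore: float = 30.0
    family_min_size: int = 3
    mcl_inflation: float = 2.0
    domain_hits_path: str | None = None
    category_lists_path: str | None = None
    antismash_regions_path: str | None = None
    seed: int = 0
    outdir: str = "rippscout_out"


@dataclass
class RunReport:
    config: dict
    seed: int
    counts: dict[str, int] = field(default_factory=dict)
    version: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "seed": self.seed, "counts": self.counts,
             "version": self.version}, indent=2, sort_keys=True) + "\n")


@dataclass
class PipelineResult:
    report: RunReport
    genomes: list[GenomeRecord]
    hits: list[CandidatePrecursor]
    cog: CogTable | None = None
    clusters: list[GeneCluster] = field(default_factory=list)
    passing: list[GeneCluster] = field(default_factory=list)
    families: list[fam.ClusterFamily] = field(default_factory=list)
    ungrouped: list[str] = field(default_factory=list)
    discarded_families: list[fam.ClusterFamily] = field(default_factory=list)


def _content_hash(*chunks: str) -> str:
    h = hashlib.sha256()
    for c in chunks:
        h.update(c.encode())
        h.update(b"\x00")
    return h.hexdigest()[:16]


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def compute_cog_table(genomes: list[GenomeRecord], engine=None,
                      min_identity: float = 60.0, min_truecogs: int = 10,
                      mcl_inflation: float = 2.0) -> CogTable:
    """BBH graph -> trueCOGs -> per-pair cutoffs -> MCL COGs with scores.

    When the full genome set supports fewer than ``min_truecogs`` trueCOGs,
    the genomes are partitioned into overlapping subgroups and each gene is
    scored within the largest subgroup containing its genome.
    """
    engine = engine or SmithWatermanEngine()
    from rippscout.align import PrecomputedHitsEngine
    from rippscout.fixtures import proteomes_of

    proteomes = proteomes_of(genomes)
    all_hits = []
    import itertools as _it
    for ga, gb in _it.permutations(sorted(proteomes), 2):
        all_hits.extend(engine.search(proteomes[ga], proteomes[gb]))
    # reuse the all-vs-all hits for BBH detection instead of re-aligning
    engine = PrecomputedHitsEngine(all_hits)
    bbh = build_bbh_graph(proteomes, engine, min_identity)
    genome_of = {gene: data["genome"] for gene, data in bbh.nodes(data=True)}
    truecogs = find_truecogs(genomes, bbh)
    if len(truecogs) >= min_truecogs:
        cutoffs = pairwise_cutoffs(truecogs, bbh)
        all_genes = [g for prots in proteomes.values() for g in prots]
        return build_cog_table(all_hits, cutoffs, genome_of, all_genes,
                               mcl_inflation)
    logger.info("only %d trueCOGs across full set; subgrouping", len(truecogs))
    groups = partition_genomes(genomes, bbh, min_truecogs)
    groups.sort(key=len, reverse=True)
    by_id = {g.id: g for g in genomes}
    merged: dict[str, tuple[str, float]] = {}
    n_total = len(genomes)
    for group in groups:
        sub = [by_id[g] for g in group]
        if len(sub) < 2:
            continue
        sub_prot = {g: proteomes[g] for g in group}
        sub_bbh = build_bbh_graph(sub_prot, engine, min_identity)
        sub_tc = find_truecogs(sub, sub_bbh)
        if not sub_tc.groups:
            continue
        cutoffs = pairwise_cutoffs(sub_tc, sub_bbh)
        sub_genome_of = {gene: d["genome"] for gene, d in sub_bbh.nodes(data=True)}
        sub_hits = [h for h in all_hits
                    if h.query_gene in sub_genome_of
                    and h.subject_gene in sub_genome_of]
        sub_genes = [g for prots in sub_prot.values() for g in prots]
        table = build_cog_table(sub_hits, cutoffs, sub_genome_of, sub_genes,
                                mcl_inflation)
        for gene, entry in table.assignments.items():
            if gene not in merged:  # largest subgroup wins
                merged[gene] = entry
    return CogTable(merged, n_total)


def run_pipeline(config: RunConfig, genomes: list[GenomeRecord] | None = None,
                 ensemble: ClassifierEnsemble | None = None,
                 training: TrainingSet | None = None,
                 engine=None, stop_after: str = "families") -> PipelineResult:
    """Execute the pipeline; see module docstring for the stage order.

    ``genomes``/``ensemble``/``training``/``engine`` allow in-memory inputs
    (as the CLI and tests use); otherwise they are loaded from the paths in
    ``config``.  ``stop_after`` truncates the run after the named stage.
    """
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(asdict(config), config.seed)
    result = PipelineResult(report, genomes or [], [])

    def stage_failed(stage: str, exc: Exception):
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- load genomes
    if genomes is None:
        genomes = [read_genome(p) for p in config.genome_paths]
        result.genomes = genomes
    if not genomes:
        raise ValueError("no genomes supplied")

    # --- scan: candidate genes + SVM scoring + dedup
    try:
        candidates = []
        for genome in genomes:
            small = [g for g in genome.genes
                     if len(g.product_seq) < config.max_precursor_len]
            small += find_intergenic_orfs(genome,
                                          max_len_aa=config.max_precursor_len)
            candidates.append((genome, small))
        report.counts["candidates_scanned"] = sum(len(s) for _g, s in candidates)
        if ensemble is None:
            if config.model_path:
                ensemble = ClassifierEnsemble.load(config.model_path)
            else:
                if training is None:
                    if not config.training_data_path:
                        raise ValueError(
                            "no model, training set, or training data path")
                    training = TrainingSet.from_fasta(config.training_data_path)
                ensemble = train_ensemble(training, config.seed)
        hits: list[CandidatePrecursor] = []
        for genome, small in candidates:
            scored = score_peptides(ensemble, small, cutoff=config.svm_cutoff)
            hits.extend(h for h in scored if h.passed)
        report.counts["passing_svm"] = len(hits)
        hits = deduplicate_hits(hits)
        report.counts["after_dedup"] = len(hits)
        result.hits = hits
        _write_tsv(outdir / "precursors.tsv",
                   ["gene", "contig", "start", "end", "strand", "source",
                    "score", "passed"],
                   [[h.gene.id, h.gene.contig_id, h.gene.start, h.gene.end,
                     h.gene.strand, h.gene.source, f"{h.score:.4f}",
                     h.passed] for h in hits])
    except Exception as exc:  # noqa: BLE001
        stage_failed("scan", exc)
    if stop_after == "scan":
        report.to_json(outdir / "report.json")
        return result

    # --- cog (cached on content hash)
    try:
        from rippscout.fixtures import proteomes_of

        proteomes = proteomes_of(genomes)
        key = _content_hash(
            json.dumps({g: sorted(p.items()) for g, p in proteomes.items()},
                       sort_keys=True),
            f"{config.bbh_min_identity}|{config.min_truecogs}|{config.mcl_inflation}")
        cache = outdir / f"cache_cog_{key}.joblib"
        if cache.exists():
            cog = joblib.load(cache)
            logger.info("loaded cached COG table %s", cache.name)
        else:
            cog = compute_cog_table(genomes, engine, config.bbh_min_identity,
                                    config.min_truecogs, config.mcl_inflation)
            joblib.dump(cog, cache)
        result.cog = cog
        cog.to_tsv(outdir / "cog_scores.tsv")
        report.counts["cogs"] = len({c for c, _s in cog.assignments.values()})
    except Exception as exc:  # noqa: BLE001
        stage_failed("cog", exc)
    if stop_after == "cog":
        report.to_json(outdir / "report.json")
        return result

    # --- cluster formation
    try:
        clusters: list[GeneCluster] = []
        cog = result.cog
        for genome in genomes:
            contig_ids = {c.id for c in genome.contigs}
            mine = [h for h in result.hits if h.gene.contig_id in contig_ids]
            formed = []
            genome_with_orfs = _with_intergenic(genome, mine)
            for h in mine:
                if config.cluster_method == "simple":
                    formed.append(simple_method(genome_with_orfs, h, cog,
                                                config.cluster_max_gap))
                else:
                    formed.append(island_method(
                        genome_with_orfs, h, cog, config.island_gap,
                        config.cluster_max_gap, config.island_margin,
                        config.island_max_outliers))
            clusters.extend(fuse_clusters(formed, cog, genome_with_orfs,
                                          config.fuse_within))
        result.clusters = clusters
        report.counts["clusters_formed"] = len(clusters)
    except Exception as exc:  # noqa: BLE001
        stage_failed("cluster", exc)
    if stop_after == "cluster":
        _write_clusters(outdir, result)
        report.to_json(outdir / "report.json")
        return result

    # --- annotation
    try:
        lists = (ann.CategoryLists.from_tsv(config.category_lists_path)
                 if config.category_lists_path else _toy_category_lists())
        if config.domain_hits_path:
            domain_hits = ann.read_domtblout(config.domain_hits_path)
        else:
            scanner = ann.MotifDomainScanner(TOY_MOTIF_TABLE)
            all_prots = {g.id: g.product_seq for genome in genomes
                         for g in genome.genes}
            for c in result.clusters:
                for g in c.genes:
                    all_prots.setdefault(g.id, g.product_seq)
            domain_hits = scanner.scan(all_prots)
        for c in result.clusters:
            genome = next(g for g in genomes
                          if any(ct.id == c.contig_id for ct in g.contigs))
            ann.extend_flanks(c, _with_intergenic(genome, result.hits))
            ann.annotate_cluster(c, domain_hits, lists)
    except Exception as exc:  # noqa: BLE001
        stage_failed("annotate", exc)
    if stop_after == "annotate":
        _write_clusters(outdir, result)
        report.to_json(outdir / "report.json")
        return result

    # --- filter
    try:
        if config.filter_preset == "none":
            passing = list(result.clusters)
        else:
            spec = {"mild": fam.MILD, "strict": fam.STRICT}[config.filter_preset]
            passing = [c for c in result.clusters
                       if apply_filter_cached(c, spec).passed]
        result.passing = passing
        report.counts["passing_filter"] = len(passing)
    except Exception as exc:  # noqa: BLE001
        stage_failed("filter", exc)
    if stop_after == "filter":
        _write_clusters(outdir, result)
        report.to_json(outdir / "report.json")
        return result

    # --- families
    try:
        edges = []
        import itertools as _it
        for a, b in _it.combinations(result.passing, 2):
            edge = fam.pair_clusters(a, b,
                                     min_jaccard=config.family_min_jaccard,
                                     min_bitscore=config.family_min_bitscore)
            if edge:
                edges.append(edge)
        families, ungrouped = fam.build_families(
            edges, config.family_min_size, config.mcl_inflation)
        regions = (fam.read_regions_tsv(config.antismash_regions_path)
                   if config.antismash_regions_path else None)
        _flags, retained, discarded = fam.antismash_overlap(
            result.passing, families, regions)
        result.families = retained
        result.discarded_families = discarded
        result.ungrouped = ungrouped
        report.counts["families"] = len(retained)
        report.counts["families_discarded"] = len(discarded)
        _write_tsv(outdir / "families.tsv", ["family", "cluster"],
                   [[f"family_{i + 1:04d}", m]
                    for i, f in enumerate(retained) for m in f.members])
    except Exception as exc:  # noqa: BLE001
        stage_failed("families", exc)

    _write_clusters(outdir, result)
    report.to_json(outdir / "report.json")
    _write_html(outdir, report)
    return result


def apply_filter_cached(cluster: GeneCluster, spec) -> fam.FilterReport:
    return fam.apply_filter(cluster, spec)


def _with_intergenic(genome: GenomeRecord,
                     hits: list[CandidatePrecursor]) -> GenomeRecord:
    """Genome view whose gene list includes any intergenic-ORF hits, so that
    cluster formation can seed on them."""
    contig_ids = {c.id for c in genome.contigs}
    extra = [h.gene for h in hits
             if h.gene.source == "intergenic_orf" and h.gene.contig_id in contig_ids]
    if not extra:
        return genome
    known = {g.id for g in genome.genes}
    merged = list(genome.genes) + [g for g in extra if g.id not in known]
    return GenomeRecord(genome.id, genome.contigs, merged)


def _toy_category_lists() -> ann.CategoryLists:
    lists = ann.CategoryLists()
    for acc, cat in TOY_CATEGORY_TABLE.items():
        getattr(lists, cat).add(acc)
    return lists


def _write_clusters(outdir: Path, result: PipelineResult) -> None:
    rows = []
    passing_ids = {c.id for c in result.passing}
    for c in result.clusters:
        rows.append([c.id, c.genome_id, c.contig_id, c.strand, c.span[0],
                     c.span[1], len(c.genes), ";".join(c.precursor_ids),
                     f"{c.mean_cog:.4f}", f"{c.sd_cog:.4f}",
                     c.category_counts.get("biosynthetic", 0),
                     c.category_counts.get("transporter", 0)
                     + c.flank_category_counts.get("transporter", 0),
                     c.category_counts.get("regulator", 0)
                     + c.flank_category_counts.get("regulator", 0),
                     c.category_counts.get("peptidase", 0)
                     + c.flank_category_counts.get("peptidase", 0),
                     c.id in passing_ids])
    _write_tsv(outdir / "clusters.tsv",
               ["cluster", "genome", "contig", "strand", "start", "end",
                "n_genes", "precursors", "mean_cog", "sd_cog", "biosynthetic",
                "transporter", "regulator", "peptidase", "passed_filter"],
               rows)
    with open(outdir / "clusters.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for c in result.clusters:
            fh.write(f"{c.contig_id}\trippscout\tregion\t{c.span[0] + 1}\t"
                     f"{c.span[1]}\t.\t{c.strand}\t.\tID={c.id};"
                     f"precursors={','.join(c.precursor_ids)}\n")


def _write_html(outdir: Path, report: RunReport) -> None:
    rows = "".join(f"<tr><td>{k}</td><td>{v}</td></tr>"
                   for k, v in report.counts.items())
    html = ("<!DOCTYPE html><html><head><title>rippscout run</title></head>"
            "<body><h1>rippscout run summary</h1>"
            f"<p>seed: {report.seed}</p>"
            f"<table border='1'><tr><th>stage</th><th>count</th></tr>{rows}"
            "</table></body></html>\n")
    (outdir / "summary.html").write_text(html)
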