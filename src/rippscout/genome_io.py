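"""Genome parsing, intergenic ORF calling, and codon-position GC diagnostics.

Genomes enter the pipeline either as annotated GenBank flat files or as a
nucleotide FASTA accompanied by a GFF3 file with CDS features.  Internally all
coordinates are 0-based half-open; GenBank's 1-based inclusive convention is
converted at the boundary.  Circular contigs are treated as linear: draft
assemblies dominate the intended use case and origin-spanning genes are rare
enough to ignore.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

#: NCBI translation table used throughout (bacterial/archaeal).
TRANSLATION_TABLE = 11

#: Start codons permitted for intergenic ORF calling (table 11 bacterial starts
#: ATG/GTG/TTG; the rarer ATT/CTG initiators are not considered).
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

NUCLEOTIDES = set("ACGTN")


class GenomeParseError(ValueError):
    """Raised when an input genome file cannot be interpreted."""


@dataclass(frozen=True)
class Contig:
    """A single DNA sequence (chromosome, plasmid, or assembly contig)."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id!r} has empty sequence")
        bad = set(self.sequence.upper()) - NUCLEOTIDES
        if bad:
            raise ValueError(
                f"contig {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene on a contig.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand regardless of the coding strand.  ``product_seq`` is the
    amino-acid sequence without the stop.  ``source`` distinguishes genes taken
    from the input annotation from short ORFs called in intergenic space.
    ``partial`` marks genes truncated at a contig edge; these are kept but
    excluded from synteny-anchored ortholog detection.
    """

    id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product_seq: str
    source: str = "annotation"
    partial: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.id!r}: bad span [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id!r}: strand must be '+' or '-'")
        if self.source not in ("annotation", "intergenic_orf"):
            raise ValueError(f"gene {self.id!r}: unknown source {self.source!r}")
        if len(self.product_seq) < 1:
            raise ValueError(f"gene {self.id!r}: empty product")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """One genome: contigs plus per-contig gene models sorted by start."""

    id: str
    contigs: list[Contig]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        contig_ids = {c.id for c in self.contigs}
        for g in self.genes:
            if g.contig_id not in contig_ids:
                raise ValueError(f"gene {g.id!r} on unknown contig {g.contig_id!r}")
            if g.end > len(self.contig(g.contig_id)):
                raise ValueError(f"gene {g.id!r} extends beyond contig")
        self.genes.sort(key=lambda g: (g.contig_id, g.start, g.end))

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)

    def genes_on(self, contig_id: str) -> list[GeneModel]:
        return [g for g in self.genes if g.contig_id == contig_id]

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def coding_sequence(self, gene: GeneModel) -> str:
        """Strand-aware nucleotide sequence of a gene (5'->3')."""
        seq = self.contig(gene.contig_id).sequence[gene.start:gene.end]
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq.upper()


# ---------------------------------------------------------------------------
# Reading and writing


def read_genome(path: str | Path, gff: str | Path | None = None,
                genome_id: str | None = None) -> GenomeRecord:
    """Parse a genome from GenBank, or from FASTA plus a GFF3 annotation.

    Parameters
    ----------
    path:
        GenBank flat file (annotation embedded) or nucleotide FASTA.
    gff:
        GFF3 file with CDS features; required when ``path`` is FASTA.
    genome_id:
        Identifier for the returned record; defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    gid = genome_id or path.stem
    with path.open() as fh:
        text_head = fh.read(200)
    if text_head.startswith(">"):
        if gff is None:
            raise GenomeParseError(
                f"{path} is a FASTA file without annotation; supply a GFF3 file "
                "with CDS features or pre-annotate with an external gene caller "
                "(e.g. prodigal)"
            )
        return _read_fasta_gff(path, Path(gff), gid)
    return _read_genbank(path, gid)


def _read_genbank(path: Path, gid: str) -> GenomeRecord:
    contigs: list[Contig] = []
    genes: list[GeneModel] = []
    try:
        with path.open() as fh:
            records = list(SeqIO.parse(fh, "genbank"))
    except Exception as exc:  # malformed flat file
        raise GenomeParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise GenomeParseError(f"no records found in {path}")
    for rec in records:
        circular = rec.annotations.get("topology", "linear") == "circular"
        contigs.append(Contig(rec.id, str(rec.seq).upper(), circular=circular))
        n = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n += 1
            genes.append(_gene_from_feature(feat, rec, n))
    return GenomeRecord(gid, contigs, genes)


def _gene_from_feature(feat: SeqFeature, rec: SeqRecord, index: int) -> GeneModel:
    start = int(feat.location.start)
    end = int(feat.location.end)
    strand = "-" if feat.location.strand == -1 else "+"
    quals = feat.qualifiers
    gene_id = (quals.get("locus_tag") or quals.get("protein_id")
               or quals.get("gene") or [f"{rec.id}_cds{index}"])[0]
    partial = "<" in str(feat.location) or ">" in str(feat.location)
    if "translation" in quals:
        product = quals["translation"][0]
    else:
        try:
            product = str(feat.extract(rec.seq).translate(
                table=TRANSLATION_TABLE, cds=not partial))
        except Exception as exc:
            raise GenomeParseError(
                f"record {rec.id}, CDS {gene_id}: cannot translate ({exc})"
            ) from exc
    product = product.rstrip("*")
    return GeneModel(gene_id, rec.id, start, end, strand, product,
                     source="annotation", partial=partial)


def _read_fasta_gff(fasta: Path, gff: Path, gid: str) -> GenomeRecord:
    with fasta.open() as fh:
        contigs = [Contig(rec.id, str(rec.seq).upper())
                   for rec in SeqIO.parse(fh, "fasta")]
    if not contigs:
        raise GenomeParseError(f"no sequences found in {fasta}")
    by_id = {c.id: c for c in contigs}
    genes: list[GeneModel] = []
    n = 0
    for line in gff.read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 8:
            raise GenomeParseError(f"{gff}: malformed GFF3 line: {line.strip()!r}")
        seqid, _src, ftype, start1, end1, _score, strand, _phase = cols[:8]
        if ftype != "CDS":
            continue
        if seqid not in by_id:
            raise GenomeParseError(f"{gff}: CDS on unknown sequence {seqid!r}")
        n += 1
        attrs = dict(
            kv.split("=", 1) for kv in (cols[8].split(";") if len(cols) > 8 else [])
            if "=" in kv
        )
        gene_id = attrs.get("ID") or attrs.get("locus_tag") or f"{seqid}_cds{n}"
        start = int(start1) - 1  # GFF3 is 1-based inclusive
        end = int(end1)
        partial = attrs.get("partial", "false").lower() in ("true", "1", "yes")
        nt = by_id[seqid].sequence[start:end]
        if strand == "-":
            nt = str(Seq(nt).reverse_complement())
        product = str(Seq(nt).translate(table=TRANSLATION_TABLE)).rstrip("*")
        genes.append(GeneModel(gene_id, seqid, start, end, strand, product,
                               source="annotation", partial=partial))
    return GenomeRecord(gid, contigs, genes)


def write_genbank(genome: GenomeRecord, path: str | Path) -> None:
    """Write a GenomeRecord as a GenBank flat file (round-trip safe)."""
    records = []
    for contig in genome.contigs:
        rec = SeqRecord(Seq(contig.sequence), id=contig.id, name=contig.id[:16],
                        description="")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "circular" if contig.circular else "linear"
        for g in genome.genes_on(contig.id):
            loc = SimpleLocation(g.start, g.end, strand=1 if g.strand == "+" else -1)
            feat = SeqFeature(loc, type="CDS", qualifiers={
                "locus_tag": [g.id],
                "translation": [g.product_seq],
                "transl_table": [str(TRANSLATION_TABLE)],
                "note": [f"source:{g.source}"],
            })
            rec.features.append(feat)
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


# ---------------------------------------------------------------------------
# Intergenic ORF calling


def _intergenic_intervals(genome: GenomeRecord, contig: Contig) -> list[tuple[int, int]]:
    """Complement of annotated gene spans on a contig (strand-agnostic)."""
    spans = sorted((g.start, g.end) for g in genome.genes_on(contig.id)
                   if g.source == "annotation")
    out: list[tuple[int, int]] = []
    pos = 0
    for s, e in spans:
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < len(contig):
        out.append((pos, len(contig)))
    return out


def _orfs_in_window(seq: str, max_len_aa: int, min_len_nt: int):
    """Yield (start, end, strand) ORFs wholly inside ``seq`` (0-based, half-open).

    An ORF runs from a start codon (ATG/GTG/TTG) to the first in-frame stop,
    stop codon included in the span.  Within one stop-to-stop segment only the
    first (longest) start is used.
    """
    n = len(seq)
    rc = str(Seq(seq).reverse_complement())
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            start_pos: int | None = None
            for i in range(frame, n - 2, 3):
                codon = s[i:i + 3]
                if codon in STOP_CODONS:
                    if start_pos is not None:
                        span = i + 3 - start_pos
                        n_aa = span // 3 - 1
                        if span >= min_len_nt and 1 <= n_aa < max_len_aa:
                            if strand == "+":
                                yield start_pos, i + 3, "+"
                            else:
                                yield n - (i + 3), n - start_pos, "-"
                    start_pos = None
                elif codon in START_CODONS and start_pos is None:
                    start_pos = i


def find_intergenic_orfs(genome: GenomeRecord, max_len_aa: int = 100,
                         min_len_nt: int = 30) -> list[GeneModel]:
    """Call short ORFs lying wholly within intergenic space.

    Both strands and all three frames are scanned per intergenic interval.
    Returned ORFs encode fewer than ``max_len_aa`` residues and span at least
    ``min_len_nt`` nucleotides (stop codon included).  ORFs never overlap an
    annotated gene, so none can share a span with one.
    """
    out: list[GeneModel] = []
    for contig in genome.contigs:
        for lo, hi in _intergenic_intervals(genome, contig):
            if hi - lo < min_len_nt:
                continue
            window = contig.sequence[lo:hi].upper()
            if "N" in window:
                continue  # ambiguous gap sequence: skip
            for s, e, strand in _orfs_in_window(window, max_len_aa, min_len_nt):
                nt = window[s:e]
                if strand == "-":
                    nt = str(Seq(nt).reverse_complement())
                aa = str(Seq(nt[:-3]).translate(table=TRANSLATION_TABLE))
                if "*" in aa:
                    continue
                out.append(GeneModel(
                    f"{contig.id}_iorf_{lo + s}_{lo + e}_{strand}",
                    contig.id, lo + s, lo + e, strand, aa,
                    source="intergenic_orf"))
    out.sort(key=lambda g: (g.contig_id, g.start, g.end, g.strand))
    return out


# ---------------------------------------------------------------------------
# Codon-position GC diagnostic


def codon_position_gc(genome: GenomeRecord, gene: GeneModel, window: int = 5,
                      step: int = 2) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moving-average GC fraction at codon positions 1, 2 and 3 along a gene.

    Real protein-coding genes in high-GC organisms show a characteristic
    separation of the three traces (third position highest); spurious ORFs do
    not, which makes this a useful diagnostic for intergenic precursor hits.

    Returns three arrays of length ``floor((n_codons - window)/step) + 1``.
    """
    nt = genome.coding_sequence(gene)
    if len(nt) % 3 != 0:
        warnings.warn(
            f"gene {gene.id}: length {len(nt)} not divisible by 3; "
            "truncating trailing remainder")
        nt = nt[: len(nt) - len(nt) % 3]
    n_codons = len(nt) // 3
    if n_codons < window:
        raise ValueError(
            f"gene {gene.id}: {n_codons} codons is shorter than window {window}")
    is_gc = np.frombuffer(nt.encode(), dtype=np.uint8)
    is_gc = np.isin(is_gc, np.frombuffer(b"GCgc", dtype=np.uint8)).astype(float)
    by_pos = is_gc.reshape(n_codons, 3)
    starts = np.arange(0, n_codons - window + 1, step)
    series = []
    for p in range(3):
        vals = by_pos[:, p]
        series.append(np.array([vals[i:i + window].mean() for i in starts]))
    return series[0], series[1], series[2]
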