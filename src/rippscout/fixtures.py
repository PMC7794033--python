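"""Seeded synthetic pan-genomes and training peptides.

Every pipeline stage is exercised on data generated here, so no genome or
profile downloads are needed.  The pan-genome generator plants three kinds of
genes with known conservation:

* *core* genes present in every genome with conserved order (so synteny-
  anchored trueCOGs exist), each genome carrying a mutated copy of a shared
  ancestor at a per-genome substitution rate drawn from a small range —
  pairwise identities land around 90-99%, keeping the per-pair mu - 3*sigma
  identity cutoffs non-degenerate;
* *accessory* genes present in a chosen subset of genomes, lightly mutated;
* a *BGC*: a same-strand run of genes with small intergenic gaps (<= 50 nt),
  containing a Ser/Thr/Cys-rich precursor and genes carrying toy domain
  motifs for each functional category, present in a chosen subset of genomes
  and flanked by core genes.

Truth tables record each gene's role and presence count, from which exact
expected COG scores follow (presence / n_genomes).

The training-peptide generator emulates the structure of RiPP precursor
training data: positives are short peptides with a neutral N-terminal leader
and a C-terminal block enriched in modifiable residues, split into classes
with distinct residue biases; negatives are half protein-like sequences
(30-175 aa, background composition) and half translations of random DNA
(30-300 nt), mirroring the two negative-set sources used for this kind of
classifier.  It does not emulate real protein families, homology between
training sequences, or genuine RiPP leader motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rippscout.classifier import TrainingSet
from rippscout.genome_io import Contig, GeneModel, GenomeRecord

_AA = "ACDEFGHIKLMNPQRSTVWY"

# Roughly uniprot-like background amino-acid frequencies.
_BG_FREQ = {
    "A": 0.083, "C": 0.014, "D": 0.055, "E": 0.067, "F": 0.039, "G": 0.071,
    "H": 0.023, "I": 0.059, "K": 0.058, "L": 0.097, "M": 0.024, "N": 0.041,
    "P": 0.047, "Q": 0.039, "R": 0.055, "S": 0.066, "T": 0.053, "V": 0.069,
    "W": 0.011, "Y": 0.029,
}

# Codons per residue, translation table 11 (stop codons excluded).
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}


def _random_protein(rng: np.random.Generator, length: int,
                    freqs: dict[str, float] | None = None) -> str:
    freqs = freqs or _BG_FREQ
    aas = list(freqs)
    p = np.array([freqs[a] for a in aas])
    p /= p.sum()
    return "".join(rng.choice(aas, size=length, p=p))


def _mutate(rng: np.random.Generator, protein: str, rate: float) -> str:
    out = []
    for aa in protein:
        if rng.random() < rate:
            choices = [a for a in _AA if a != aa]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = ["ATG"]  # start
    for aa in protein:
        opts = _CODONS[aa]
        codons.append(opts[rng.integers(len(opts))])
    codons.append("TAA")
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


# ---------------------------------------------------------------------------
# Pan-genome specification


#: Toy domain motifs planted into BGC gene products; the motif scanner in the
#: annotation module maps them to synthetic accessions.
TOY_MOTIFS = {
    "biosynthetic": ("WWHHWWHHWW", "SYNBIO001"),
    "transporter": ("KKFFKKFFKK", "SYNTRA001"),
    "regulator": ("EEYYEEYYEE", "SYNREG001"),
    "peptidase": ("DDMMDDMMDD", "SYNPEP001"),
}

#: motif -> accession table for the MotifDomainScanner.
TOY_MOTIF_TABLE = {motif: acc for motif, acc in TOY_MOTIFS.values()}

#: accession -> category table matching the toy motifs.
TOY_CATEGORY_TABLE = {acc: cat for cat, (_m, acc) in TOY_MOTIFS.items()}


@dataclass(frozen=True)
class BgcSpec:
    """A planted RiPP-like gene cluster.

    ``categories`` gives the functional role of each non-precursor gene (the
    matching toy domain motif is embedded in its product); the precursor is
    inserted in the middle of the run.  ``presence`` is the number of genomes
    carrying the cluster.
    """

    categories: tuple[str, ...] = ("biosynthetic", "biosynthetic",
                                   "transporter", "regulator", "peptidase")
    presence: int = 2
    precursor_len: int = 60
    gap: int = 30
    anchor: int = 10  # planted after this many core genes


@dataclass(frozen=True)
class PangenomeSpec:
    n_genomes: int = 5
    n_core_genes: int = 30
    core_len_range: tuple[int, int] = (60, 120)
    #: number of genomes carrying each accessory gene
    accessory_presence: tuple[int, ...] = (1, 2, 3, 4)
    bgc: BgcSpec = field(default_factory=BgcSpec)
    #: per-genome substitution rate range for core genes
    core_sub_rate: tuple[float, float] = (0.005, 0.05)
    #: substitution rate for accessory and BGC genes
    accessory_sub_rate: float = 0.005
    core_gap_range: tuple[int, int] = (80, 300)
    bgc_flank_gap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("need at least 2 genomes")
        if not 0 < self.bgc.presence <= self.n_genomes:
            raise ValueError("BGC presence outside (0, n_genomes]")
        if any(not 0 < p <= self.n_genomes for p in self.accessory_presence):
            raise ValueError("accessory presence outside (0, n_genomes]")
        lo, hi = self.core_sub_rate
        if hi >= 0.12:
            # keeps expected pairwise core identity above the mu - 3*sigma
            # cutoff regime and far above the 60% BBH floor
            raise ValueError("core substitution rate too high for stable COGs")


@dataclass
class PangenomeTruth:
    """What was planted where."""

    roles: dict[str, str]  # gene id -> core / accessory / bgc / bgc_precursor
    presence: dict[str, int]  # ancestor id -> number of genomes carrying it
    ancestor_of: dict[str, str]  # gene id -> ancestor id
    bgc_coords: dict[str, tuple[str, int, int]]  # genome id -> contig span
    bgc_genomes: list[str]
    precursor_ids: dict[str, str]  # genome id -> precursor gene id


def _precursor_protein(rng: np.random.Generator, length: int,
                       class_index: int = 9) -> str:
    """Leader-plus-core precursor peptide: neutral leader, then a C-terminal
    half enriched in modifiable residues.

    Drawn from the same class-biased composition model as the training
    positives (default class: joint Ser/Thr/Cys enrichment), so the planted
    precursor is a typical member of the positive distribution rather than a
    sample from a shifted one.
    """
    leader_len = length // 2
    leader = _random_protein(rng, leader_len)
    core = _random_protein(rng, length - leader_len,
                           _class_frequencies(class_index))
    return leader + core


def synth_pangenome(spec: PangenomeSpec) -> tuple[list[GenomeRecord], PangenomeTruth]:
    """Generate a seeded synthetic pan-genome with planted conservation.

    Deterministic per spec (including seed): the same spec yields
    byte-identical genomes.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genomes
    genome_ids = [f"g{i + 1}" for i in range(n)]
    core_rates = rng.uniform(*spec.core_sub_rate, size=n)

    # Ancestral proteins
    core_anc = {
        f"core{i:04d}": _random_protein(
            rng, int(rng.integers(*spec.core_len_range)))
        for i in range(spec.n_core_genes)
    }
    acc_anc = {}
    acc_carriers = {}
    for i, presence in enumerate(spec.accessory_presence):
        aid = f"acc{i:03d}"
        acc_anc[aid] = _random_protein(
            rng, int(rng.integers(*spec.core_len_range)))
        carriers = rng.choice(n, size=presence, replace=False)
        acc_carriers[aid] = {genome_ids[j] for j in carriers}
    bgc_anc: dict[str, str] = {}
    bgc_motif_span: dict[str, tuple[int, int]] = {}
    for i, cat in enumerate(spec.bgc.categories):
        motif, _acc = TOY_MOTIFS[cat]
        body = _random_protein(rng, int(rng.integers(80, 140)))
        mid = len(body) // 2
        aid = f"bgc{i:02d}_{cat}"
        bgc_anc[aid] = body[:mid] + motif + body[mid:]
        bgc_motif_span[aid] = (mid, mid + len(motif))
    prec_anc_id = "bgc_precursor"
    bgc_anc_order = list(bgc_anc)
    # precursor goes in the middle of the BGC run
    bgc_anc_order.insert(len(bgc_anc_order) // 2, prec_anc_id)
    bgc_anc[prec_anc_id] = _precursor_protein(rng, spec.bgc.precursor_len)
    bgc_carriers = {genome_ids[j]
                    for j in rng.choice(n, size=spec.bgc.presence, replace=False)}

    # Insertion points for accessory genes along the core backbone, kept
    # clear of the BGC anchor so the planted cluster stays flanked by core
    # genes (an accessory gene of similar conservation right next to the
    # BGC would make the planted boundary genuinely ambiguous)
    allowed_slots = [s for s in range(1, spec.n_core_genes)
                     if abs(s - spec.bgc.anchor) > 2]
    acc_slots = {aid: allowed_slots[int(rng.integers(len(allowed_slots)))]
                 for aid in acc_anc}

    genomes = []
    truth = PangenomeTruth({}, {}, {}, {}, sorted(bgc_carriers), {})
    for aid in core_anc:
        truth.presence[aid] = n
    for aid, carriers in acc_carriers.items():
        truth.presence[aid] = len(carriers)
    for aid in bgc_anc:
        truth.presence[aid] = spec.bgc.presence

    for gi, gid in enumerate(genome_ids):
        grng = np.random.default_rng((spec.seed, 1000 + gi))
        parts: list[str] = [_random_dna(grng, int(grng.integers(*spec.core_gap_range)))]
        genes: list[GeneModel] = []
        pos = len(parts[0])

        def place(ancestor_id: str, protein: str, role: str, gap_after: int):
            nonlocal pos
            dna = _back_translate(grng, protein)
            gene_id = f"{gid}|{ancestor_id}"
            genes.append(GeneModel(gene_id, f"{gid}_c1", pos, pos + len(dna),
                                   "+", protein, source="annotation"))
            truth.roles[gene_id] = role
            truth.ancestor_of[gene_id] = ancestor_id
            parts.append(dna)
            gap = _random_dna(grng, gap_after)
            parts.append(gap)
            pos += len(dna) + len(gap)

        core_ids = list(core_anc)
        for ci, aid in enumerate(core_ids):
            protein = _mutate(grng, core_anc[aid], core_rates[gi])
            gap_after = int(grng.integers(*spec.core_gap_range))
            place(aid, protein, "core", gap_after)
            for acc_id, slot in sorted(acc_slots.items()):
                if slot == ci + 1 and gid in acc_carriers[acc_id]:
                    protein = _mutate(grng, acc_anc[acc_id],
                                      spec.accessory_sub_rate)
                    place(acc_id, protein, "accessory",
                          int(grng.integers(*spec.core_gap_range)))
            if ci + 1 == spec.bgc.anchor and gid in bgc_carriers:
                # fix the gap before the BGC to the flank distance
                parts[-1] = _random_dna(grng, spec.bgc_flank_gap)
                pos = pos - gap_after + spec.bgc_flank_gap
                bgc_start = pos
                for k, aid2 in enumerate(bgc_anc_order):
                    role = ("bgc_precursor" if aid2 == prec_anc_id else "bgc")
                    protein = _mutate(grng, bgc_anc[aid2],
                                      spec.accessory_sub_rate)
                    if aid2 in bgc_motif_span:
                        # domain motifs are conserved: shield the planted
                        # motif from substitution
                        ms, me = bgc_motif_span[aid2]
                        protein = (protein[:ms] + bgc_anc[aid2][ms:me]
                                   + protein[me:])
                    last = k == len(bgc_anc_order) - 1
                    gap2 = spec.bgc_flank_gap if last else spec.bgc.gap
                    place(aid2, protein, role, gap2)
                    if role == "bgc_precursor":
                        truth.precursor_ids[gid] = genes[-1].id
                bgc_end = genes[-1].end
                truth.bgc_coords[gid] = (f"{gid}_c1", bgc_start, bgc_end)
        contig = Contig(f"{gid}_c1", "".join(parts))
        genomes.append(GenomeRecord(gid, [contig], genes))
    return genomes, truth


def proteomes_of(genomes: list[GenomeRecord]) -> dict[str, dict[str, str]]:
    """Convenience: genome id -> {gene id -> protein} for annotated genes."""
    return {g.id: {gene.id: gene.product_seq for gene in g.genes
                   if gene.source == "annotation"}
            for g in genomes}


# ---------------------------------------------------------------------------
# Training peptides


@dataclass(frozen=True)
class PeptideSetSpec:
    """Synthetic precursor training data.

    Each class elevates a different subset of the modifiable residues
    (Cys/Ser/Thr) in the C-terminal half so that classes are distinct while
    sharing the family-level signal a class-independent classifier must
    exploit.  Negatives are half background-composition proteins of 30-175
    residues and half translations of random DNA of 30-300 nt.
    """

    n_classes: int = 10
    n_pos_per_class: int = 20
    n_neg: int = 600
    pos_len_range: tuple[int, int] = (40, 80)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


_CLASS_BIAS_RESIDUES = [
    ("C",), ("S",), ("T",), ("S", "C"), ("T", "C"), ("S", "T"),
    ("C", "G"), ("S", "G"), ("T", "A"), ("S", "T", "C"),
]

#: Dirichlet concentration controlling how tightly a class's background
#: composition clusters around the global background.  Members of a real
#: precursor class are homologs and therefore share their full composition,
#: not just the modifiable-residue enrichment; a moderate concentration
#: emulates that family-level coherence.
_CLASS_PROFILE_CONCENTRATION = 60.0


def _class_frequencies(class_index: int) -> dict[str, float]:
    """Core-peptide residue frequencies for a synthetic precursor class.

    Each class combines (a) a class-specific background profile, drawn once
    per class from a Dirichlet centered on the global background, and (b) an
    enrichment of that class's modifiable residues (0.45 probability mass
    split across them).
    """
    residues = _CLASS_BIAS_RESIDUES[class_index % len(_CLASS_BIAS_RESIDUES)]
    crng = np.random.default_rng((941, class_index))
    alpha = np.array([_BG_FREQ[a] for a in _AA]) * _CLASS_PROFILE_CONCENTRATION
    profile = crng.dirichlet(alpha)
    freqs = {a: 0.55 * p for a, p in zip(_AA, profile)}
    boost = 0.45 / len(residues)
    for r in residues:
        freqs[r] = freqs[r] + boost
    total = sum(freqs.values())
    return {a: f / total for a, f in freqs.items()}


def synth_training_peptides(spec: PeptideSetSpec) -> TrainingSet:
    """Generate a labeled TrainingSet; deterministic per spec."""
    rng = np.random.default_rng(spec.seed)
    positives = []
    for ci in range(spec.n_classes):
        label = f"class{ci:02d}"
        freqs = _class_frequencies(ci)
        for _ in range(spec.n_pos_per_class):
            length = int(rng.integers(*spec.pos_len_range))
            leader_len = length // 2
            leader = _random_protein(rng, leader_len)
            core = _random_protein(rng, length - leader_len, freqs)
            positives.append((leader + core, label))
    negatives = []
    n_protein_like = spec.n_neg // 2
    for _ in range(n_protein_like):
        length = int(rng.integers(30, 176))
        negatives.append(_random_protein(rng, length))
    translate = {codon: aa for aa, codons in _CODONS.items() for codon in codons}
    for _ in range(spec.n_neg - n_protein_like):
        nt_len = int(rng.integers(30, 301))
        n_aa = max(1, nt_len // 3)
        aas: list[str] = []
        while len(aas) < n_aa:  # translate random codons, stops resampled
            codon = "".join(rng.choice(list("ACGT"), size=3))
            aa = translate.get(codon)
            if aa is not None:
                aas.append(aa)
        negatives.append("".join(aas))
    return TrainingSet(positives, negatives)
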