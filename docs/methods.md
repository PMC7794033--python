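# Methods

This note documents the models and procedures implemented in `rippscout`,
the parameters that matter, the synthetic data used to test them, and the
design choices made where the design was genuinely open.

## Precursor classifier

Candidate precursors are all annotated proteins and intergenic ORFs shorter
than 100 aa (`max_precursor_len`).  Intergenic ORFs run from a start codon
(ATG/GTG/TTG, translation table 11) to the first in-frame stop, wholly
within the complement of annotated gene spans, at least 30 nt long
(`min_len_nt`; the minimum is a package choice — it matches the shortest
sequences the classifier is trained on, and anything shorter carries almost
no compositional signal).

Each peptide is described by 36 features in a fixed, versioned order
(`classifier.FEATURE_NAMES`): length; GRAVY hydrophobicity (Kyte–Doolittle
mean, `X` skipped); net charge at pH 7 (K/R +1, H +0.1, D/E −1); the 20
residue fractions; five residue-class fractions (aliphatic AVLIM, aromatic
FWY, polar-uncharged STNQC, positive KRH, negative DE); and the maximal
counts of C, S, T and S+T+C in any contiguous window of 20 and of 30
residues (window capped at the peptide length).  The windowed features
capture the local enrichment of modifiable residues typical of RiPP core
peptides.

The ensemble uses three fixed kernel configurations —
poly(degree 3, coef0 2.154, γ 2.78e−2, C 0.158),
poly(degree 4, coef0 2.154, γ 4.64e−3, C 25.119), and
RBF(γ 1e−5, C 6.310e5) — each trained once on all positives and once per
leave-one-class-out subset: 3(k+1) members for k classes.  Features are
standardized per member on that member's own training split.  Member
probabilities come from sigmoid (Platt) calibration of the SVM decision
function (`CalibratedClassifierCV(..., method="sigmoid", cv=3,
ensemble=False)`); inverse-frequency class weights
(`class_weight="balanced"`) offset the positive/negative imbalance and can
be disabled.  The ensemble score is the arithmetic mean of member
probabilities; the default pass cutoff is 0.9.  All member seeds derive
deterministically from the run seed, so identical inputs and seed reproduce
identical scores.  Fully-contained duplicate hits are removed, the survivor
chosen by score, then annotated-over-intergenic source, then length, then
position.

## Conservation (COG) scoring

Proteomes are compared all-vs-all.  The built-in engine is exact local
alignment (Biopython `PairwiseAligner`, BLOSUM62, gap open 11 / extend 1)
with a BLAST-style bitscore from the gapped BLOSUM62 Karlin–Altschul
parameters (λ = 0.267, K = 0.041) and percent identity over aligned columns
(gaps included), so no external aligner is needed; a reader for
DIAMOND/BLAST 12-column tabular output serves large production runs.
"Similarity" thresholds are applied to percent identity throughout.

Bidirectional best hits (best by bitscore, ties by identity then subject
id) at >= 60.0% identity form the BBH graph.  trueCOGs are connected
components of the flank-conserved BBH pair relation that contain exactly
one gene per genome and are cliques; flank correspondence accepts direct
(prev–prev/next–next) or inverted (prev–next/next–prev) matching to
tolerate local inversions.  Genes at contig edges, partial genes, and genes
with partial flanks never anchor trueCOGs.

Each unordered genome pair's identity cutoff is mean − 3·SD (population
SD; zero for a single value; floored at 0) of that pair's trueCOG
identities.  Gene pairs strictly above their pair cutoff are clustered with
the Markov Cluster Algorithm (in-house dense implementation: self-loops at
the column maximum, expansion/inflation iterations, inflation 2.0 by
default — the standard MCL default, as the original procedure does not fix
one).  A gene's COG score is the number of *distinct genomes* represented
in its COG divided by the genome count; counting distinct genomes rather
than members keeps the score in (0, 1] in the presence of paralogs.  Genes
in no kept pair are singletons scoring 1/n, and cluster statistics treat
unassigned genes the same way.

When the full set supports <= 10 trueCOGs, genomes are rearranged into
overlapping subgroups: seed with the pair sharing the most trueCOGs, add
genomes greedily while the joint trueCOG count stays at or above the
minimum, then reseed from uncovered genomes (or, once all are covered, the
genome linked to the fewest others), stopping after 3 successive iterations
without new cross-genome links (the termination patience is a package
choice; the procedure's description leaves it open).  Genes are then scored
within the largest subgroup containing their genome.

## Cluster formation

The *simple* method extends from the precursor over consecutive same-strand
genes while the end-to-start gap is <= 750 nt; opposite-strand genes are
never members but their footprint counts toward the gap.  The *island*
method first groups same-strand genes with gaps <= 50 nt into islands, then
repeatedly attempts to fuse the nearest unfused island within 750 nt on
either side (closer side first, ties toward increasing coordinates),
fusing iff |mean_A − mean_B| <= 0.1 + sd_A + sd_B over the islands' COG
scores.  Up to 2 outlier genes per cluster may be excluded from the
mean/SD computation when that enables a fusion; additionally, a *failing*
nearest island small enough to fit the remaining outlier budget is absorbed
wholesale as outliers iff the island beyond it then fuses — this is the
conserved-transporter-inside-a-BGC situation.  Fusion never hops past a
failed island that was not absorbed.  Outliers remain cluster members but
are excluded from the statistics.  Finally, clusters on the same contig and
strand that overlap or lie within 50 nt are fused transitively.

## Annotation, filtering, families

Clusters are extended by up to 5 flanking genes per side (any strand,
truncated at contig edges; flanks never enter COG statistics).  Domain hits
are E-value filtered (<= 1e−5 by default; a package choice) and each
protein takes the first matching category in the fixed order regulator >
peptidase > transporter > biosynthetic; accessions appearing on several
category lists are resolved by the same order.  Production input is HMMER3
`--domtblout`; tests use an exact-motif toy scanner so no profile database
is required.

Filter presets: **mild** = mean COG <= 0.25, >= 3 genes, >= 2 biosynthetic,
>= 1 transporter; **strict** additionally requires >= 1 regulator and >= 1
peptidase at mean COG <= 0.10.  Gene and biosynthetic counts use core genes
only; the transporter/regulator/peptidase requirements search core plus the
5-gene flanks ("in or around the gene cluster").

Clusters pair when their core-gene domain sets have Jaccard >= 0.5 *and*
their best precursor alignment reaches bitscore 30; the edge weight is the
mean of the Jaccard index and the identity fraction of the best-scoring
precursor pair.  MCL over this network yields families; families smaller
than 3 go to an ungrouped list; families in which strictly more than half
of the members overlap (>= 1 bp) antiSMASH non-RiPP regions are discarded.
The Jaccard domain set uses core genes only (not flanks) — comparing
pathway content, not genomic context.

## Peptide mass arithmetic

Residue monoisotopic masses are hard-coded from IUPAC atomic masses; a
peptide's neutral mass is residues + water (18.010565) + modification
deltas.  Built-in deltas: dehydration −18.010565, reduction +2.015650,
their combination (Ser→Ala) −15.994915, methylation +14.015650,
dimethylation +28.031300, oxidative decarboxylation (CO2 + 2H) −46.005480,
thioether cyclization 0.  Crosslink types validate their constituent site
modifications (Lan/MeLan require the dehydration; AviCys/AviMeCys also the
decarboxylation) and add no mass themselves.  `annotate_delta` matches an
observed shift against all table entries and combinations of up to two
(default tolerance 0.02 Da).  Stereochemistry is not modeled.  The bundled
31-residue reference structure (core `TTPVCAASVASSTWCASAASAISGATYEAGC`,
NMe2-MeLan 1–5, Lan 11–15, AviMeCys 26–31, Dha-12, Dhb-2/13, four
Ser→d-Ala reductions, N-terminal dimethylation) evaluates to 2703.2396 Da;
tests verify it against an independent atom-composition computation.

## Synthetic data: what it emulates and what it does not

The pan-genome generator plants, per genome: core genes (present
everywhere, conserved order, per-genome substitution rate drawn from
0.005–0.05 so pairwise identities fall in ~90–99% and the mu − 3·sigma
cutoffs are non-degenerate), accessory genes (present in a chosen subset,
rate 0.005), and one same-strand BGC with gaps <= 50 nt containing a
precursor and genes carrying exact toy domain motifs for each functional
category; the motif itself is shielded from substitution (domain motifs
are conserved in reality, and the toy scanner is exact-match).  The BGC is
flanked by core genes at a fixed 100 nt gap, and accessory insertion slots
keep >= 3 core genes away from the BGC so the planted boundary is
unambiguous.  Truth tables give every gene's role and presence count, so
expected COG scores are exact (presence/n).

Training peptides: positives are 40–80 aa with a random leader half and a
C-terminal half drawn from a class-specific composition (a Dirichlet draw
around background, concentration 60, plus 0.45 probability mass on that
class's modifiable residues — classes 1–10 bias C; S; T; S,C; T,C; S,T;
C,G; S,G; T,A; S,T,C).  The Dirichlet profile gives classes the family-
level compositional coherence real homologous precursor families have.
Negatives are half background-composition proteins of 30–175 aa and half
translations of random DNA of 30–300 nt (stop codons resampled).  Defaults
are 10 classes × 20 positives and 600 negatives — a deliberately scaled-
down emulation of a real 175-positive / 20,000-negative corpus, sized so
that per-member probability calibration is stable at desk scale.  Planted
BGC precursors are drawn from the same positive model (the joint S/T/C
class), i.e. they represent detectable in-distribution precursors.

What the generator does **not** emulate: real codon usage and GC skew,
homology between training classes, genuine leader-peptide recognition
motifs, horizontal transfer, rearrangements, draft-assembly fragmentation,
or realistic domain models.  Passing tests therefore demonstrate that the
algorithms recover planted structure under their stated assumptions — not
field performance on real genomes, which additionally depends on
annotation quality and the realism of training data supplied by the user.

Problem sizes in the test suite (5 genomes × ~30 genes for conservation
recovery; 10 genomes × 20 core genes for the strict-filter demonstration;
100 seeded replicates for boundary-recovery and oracle-equivalence checks)
were chosen so planted structure is recoverable exactly while the all-vs-all
alignment stage stays small.  With 5 genomes the smallest non-singleton COG
score is 2/5 = 0.4, which no Table-style absolute filter bound (0.25/0.10)
can accept; strict-filter recovery is therefore demonstrated on a
10-genome set with a single-carrier BGC (mean COG exactly 0.10).  The
end-to-end tests use fixed seeds; individual precursor scores near the 0.9
cutoff vary between draws, as they do in reality.

## Numerical and degenerate-input choices

Population SD (ddof 0) everywhere a spread enters a rule; SD of one value
is 0.  Island and filter comparisons are inclusive (<=).  The MCL
implementation prunes entries below 1e−7 and stops at max-change < 1e−8 or
200 iterations; overlapping attractor supports are merged, so output is a
partition.  Empty intergenic gaps, contig-edge clusters, missing antiSMASH
regions (stage skipped with "unknown" flags), and genomes sharing no
trueCOGs (emitted as their own subgroup with a warning) are all handled
without error.  Circular contigs are treated as linear; origin-spanning
genes are not modeled.

## Known limitations

The built-in aligner is exact but O(n²) in total gene count — beyond a few
hundred proteins per genome set, precompute hits with DIAMOND and use the
tabular reader.  The classifier cannot exceed the information in its
36 compositional features; motif-level leader signals are invisible to it.
Precursors on the opposite strand of their machinery are missed by design.
Subgroup COG scores are relative to the subgroup, not the full set.
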