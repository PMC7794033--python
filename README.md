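# rippscout

Class-independent genome mining for RiPP biosynthetic gene clusters.

RiPPs (ribosomally synthesized and post-translationally modified peptides)
are natural products made from short gene-encoded precursor peptides.
Because each RiPP class has its own modifying enzymes, rule-based mining
tools only find classes that are already known.  `rippscout` is for
natural-product researchers who want to find *novel* RiPP classes in sets of
related bacterial genomes (typically one genus).  It combines three
class-agnostic signals:

1. **Precursor detection.**  Every predicted protein and intergenic ORF
   under 100 aa is scored by an SVM ensemble over 36 sequence features
   (length, GRAVY hydrophobicity, charge, residue and residue-class
   fractions, and maximal Cys/Ser/Thr counts in 20- and 30-residue windows).
   Three kernel configurations (two polynomial, one RBF) are each trained on
   the full positive set and on every leave-one-class-out subset, so a
   *k*-class training input yields 3(*k*+1) members; the score is the mean
   calibrated probability and the default cutoff is 0.9.  Leaving classes
   out during training forces the ensemble to generalize across classes.

2. **Conservation (COG) scoring.**  All proteins in the genome set are
   compared all-vs-all; bidirectional best hits at >= 60% identity anchor
   *trueCOGs* — genes that are BBHs across all genome pairs with both
   flanking genes also BBHs (conserved synteny).  Each genome pair gets an
   identity cutoff mu - 3·sigma from its trueCOG identity distribution;
   gene pairs above the cutoff are clustered with the Markov Cluster
   Algorithm into COGs, and each gene's **COG score** is the fraction of
   genomes containing a member of its COG.  Core genes score near 1,
   BGC genes near 1/n — the accessory genome lights up at low scores.

3. **Operon-like cluster formation.**  Same-strand genes around each
   candidate precursor are grouped into islands (gaps <= 50 nt) which are
   fused when their mean COG scores agree within 0.1 + sd_A + sd_B, with up
   to 2 outlier genes excluded from the statistics; a simple distance-only
   method (gap <= 750 nt) is also provided.  Clusters are then annotated
   with protein-domain hits, categorized (regulator > peptidase >
   transporter > biosynthetic), filtered with mild/strict presets, linked
   into candidate families by domain Jaccard (>= 0.5) plus precursor
   alignment (bitscore >= 30), clustered with MCL, and screened against
   antiSMASH regions (families with more than half of their members inside
   non-RiPP BGCs are discarded).

A small mass-arithmetic module supports downstream structure work: neutral
monoisotopic masses of modified peptides (dehydration -18.010565 Da,
reduction +2.01565, Ser->Ala -15.994915, dimethylation +28.0313, oxidative
decarboxylation -46.00548, mass-neutral thioether rings), annotation of
observed mass shifts, and [M+nH]n+ adduct conversion.

## Worked example

A bundled generator builds fully synthetic pan-genomes with planted core
genes, accessory genes, and one RiPP-like BGC, plus labeled training
peptides, so the whole pipeline runs with no downloads:

```bash
rippscout synth --outdir demo --seed 3 --bgc-presence 1
rippscout run demo/g1.gbk demo/g2.gbk demo/g3.gbk demo/g4.gbk demo/g5.gbk \
    --training-data demo/training_peptides.fasta \
    --seed 3 --outdir demo_out --filter mild
```

prints the per-stage counts:

```json
{
  "after_dedup": 1,
  "candidates_scanned": 771,
  "clusters_formed": 1,
  "cogs": 40,
  "families": 0,
  "families_discarded": 0,
  "passing_filter": 1,
  "passing_svm": 1
}
```

771 short ORFs were scored, exactly one (the planted precursor) passed the
0.9 cutoff, and the island method built one cluster around it.
`demo_out/clusters.tsv` shows the cluster:

```text
cluster                     genome contig strand start end  n_genes precursors        mean_cog sd_cog biosynthetic transporter regulator peptidase passed_filter
g5_g5|bgc_precursor_island  g5     g5_c1  +      4982 7262  6       g5|bgc_precursor  0.2000   0.0000 2            1           1         1         True
```

The span 4982–7262 matches the planted BGC coordinates in
`demo/truth_bgc.tsv` exactly; the mean COG score 0.2 reflects presence in
1 of 5 genomes, and the cluster carries the planted biosynthetic,
transporter, regulator and peptidase genes, so it passes the mild filter.

Mass arithmetic from the same CLI:

```bash
$ rippscout mass --delta -18.01
dehydration     error +0.00056 Da
$ rippscout mass --mz 500.0 --charge 1
neutral mass: 498.992724 Da
```

In Python, the bundled 31-residue lanthipeptide reference structure (three
thioether rings, six dehydrations, four d-Ala reductions, N-terminal
dimethylation, C-terminal oxidative decarboxylation):

```python
>>> from rippscout import pristinin_a3, monoisotopic_mass
>>> round(monoisotopic_mass(pristinin_a3()), 3)
2703.24
```

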