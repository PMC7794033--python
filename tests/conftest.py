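"""Shared fixtures: a synthetic 5-genome pan-genome with its full homology
analysis (computed once per session — the all-vs-all Smith-Waterman pass
dominates), and a small trained classifier ensemble."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from rippscout.align import PrecomputedHitsEngine, SmithWatermanEngine
from rippscout.classifier import train_ensemble
from rippscout.fixtures import (PangenomeSpec, PeptideSetSpec, proteomes_of,
                                synth_pangenome, synth_training_peptides)
from rippscout.pangenome import (build_bbh_graph, build_cog_table,
                                 find_truecogs, pairwise_cutoffs)

PANGENOME_SEED = 1


@dataclass
class PangenomeAnalysis:
    genomes: list
    truth: object
    proteomes: dict
    hits: list
    bbh: object
    truecogs: object
    cutoffs: list
    cog: object
    genome_of: dict


@pytest.fixture(scope="session")
def pangenome():
    genomes, truth = synth_pangenome(PangenomeSpec(seed=PANGENOME_SEED))
    return genomes, truth


@pytest.fixture(scope="session")
def pangenome_analysis(pangenome):
    genomes, truth = pangenome
    proteomes = proteomes_of(genomes)
    sw = SmithWatermanEngine()
    hits = []
    for ga, gb in itertools.permutations(sorted(proteomes), 2):
        hits.extend(sw.search(proteomes[ga], proteomes[gb]))
    engine = PrecomputedHitsEngine(hits)
    bbh = build_bbh_graph(proteomes, engine)
    truecogs = find_truecogs(genomes, bbh)
    cutoffs = pairwise_cutoffs(truecogs, bbh)
    genome_of = {gene: d["genome"] for gene, d in bbh.nodes(data=True)}
    cog = build_cog_table(hits, cutoffs, genome_of,
                          [g for p in proteomes.values() for g in p])
    return PangenomeAnalysis(genomes, truth, proteomes, hits, bbh, truecogs,
                             cutoffs, cog, genome_of)


@pytest.fixture(scope="session")
def small_ensemble():
    """6-class ensemble on the default-size synthetic training set."""
    training = synth_training_peptides(PeptideSetSpec(n_classes=6, seed=7))
    return train_ensemble(training, seed=7)


@pytest.fixture(scope="session")
def default_ensemble():
    """Ensemble trained on the default 10-class synthetic training set."""
    training = synth_training_peptides(PeptideSetSpec(seed=7))
    return train_ensemble(training, seed=7)
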