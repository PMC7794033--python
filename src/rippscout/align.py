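"""Protein homology engines and pairwise alignment utilities.

Two interchangeable engines produce :class:`HomologyHit` tables:

* :class:`SmithWatermanEngine` — exact local alignment (BLOSUM62, gap open 11
  / extend 1) through Biopython's PairwiseAligner, with a BLAST-like bitscore
  computed from the raw score using the standard gapped BLOSUM62 Karlin-
  Altschul parameters.  No external binary required; intended for moderate
  problem sizes and for tests.
* :class:`TabularHitsEngine` — reads precomputed DIAMOND/BLAST tabular output
  (``qseqid sseqid pident length mismatch gapopen qstart qend sstart send
  evalue bitscore`` or any prefix containing the used columns) for production
  runs on large genome sets.

Percent identity is computed over aligned columns (gap columns included),
matching the BLAST ``pident`` convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

# Karlin-Altschul parameters for gapped BLOSUM62, open 11 / extend 1
# (the BLAST defaults for protein searches).
_LAMBDA = 0.267
_K = 0.041


@dataclass(frozen=True)
class HomologyHit:
    """A directed local-alignment hit between two proteins."""

    query_gene: str
    subject_gene: str
    percent_identity: float  # 0-100, over aligned columns
    bitscore: float
    coverage: float  # aligned query fraction, 0-1

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity outside [0, 100]")


def bitscore_from_raw(raw_score: float) -> float:
    """BLAST-style normalized bitscore: (lambda*S - ln K) / ln 2."""
    return (_LAMBDA * raw_score - math.log(_K)) / math.log(2)


def make_protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_pair(seq_a: str, seq_b: str,
               aligner: Align.PairwiseAligner | None = None
               ) -> tuple[float, float, float]:
    """Best local alignment of two proteins.

    Returns ``(percent_identity, bitscore, query_coverage)``; all zeros when
    no positive-scoring alignment exists.
    """
    aligner = aligner or make_protein_aligner()
    try:
        alignment = aligner.align(seq_a, seq_b)[0]
    except (IndexError, ValueError):
        return 0.0, 0.0, 0.0
    if alignment.score <= 0:
        return 0.0, 0.0, 0.0
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    pident = 100.0 * counts.identities / aligned_cols if aligned_cols else 0.0
    qspan = alignment.aligned[0]
    qcov = sum(e - s for s, e in qspan) / len(seq_a) if len(seq_a) else 0.0
    return pident, bitscore_from_raw(alignment.score), qcov


class SmithWatermanEngine:
    """All-vs-all exact local alignment homology engine."""

    def __init__(self, min_bitscore: float = 25.0):
        self.min_bitscore = min_bitscore
        self._aligner = make_protein_aligner()

    def search(self, queries: dict[str, str], subjects: dict[str, str]
               ) -> list[HomologyHit]:
        """Align every query against every subject; self-hits are skipped."""
        hits = []
        for qid, qseq in queries.items():
            for sid, sseq in subjects.items():
                if qid == sid:
                    continue
                pident, bits, cov = align_pair(qseq, sseq, self._aligner)
                if bits >= self.min_bitscore:
                    hits.append(HomologyHit(qid, sid, pident, bits, cov))
        return hits


class PrecomputedHitsEngine:
    """Homology engine over an in-memory hit table."""

    def __init__(self, hits: list[HomologyHit]):
        self.hits = list(hits)

    def search(self, queries: dict[str, str], subjects: dict[str, str]
               ) -> list[HomologyHit]:
        return [h for h in self.hits
                if h.query_gene in queries and h.subject_gene in subjects]


class TabularHitsEngine(PrecomputedHitsEngine):
    """Homology engine backed by DIAMOND/BLAST ``--outfmt 6`` tabular output."""

    def __init__(self, path: str | Path):
        super().__init__(read_tabular_hits(path))


def read_tabular_hits(path: str | Path) -> list[HomologyHit]:
    """Parse DIAMOND/BLAST tabular output (default 12-column layout)."""
    hits = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise ValueError(
                f"{path}: expected >=12 tab-separated columns, got {len(cols)}")
        qlen_cov = 1.0  # coverage is not in the default layout
        hits.append(HomologyHit(cols[0], cols[1], float(cols[2]),
                                float(cols[11]), qlen_cov))
    return hits
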