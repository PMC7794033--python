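"""SVM ensemble for candidate RiPP precursor peptide detection.

Short peptides (annotated proteins and intergenic ORFs under ~100 aa) are
described by 36 sequence features and scored by an ensemble of support vector
machines.  Three kernel configurations are each trained once on the full
positive set and once per leave-one-class-out subset, so an input with *k*
precursor classes yields ``3 * (k + 1)`` members.  The ensemble score of a
peptide is the arithmetic mean of the members' calibrated probabilities; with
the default cutoff of 0.9 a peptide "passes" when its mean score reaches the
cutoff.

The leave-one-class-out construction is what makes the classifier
class-independent: members that never saw a given precursor class must still
recognize its members from properties shared across RiPP precursors (length,
charge, and local enrichment of modifiable residues such as Cys/Ser/Thr).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

FEATURE_SCHEMA_VERSION = 1

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Kyte-Doolittle hydropathy, used for the GRAVY feature.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Side-chain charge contributions at pH 7.
_CHARGE = {"K": 1.0, "R": 1.0, "H": 0.1, "D": -1.0, "E": -1.0}

_CLASS_SETS = {
    "aliphatic": set("AVLIM"),
    "aromatic": set("FWY"),
    "polar_uncharged": set("STNQC"),
    "positive": set("KRH"),
    "negative": set("DE"),
}

#: Documented fixed order of the 36 features.
FEATURE_NAMES: tuple[str, ...] = (
    ("length", "gravy", "net_charge")
    + tuple(f"frac_{aa}" for aa in AMINO_ACIDS)
    + tuple(f"frac_{c}" for c in _CLASS_SETS)
    + tuple(f"max_{res}_w{w}" for w in (20, 30) for res in ("C", "S", "T", "STC"))
)

#: The three kernel configurations of the ensemble.
KERNEL_CONFIGS: dict[str, dict] = {
    "SVM3": dict(kernel="poly", degree=3, coef0=2.154, gamma=2.78e-2, C=0.158),
    "SVM4": dict(kernel="poly", degree=4, coef0=2.154, gamma=4.64e-3, C=25.119),
    "SVMr": dict(kernel="rbf", gamma=1e-5, C=6.310e5),
}


@dataclass(frozen=True)
class FeatureVector:
    peptide_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (36,):
            raise ValueError("feature vector must have exactly 36 entries")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def _max_window_count(mask: np.ndarray, window: int) -> int:
    """Highest count of True entries in any contiguous window of given size."""
    n = len(mask)
    w = min(window, n)
    csum = np.concatenate(([0], np.cumsum(mask)))
    return int((csum[w:] - csum[:-w]).max())


def extract_features(peptide: str, peptide_id: str = "") -> FeatureVector:
    """Compute the 36-feature description of a peptide.

    ``X`` is tolerated: it contributes to length but to no residue class,
    no charge, and is skipped in the GRAVY average.
    """
    if not peptide:
        raise ValueError("empty peptide")
    pep = peptide.upper()
    unknown = set(pep) - set(AMINO_ACIDS) - {"X"}
    if unknown:
        raise ValueError(f"non-standard residues in peptide: {sorted(unknown)}")
    n = len(pep)
    arr = np.frombuffer(pep.encode(), dtype=np.uint8)
    kd_vals = [_KD[a] for a in pep if a != "X"]
    gravy = float(np.mean(kd_vals)) if kd_vals else 0.0
    charge = sum(_CHARGE.get(a, 0.0) for a in pep)
    counts = {aa: int((arr == ord(aa)).sum()) for aa in AMINO_ACIDS}
    fracs = [counts[aa] / n for aa in AMINO_ACIDS]
    class_fracs = [sum(counts[aa] for aa in s) / n for s in _CLASS_SETS.values()]
    windowed = []
    for w in (20, 30):
        masks = {
            "C": arr == ord("C"),
            "S": arr == ord("S"),
            "T": arr == ord("T"),
        }
        masks["STC"] = masks["C"] | masks["S"] | masks["T"]
        for res in ("C", "S", "T", "STC"):
            windowed.append(_max_window_count(masks[res], w))
    values = np.array([n, gravy, charge] + fracs + class_fracs + windowed,
                      dtype=float)
    return FeatureVector(peptide_id or pep[:10], values)


def _feature_matrix(peptides: list[str]) -> np.ndarray:
    return np.vstack([extract_features(p).values for p in peptides])


# ---------------------------------------------------------------------------
# Training data


@dataclass
class TrainingSet:
    """Labeled precursor training data.

    ``positives`` maps each peptide to its RiPP class label (e.g.
    "lanthipeptide"); ``negatives`` are non-precursor sequences.
    """

    positives: list[tuple[str, str]]
    negatives: list[str]

    def __post_init__(self) -> None:
        if not self.class_labels:
            raise ValueError("training set has no positive classes")

    @property
    def class_labels(self) -> list[str]:
        return sorted({label for _, label in self.positives})

    @classmethod
    def from_fasta(cls, path: str | Path) -> "TrainingSet":
        """Read training peptides from FASTA with ``|class=<label>`` header
        tags on positives; records tagged ``|class=negative`` (or untagged)
        are negatives."""
        from Bio import SeqIO

        positives, negatives = [], []
        with open(path) as fh:
            records = list(SeqIO.parse(fh, "fasta"))
        for rec in records:
            label = None
            for part in rec.description.split("|"):
                if part.startswith("class="):
                    label = part.split("=", 1)[1].strip()
            seq = str(rec.seq)
            if label and label != "negative":
                positives.append((seq, label))
            else:
                negatives.append(seq)
        return cls(positives, negatives)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, (seq, label) in enumerate(self.positives):
                fh.write(f">pos_{i}|class={label}\n{seq}\n")
            for i, seq in enumerate(self.negatives):
                fh.write(f">neg_{i}|class=negative\n{seq}\n")


# ---------------------------------------------------------------------------
# Ensemble


@dataclass
class EnsembleMember:
    kernel_name: str
    left_out_class: str | None
    model: Pipeline

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)[:, 1]


@dataclass
class ClassifierEnsemble:
    members: list[EnsembleMember]
    class_labels: list[str]
    seed: int
    schema_version: int = FEATURE_SCHEMA_VERSION

    def __len__(self) -> int:
        return len(self.members)

    def score(self, peptides: list[str]) -> np.ndarray:
        """Mean calibrated probability over all members, one per peptide."""
        if not peptides:
            return np.zeros(0)
        X = _feature_matrix(peptides)
        probs = np.vstack([m.predict_proba(X) for m in self.members])
        return probs.mean(axis=0)

    def loco_score(self, peptides: list[str], left_out_class: str) -> np.ndarray:
        """Mean probability over only the members that never saw
        ``left_out_class`` during training (one per kernel config)."""
        members = [m for m in self.members if m.left_out_class == left_out_class]
        if not members:
            raise KeyError(f"no members with left-out class {left_out_class!r}")
        X = _feature_matrix(peptides)
        return np.vstack([m.predict_proba(X) for m in members]).mean(axis=0)

    def save(self, path: str | Path) -> None:
        joblib.dump({"schema_version": self.schema_version,
                     "class_labels": self.class_labels,
                     "seed": self.seed,
                     "members": self.members}, path)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierEnsemble":
        blob = joblib.load(path)
        if blob.get("schema_version") != FEATURE_SCHEMA_VERSION:
            raise ValueError(
                f"model schema version {blob.get('schema_version')} does not "
                f"match library version {FEATURE_SCHEMA_VERSION}")
        return cls(blob["members"], blob["class_labels"], blob["seed"])


def train_ensemble(data: TrainingSet, seed: int,
                   class_weight: str | None = "balanced") -> ClassifierEnsemble:
    """Train the 3-kernel, leave-one-class-out SVM ensemble.

    For each kernel configuration one member is trained on all positives and
    one per class with that class's positives withheld, giving
    ``3 * (n_classes + 1)`` members.  Features are standardized on each
    member's own training split and the scaler is stored with the member.
    Member probabilities come from sigmoid (Platt) calibration of the SVM
    decision function.  ``class_weight='balanced'`` applies inverse-frequency
    class weights to offset the heavily unbalanced positive/negative ratio;
    pass ``None`` to disable.
    """
    labels = data.class_labels
    if len(labels) < 2:
        raise ValueError("need at least 2 positive classes for leave-one-class-out")
    if not data.negatives:
        raise ValueError("need at least 1 negative training sequence")
    X_neg = _feature_matrix(data.negatives)
    members: list[EnsembleMember] = []
    subsets: list[str | None] = [None] + labels
    idx = 0
    for kernel_name, params in KERNEL_CONFIGS.items():
        for left_out in subsets:
            pos = [seq for seq, lab in data.positives if lab != left_out]
            if not pos:
                raise ValueError(
                    f"leaving out class {left_out!r} empties the positive set")
            X = np.vstack([_feature_matrix(pos), X_neg])
            y = np.concatenate([np.ones(len(pos)), np.zeros(len(X_neg))])
            member_seed = (seed * 1_000_003 + idx) % (2**31 - 1)
            svc = SVC(class_weight=class_weight, random_state=member_seed,
                      **params)
            model = Pipeline([
                ("scale", StandardScaler()),
                ("svc", CalibratedClassifierCV(svc, method="sigmoid", cv=3,
                                               ensemble=False)),
            ])
            model.fit(X, y)
            members.append(EnsembleMember(kernel_name, left_out, model))
            idx += 1
    return ClassifierEnsemble(members, labels, seed)


# ---------------------------------------------------------------------------
# Scoring gene models and deduplication


@dataclass(frozen=True)
class CandidatePrecursor:
    """A gene whose product was scored as a possible RiPP precursor."""

    gene: "GeneModel"  # noqa: F821 - forward ref to genome_io.GeneModel
    score: float
    passed: bool


def score_peptides(ensemble: ClassifierEnsemble, genes: list,
                   cutoff: float = 0.9) -> list[CandidatePrecursor]:
    """Score gene products and flag those at or above ``cutoff``.

    Output order is stable by genomic position (contig, start, end, strand).
    """
    ordered = sorted(genes, key=lambda g: (g.contig_id, g.start, g.end, g.strand))
    scores = ensemble.score([g.product_seq for g in ordered])
    return [CandidatePrecursor(g, float(s), bool(s >= cutoff))
            for g, s in zip(ordered, scores)]


def deduplicate_hits(hits: list[CandidatePrecursor]) -> list[CandidatePrecursor]:
    """Remove candidate precursors whose gene span is fully contained in
    another hit's span on the same contig (either strand).

    Of a containing pair the survivor is chosen by higher score, then
    annotated over intergenic source, then longer span, then leftmost start.
    Partial overlaps keep both hits.
    """
    def rank(h: CandidatePrecursor):
        return (-h.score, 0 if h.gene.source == "annotation" else 1,
                -(len(h.gene)), h.gene.start, h.gene.id)

    ordered = sorted(hits, key=rank)
    kept: list[CandidatePrecursor] = []
    for h in ordered:
        contained = any(
            k.gene.contig_id == h.gene.contig_id
            and ((k.gene.start <= h.gene.start and h.gene.end <= k.gene.end)
                 or (h.gene.start <= k.gene.start and k.gene.end <= h.gene.end))
            for k in kept)
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: (h.gene.contig_id, h.gene.start, h.gene.end))
    return kept
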