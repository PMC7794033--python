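"""Monoisotopic mass arithmetic for post-translationally modified peptides.

RiPP structure elucidation leans on exact mass differences between the
gene-encoded precursor and the observed product.  The deltas modeled here are
the ones recurring in lanthipeptide-like chemistry:

* dehydration of Ser/Thr to Dha/Dhb: -18.010565 Da (loss of H2O);
* reduction of a dehydrated residue (Dha -> d-Ala): +2.015650 Da;
* their combination, net Ser -> Ala: -15.994915 Da;
* N-methylation: +14.015650 Da per methyl, +28.031300 Da for dimethylation;
* oxidative decarboxylation of a C-terminal Cys (AviCys-type, loss of
  CO2 + 2H): -46.005480 Da;
* thioether cyclization (Lan/MeLan/AviCys ring closure by Michael addition):
  0 Da — the mass change is carried entirely by the constituent site
  modifications.

Masses are neutral monoisotopic; [M+nH]n+ adducts are converted with
:func:`neutral_mass_from_mz`.  Stereochemistry is not modeled (d- and
l-residues are mass-identical).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

#: Monoisotopic residue masses (peptide-bond residues, Da), from IUPAC 2021
#: atomic masses.
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER = 18.010565
PROTON = 1.007276


@dataclass(frozen=True)
class Modification:
    name: str
    exact_delta: float

    @property
    def nominal_delta(self) -> int:
        return round(self.exact_delta)


_BUILTIN_MODIFICATIONS = (
    Modification("dehydration", -18.010565),
    Modification("reduction", +2.015650),
    Modification("dehydration+reduction", -15.994915),
    Modification("methylation", +14.015650),
    Modification("dimethylation", +28.031300),
    Modification("oxidative_decarboxylation", -46.005480),
    Modification("thioether_cyclization", 0.0),
)


class ModificationTable:
    """Named monoisotopic mass deltas, extensible from a two-column TSV."""

    def __init__(self, modifications: tuple[Modification, ...] = _BUILTIN_MODIFICATIONS):
        self._mods = {m.name: m for m in modifications}

    def __getitem__(self, name: str) -> Modification:
        return self._mods[name]

    def __contains__(self, name: str) -> bool:
        return name in self._mods

    def names(self) -> list[str]:
        return list(self._mods)

    def add(self, name: str, exact_delta: float) -> None:
        self._mods[name] = Modification(name, exact_delta)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ModificationTable":
        table = cls(())
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, delta = line.rstrip("\n").split("\t")[:2]
            table.add(name, float(delta))
        return table


DEFAULT_TABLE = ModificationTable()

#: Thioether crosslink types and the site modifications each one implies at
#: its (first, second) position.  Ring closure itself is mass-neutral.
CROSSLINK_REQUIREMENTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    # Lan: Dha (dehydrated Ser) + Cys
    "Lan": (("dehydration",), ()),
    # MeLan: Dhb (dehydrated Thr) + Cys
    "MeLan": (("dehydration",), ()),
    # AviCys: Dha partner + decarboxylated Cys
    "AviCys": (("dehydration",), ("oxidative_decarboxylation",)),
    # AviMeCys: Dhb partner + decarboxylated Cys
    "AviMeCys": (("dehydration",), ("oxidative_decarboxylation",)),
    "disulfide": ((), ()),
}


@dataclass(frozen=True)
class Crosslink:
    pos_i: int  # 1-based
    pos_j: int
    type: str

    def __post_init__(self) -> None:
        if self.type not in CROSSLINK_REQUIREMENTS:
            raise ValueError(f"unknown crosslink type {self.type!r}")


@dataclass
class ModifiedPeptide:
    """A core peptide with site modifications and thioether crosslinks.

    ``site_modifications`` holds ``(position, modification name)`` pairs with
    1-based positions; a position may carry several modifications.  Crosslink
    types validate that their constituent site modifications are present —
    e.g. an AviMeCys bridge requires a dehydration at the Thr partner and an
    oxidative decarboxylation at the Cys partner.
    """

    core_sequence: str
    site_modifications: list[tuple[int, str]] = field(default_factory=list)
    crosslinks: list[Crosslink] = field(default_factory=list)
    table: ModificationTable = field(default_factory=lambda: DEFAULT_TABLE)

    def __post_init__(self) -> None:
        n = len(self.core_sequence)
        bad = set(self.core_sequence) - set(RESIDUE_MASS)
        if bad:
            raise ValueError(f"unknown residue letters: {sorted(bad)}")
        for pos, name in self.site_modifications:
            if not 1 <= pos <= n:
                raise ValueError(f"modification position {pos} outside 1..{n}")
            if name not in self.table:
                raise ValueError(f"unknown modification {name!r}")
        mods_at = {}
        for pos, name in self.site_modifications:
            mods_at.setdefault(pos, set()).add(name)
        for xl in self.crosslinks:
            for pos in (xl.pos_i, xl.pos_j):
                if not 1 <= pos <= n:
                    raise ValueError(f"crosslink position {pos} outside 1..{n}")
            req_i, req_j = CROSSLINK_REQUIREMENTS[xl.type]
            for pos, required in ((xl.pos_i, req_i), (xl.pos_j, req_j)):
                missing = set(required) - mods_at.get(pos, set())
                if missing:
                    raise ValueError(
                        f"{xl.type} crosslink at {xl.pos_i}-{xl.pos_j} requires "
                        f"{sorted(missing)} at position {pos}")


def monoisotopic_mass(p: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification
    deltas.  Crosslink formation contributes nothing beyond its constituent
    site modifications."""
    mass = sum(RESIDUE_MASS[a] for a in p.core_sequence) + WATER
    mass += sum(p.table[name].exact_delta for _pos, name in p.site_modifications)
    return mass


def annotate_delta(observed: float, tol: float = 0.02, max_combo: int = 2,
                   table: ModificationTable = DEFAULT_TABLE
                   ) -> list[tuple[tuple[str, ...], float]]:
    """Modification (combinations) whose summed exact delta matches an
    observed mass shift.

    Returns ``(names, error)`` tuples for all combinations of up to
    ``max_combo`` table entries (with repetition) within ``tol`` Da, sorted
    by absolute error.  Zero-delta entries are excluded from combinations
    with other entries, since they never change a match.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    names = table.names()
    results = []
    for k in range(1, max_combo + 1):
        for combo in itertools.combinations_with_replacement(names, k):
            if k > 1 and any(table[n].exact_delta == 0.0 for n in combo):
                continue
            delta = sum(table[n].exact_delta for n in combo)
            err = observed - delta
            if abs(err) <= tol:
                results.append((combo, err))
    results.sort(key=lambda r: (abs(r[1]), len(r[0]), r[0]))
    return results


def neutral_mass_from_mz(mz: float, charge: int, proton: float = PROTON) -> float:
    """Neutral monoisotopic mass of an [M+zH]z+ ion."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return mz * charge - charge * proton


def mz_from_neutral_mass(mass: float, charge: int, proton: float = PROTON) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (mass + charge * proton) / charge


def pristinin_a3() -> ModifiedPeptide:
    """The mature pristinin A3 structure, 31 residues.

    Gene-encoded core ``TTPVCAASVASSTWCASAASAISGATYEAGC`` carrying:
    an N-terminal dimethylation; dehydrations at Thr-1, Thr-2, Ser-11,
    Ser-12 (Dha), Thr-13 (Dhb) and Thr-26; four Ser -> d-Ala conversions
    (dehydration + reduction) at 8, 17, 20 and 23; oxidative decarboxylation
    of the C-terminal Cys-31; and three thioether rings — NMe2-MeLan 1-5,
    Lan 11-15, and AviMeCys 26-31.
    """
    core = "TTPVCAASVASSTWCASAASAISGATYEAGC"
    mods = [
        (1, "dimethylation"),
        (1, "dehydration"),
        (2, "dehydration"),
        (8, "dehydration+reduction"),
        (11, "dehydration"),
        (12, "dehydration"),
        (13, "dehydration"),
        (17, "dehydration+reduction"),
        (20, "dehydration+reduction"),
        (23, "dehydration+reduction"),
        (26, "dehydration"),
        (31, "oxidative_decarboxylation"),
    ]
    links = [Crosslink(1, 5, "MeLan"), Crosslink(11, 15, "Lan"),
             Crosslink(26, 31, "AviMeCys")]
    return ModifiedPeptide(core, mods, links)
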