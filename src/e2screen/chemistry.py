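"""Average-mass chemistry for the ubiquitin discharge assay.

Everything in the assay is read out as singly protonated average masses
((M+H)+ in linear-mode MALDI-TOF), so this module works exclusively with
average atomic weights: ubiquitin and mutants from their sequence, small
nucleophiles from their elemental formula, condensation adducts
(isopeptide / oxyester / thioester / alpha-amine, all losing one water),
and the uniformly 15N-labeled internal standard.  The assembled expected
m/z values form the mass control list against which detected peaks are
matched.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "MolecularSpecies",
    "BondType",
    "ControlEntry",
    "MassControlList",
    "mass_from_formula",
    "average_mass_from_sequence",
    "adduct_mass",
    "isotope_label_mass",
    "nitrogen_count",
    "build_mass_control_list",
    "UBIQUITIN_SEQUENCE",
    "NUCLEOPHILES",
    "ADDUCT_LABELS",
    "PRINTED_MASSES",
]

# IUPAC 2021 conventional (abridged) average atomic weights, Da.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

#: Mass of a proton, Da; added once per charge for (M+nH)n+ reporting.
PROTON_MASS = 1.00728

#: Average mass of one water molecule, Da (lost in every condensation).
WATER_MASS = 2 * ATOMIC_WEIGHTS["H"] + ATOMIC_WEIGHTS["O"]

#: Exact mass of 15N minus the average weight of natural N: the per-atom
#: shift of a uniformly 15N-labeled species.
N15_SHIFT = 15.0001086 - ATOMIC_WEIGHTS["N"]

# Amino-acid residue compositions (residue = amino acid minus one water).
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

#: Canonical 76-residue human ubiquitin.
UBIQUITIN_SEQUENCE = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYN"
    "IQKESTLHLVLRLRGG"
)

VALID_BOND_KINDS = ("isopeptide", "oxyester", "thioester", "alpha-amine")


class UnsupportedElementError(ValueError):
    """An elemental formula contains an element outside the supported table."""


def mass_from_formula(formula: Mapping[str, int]) -> float:
    """Average molecular mass (Da) of an elemental composition.

    Parameters
    ----------
    formula
        Element symbol -> atom count.  Supported elements: C, H, N, O, S.
        An empty map yields 0.0.
    """
    total = 0.0
    for element, count in formula.items():
        if element not in ATOMIC_WEIGHTS:
            raise UnsupportedElementError(
                f"unsupported element {element!r}; supported: "
                f"{sorted(ATOMIC_WEIGHTS)}"
            )
        if count < 0:
            raise ValueError(f"negative count for element {element!r}: {count}")
        total += count * ATOMIC_WEIGHTS[element]
    return total


def average_mass_from_sequence(sequence: str) -> float:
    """Neutral average mass (Da) of a peptide from its one-letter sequence.

    Sums residue masses and adds one water for the free termini.
    """
    if not sequence:
        raise ValueError("sequence must contain at least one residue")
    total = WATER_MASS
    for letter in sequence:
        if letter not in RESIDUE_FORMULAS:
            raise ValueError(f"unknown residue letter {letter!r}")
        total += mass_from_formula(RESIDUE_FORMULAS[letter])
    return total


def nitrogen_count(sequence: str) -> int:
    """Total nitrogen atoms (backbone + side chains) in a peptide."""
    if not sequence:
        raise ValueError("sequence must contain at least one residue")
    return sum(RESIDUE_FORMULAS[letter]["N"] for letter in sequence)


@dataclass(frozen=True)
class MolecularSpecies:
    """A named chemical entity defined by a sequence or an elemental formula.

    ``charge_adduct`` is the number of protons added for (M+nH)n+ m/z
    reporting; the assay works in (M+H)+ throughout (default 1).
    """

    label: str
    sequence: str | None = None
    formula: Mapping[str, int] | None = None
    charge_adduct: int = 1

    def __post_init__(self) -> None:
        if (self.sequence is None) == (self.formula is None):
            raise ValueError(
                f"{self.label!r}: exactly one of sequence/formula is required"
            )
        if self.sequence is not None and not self.sequence:
            raise ValueError(f"{self.label!r}: empty sequence")
        if self.formula is not None and not self.formula:
            raise ValueError(f"{self.label!r}: empty formula")
        if self.charge_adduct < 0:
            raise ValueError("charge_adduct must be >= 0")
        # Validate composition eagerly so bad species fail at construction.
        self.average_mass  # noqa: B018

    @property
    def average_mass(self) -> float:
        """Neutral average mass, Da."""
        if self.sequence is not None:
            return average_mass_from_sequence(self.sequence)
        assert self.formula is not None
        return mass_from_formula(self.formula)

    @property
    def mz(self) -> float:
        """(M+nH)n+ average m/z with n = ``charge_adduct`` (n=0: neutral M)."""
        n = self.charge_adduct
        if n == 0:
            return self.average_mass
        return (self.average_mass + n * PROTON_MASS) / n


@dataclass(frozen=True)
class BondType:
    """Kind of linkage formed when ubiquitin condenses onto a nucleophile.

    All four kinds are condensations that release one water, so the kind is
    bookkeeping only — it never changes the mass arithmetic.
    """

    kind: str

    def __post_init__(self) -> None:
        if self.kind not in VALID_BOND_KINDS:
            raise ValueError(
                f"unknown bond kind {self.kind!r}; expected one of "
                f"{VALID_BOND_KINDS}"
            )


def adduct_mass(
    base_mz: float,
    nucleophile: MolecularSpecies,
    bond: BondType | str = "oxyester",
) -> float:
    """Expected adduct m/z: base m/z plus nucleophile mass minus one water.

    ``base_mz`` is the (M+H)+ m/z of the unreacted protein; condensation
    preserves the proton, so the adduct stays singly protonated.
    """
    if base_mz <= 0:
        raise ValueError("base_mz must be positive")
    if isinstance(bond, str):
        bond = BondType(bond)
    return base_mz + nucleophile.average_mass - WATER_MASS


def isotope_label_mass(species_mz: float, n_nitrogen: int) -> float:
    """m/z of the uniformly 15N-labeled counterpart of a species.

    Each of the ``n_nitrogen`` nitrogen atoms gains ``N15_SHIFT`` Da.
    """
    if n_nitrogen < 0:
        raise ValueError("nitrogen count must be >= 0")
    return species_mz + n_nitrogen * N15_SHIFT


# ---------------------------------------------------------------------------
# The assay's species panel

#: Nucleophiles screened in the discharge assay, as the reagent forms used:
#: N-alpha-acetyl-L-lysine, N-acetyl-L-serine, N-acetyl-L-threonine,
#: glycerol, D-glucose.
NUCLEOPHILES: dict[str, MolecularSpecies] = {
    "Ac-K": MolecularSpecies("Ac-K", formula={"C": 8, "H": 16, "N": 2, "O": 3}),
    "Ac-S": MolecularSpecies("Ac-S", formula={"C": 5, "H": 9, "N": 1, "O": 4}),
    "Ac-T": MolecularSpecies("Ac-T", formula={"C": 6, "H": 11, "N": 1, "O": 4}),
    "glycerol": MolecularSpecies("glycerol", formula={"C": 3, "H": 8, "O": 3}),
    "glucose": MolecularSpecies("glucose", formula={"C": 6, "H": 12, "O": 6}),
}

#: Bond each nucleophile forms with the ubiquitin C terminus.
NUCLEOPHILE_BONDS: dict[str, str] = {
    "Ac-K": "isopeptide",
    "Ac-S": "oxyester",
    "Ac-T": "oxyester",
    "glycerol": "oxyester",
    "glucose": "oxyester",
}

#: Adduct label used in control lists and result tables, per nucleophile.
ADDUCT_LABELS: dict[str, str] = {
    "Ac-K": "Ub-K",
    "Ac-S": "Ub-S",
    "Ac-T": "Ub-T",
    "glycerol": "Ub-glycerol",
    "glucose": "Ub-Glucose",
}

UBIQUITIN = MolecularSpecies("Ub", sequence=UBIQUITIN_SEQUENCE)

#: Instrument-software mass list actually used in the screen, for override
#: mode and for cross-checking the computed arithmetic.
PRINTED_MASSES: dict[str, float] = {
    "Ub": 8565.7,
    "Ub-K": 8735.7,
    "Ub-T": 8709.6,
    "Ub-S": 8695.8,
    "Ub-glycerol": 8640.5,
    "Ub-Glucose": 8729.9,
    "15N-Ub": 8669.5,
}

STANDARD_LABEL = "15N-Ub"

VALID_ROLES = ("analyte", "adduct", "standard")


@dataclass(frozen=True)
class ControlEntry:
    label: str
    expected_mz: float
    role: str
    source: str = "computed"  # computed | override

    def __post_init__(self) -> None:
        if self.expected_mz <= 0:
            raise ValueError(f"{self.label!r}: expected_mz must be positive")
        if self.role not in VALID_ROLES:
            raise ValueError(f"{self.label!r}: unknown role {self.role!r}")


@dataclass
class MassControlList:
    """Ordered expected-(M+H)+ list against which detected peaks are matched."""

    entries: list[ControlEntry] = field(default_factory=list)
    match_tolerance: float = 5.0

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate control-list labels in {labels}")
        standards = [e for e in self.entries if e.role == "standard"]
        if len(standards) > 1:
            raise ValueError("at most one standard entry is allowed")
        self._warn_if_ambiguous()

    def _warn_if_ambiguous(self) -> None:
        for i, a in enumerate(self.entries):
            for b in self.entries[i + 1 :]:
                if abs(a.expected_mz - b.expected_mz) < 2 * self.match_tolerance:
                    logger.warning(
                        "control entries %s (%.1f) and %s (%.1f) are closer "
                        "than 2x match tolerance (%.1f Da); matching may be "
                        "ambiguous",
                        a.label, a.expected_mz, b.label, b.expected_mz,
                        self.match_tolerance,
                    )

    @property
    def standard(self) -> ControlEntry | None:
        for e in self.entries:
            if e.role == "standard":
                return e
        return None

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, label: str) -> ControlEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "expected_mz", "role", "source"])
            for e in self.entries:
                writer.writerow([e.label, repr(e.expected_mz), e.role, e.source])

    @classmethod
    def from_csv(cls, path, match_tolerance: float = 5.0) -> "MassControlList":
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries.append(
                    ControlEntry(
                        label=row["label"],
                        expected_mz=float(row["expected_mz"]),
                        role=row["role"],
                        source=row.get("source", "override"),
                    )
                )
        return cls(entries=entries, match_tolerance=match_tolerance)


def build_mass_control_list(
    analyte: MolecularSpecies = UBIQUITIN,
    nucleophiles: Sequence[MolecularSpecies] | Iterable[str] = (),
    standard_nitrogen: int | None = None,
    match_tolerance: float = 5.0,
    overrides: Mapping[str, float] | None = None,
    adduct_labels: Mapping[str, str] | None = None,
) -> MassControlList:
    """Assemble the expected-m/z control list for one assay configuration.

    Parameters
    ----------
    analyte
        The unreacted protein (its (M+H)+ is the analyte entry).
    nucleophiles
        Species (or panel keys into :data:`NUCLEOPHILES`) whose condensation
        adducts are listed.
    standard_nitrogen
        Nitrogen count of the analyte for the uniformly 15N-labeled internal
        standard; ``None`` omits the standard (ubiquitin-mutant mode).
    overrides
        label -> m/z replacing the computed value (e.g. the instrument
        software's printed list); overridden entries carry source="override".
    """
    adduct_labels = dict(ADDUCT_LABELS if adduct_labels is None else adduct_labels)
    overrides = dict(overrides or {})

    def _mz(label: str, computed: float, role: str) -> ControlEntry:
        if label in overrides:
            return ControlEntry(label, overrides[label], role, source="override")
        return ControlEntry(label, computed, role, source="computed")

    entries = [_mz(analyte.label, analyte.mz, "analyte")]
    for nuc in nucleophiles:
        if isinstance(nuc, str):
            nuc = NUCLEOPHILES[nuc]
        label = adduct_labels.get(nuc.label, f"{analyte.label}-{nuc.label}")
        bond = NUCLEOPHILE_BONDS.get(nuc.label, "oxyester")
        entries.append(_mz(label, adduct_mass(analyte.mz, nuc, bond), "adduct"))
    if standard_nitrogen is not None:
        entries.append(
            _mz(
                STANDARD_LABEL,
                isotope_label_mass(analyte.mz, standard_nitrogen),
                "standard",
            )
        )
    return MassControlList(entries=entries, match_tolerance=match_tolerance)


def default_control_list(
    match_tolerance: float = 5.0, use_printed: bool = False
) -> MassControlList:
    """The screen's standard seven-entry list (Ub, five adducts, 15N-Ub)."""
    return build_mass_control_list(
        analyte=UBIQUITIN,
        nucleophiles=list(NUCLEOPHILES.values()),
        standard_nitrogen=nitrogen_count(UBIQUITIN_SEQUENCE),
        match_tolerance=match_tolerance,
        overrides=PRINTED_MASSES if use_printed else None,
    )
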