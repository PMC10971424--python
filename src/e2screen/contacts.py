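"""Distance-based classification of E2~Ub interface contacts.

Reads a PDB coordinate model and classifies residue pairs across a chosen
chain pair as hydrophobic, ionic, or cation-pi.  Hydrophobic and ionic
contacts use a heavy-atom distance cutoff (default 4.5 A); cation-pi
contacts use the distance from a cationic group center (Lys NZ, Arg CZ)
to an aromatic ring centroid (Phe/Tyr six-ring, Trp five- and six-rings
separately, His imidazole) with an inclusive 6.0 A cutoff.  The C-terminal
backbone carboxylate counts as an anionic partner, so e.g. a histidine
facing the ubiquitin Gly76 tail is read as an ionic contact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StructureModel",
    "Atom",
    "ContactRecord",
    "parse_structure",
    "residue_contacts",
    "cation_pi_contacts",
    "contacts_to_frame",
]

CANONICAL_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Residues whose side-chain carbons participate in hydrophobic packing.
APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: Side-chain atoms carrying formal charge at physiological pH.
CATIONIC_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}
ANIONIC_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}

#: Cation center used for cation-pi screening.
CATION_PI_CENTERS = {"LYS": "NZ", "ARG": "CZ"}

#: Aromatic ring definitions: residue -> {ring name -> atom names}.
AROMATIC_RINGS: dict[str, dict[str, tuple[str, ...]]] = {
    "PHE": {"ring": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")},
    "TYR": {"ring": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")},
    "TRP": {
        "ring5": ("CG", "CD1", "NE1", "CE2", "CD2"),
        "ring6": ("CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"),
    },
    "HIS": {"ring": ("CG", "ND1", "CD2", "CE1", "NE2")},
}


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    x: float
    y: float
    z: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StructureModel:
    """Flat atom list of one coordinate model (ATOM records only)."""

    atoms: list[Atom]

    def chains(self) -> set[str]:
        return {a.chain for a in self.atoms}

    def residues(self, chain: str) -> dict[int, list[Atom]]:
        out: dict[int, list[Atom]] = {}
        for a in self.atoms:
            if a.chain == chain:
                out.setdefault(a.residue_number, []).append(a)
        return out


@dataclass(frozen=True)
class ContactRecord:
    """One classified residue-residue contact.

    ``kind`` is hydrophobic, ionic, or cation_pi; for Trp cation-pi
    contacts ``detail`` says which ring (ring5/ring6) qualified.
    """

    chain_a: str
    residue_a: int
    resname_a: str
    chain_b: str
    residue_b: int
    resname_b: str
    kind: str
    distance: float
    detail: str = ""

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def parse_structure(path) -> StructureModel:
    """Load ATOM records from a PDB file via gemmi.

    HETATM records are ignored; for alternate locations the
    highest-occupancy conformer of each atom is kept.  Files without any
    ATOM record are rejected.
    """
    import gemmi

    path = Path(path)
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: malformed PDB file: {exc}") from exc
    atoms: list[Atom] = []
    if len(structure) == 0:
        raise ValueError(f"{path}: no coordinate model found")
    model = structure[0]
    for chain in model:
        for residue in chain:
            if residue.het_flag == "H":
                continue
            if residue.name not in CANONICAL_RESIDUES:
                logger.warning(
                    "%s: skipping non-canonical residue %s %s%d",
                    path, residue.name, chain.name, residue.seqid.num,
                )
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for name, atom in best.items():
                pos = atom.pos
                if not all(np.isfinite([pos.x, pos.y, pos.z])):
                    raise ValueError(
                        f"{path}: non-finite coordinates for atom {name} in "
                        f"{residue.name} {chain.name}{residue.seqid.num}"
                    )
                atoms.append(
                    Atom(
                        chain=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=name,
                        x=pos.x, y=pos.y, z=pos.z,
                    )
                )
    if not atoms:
        raise ValueError(f"{path}: no ATOM records parsed")
    return StructureModel(atoms=atoms)


def _require_chains(model: StructureModel, chain_a: str, chain_b: str) -> None:
    present = model.chains()
    for c in (chain_a, chain_b):
        if c not in present:
            raise ValueError(f"chain {c!r} not present (found {sorted(present)})")


def _side_chain_carbons(atoms: list[Atom]) -> list[Atom]:
    return [
        a for a in atoms
        if a.atom_name not in BACKBONE_ATOMS and a.atom_name.startswith("C")
    ]


def _charged_atoms(atoms: list[Atom], terminal: bool) -> tuple[list[Atom], list[Atom]]:
    """(cationic, anionic) atoms of one residue.

    The C-terminal residue contributes its backbone carboxylate oxygens
    (O and OXT) as anionic partners.
    """
    resname = atoms[0].residue_name
    cationic = [a for a in atoms if a.atom_name in CATIONIC_ATOMS.get(resname, ())]
    anionic = [a for a in atoms if a.atom_name in ANIONIC_ATOMS.get(resname, ())]
    if terminal:
        anionic += [a for a in atoms if a.atom_name in ("O", "OXT")]
    return cationic, anionic


def residue_contacts(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    heavy_atom_cutoff: float = 4.5,
) -> list[ContactRecord]:
    """Hydrophobic and ionic contacts between two chains.

    Hydrophobic: any side-chain carbon pair at <= cutoff between apolar
    residues.  Ionic: any cationic/anionic group atom pair at <= cutoff,
    including the C-terminal backbone carboxylate as an anionic group.
    Cutoffs are inclusive; the minimum qualifying distance is reported.
    """
    _require_chains(model, chain_a, chain_b)
    res_a = model.residues(chain_a)
    res_b = model.residues(chain_b)
    last_a, last_b = max(res_a), max(res_b)
    records: list[ContactRecord] = []
    for num_a, atoms_a in sorted(res_a.items()):
        for num_b, atoms_b in sorted(res_b.items()):
            name_a = atoms_a[0].residue_name
            name_b = atoms_b[0].residue_name
            # hydrophobic
            if name_a in APOLAR_RESIDUES and name_b in APOLAR_RESIDUES:
                d = _min_distance(_side_chain_carbons(atoms_a),
                                  _side_chain_carbons(atoms_b))
                if d is not None and d <= heavy_atom_cutoff:
                    records.append(ContactRecord(
                        chain_a, num_a, name_a, chain_b, num_b, name_b,
                        kind="hydrophobic", distance=d,
                    ))
            # ionic (either polarity)
            cat_a, ani_a = _charged_atoms(atoms_a, terminal=num_a == last_a)
            cat_b, ani_b = _charged_atoms(atoms_b, terminal=num_b == last_b)
            candidates = [
                _min_distance(cat_a, ani_b),
                _min_distance(ani_a, cat_b),
            ]
            dists = [d for d in candidates if d is not None]
            if dists and min(dists) <= heavy_atom_cutoff:
                records.append(ContactRecord(
                    chain_a, num_a, name_a, chain_b, num_b, name_b,
                    kind="ionic", distance=min(dists),
                ))
    return records


def _min_distance(atoms_a: list[Atom], atoms_b: list[Atom]) -> float | None:
    if not atoms_a or not atoms_b:
        return None
    pa = np.array([a.xyz for a in atoms_a])
    pb = np.array([b.xyz for b in atoms_b])
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return float(d.min())


def ring_centroids(atoms: list[Atom]) -> dict[str, np.ndarray]:
    """Aromatic ring centroid(s) of one residue; empty for non-aromatics.

    The centroid is the plain geometric mean of the ring atoms, so for a
    regular polygon it coincides with the geometric center exactly.
    """
    resname = atoms[0].residue_name
    rings = AROMATIC_RINGS.get(resname, {})
    by_name = {a.atom_name: a for a in atoms}
    out = {}
    for ring_name, members in rings.items():
        if all(m in by_name for m in members):
            out[ring_name] = np.mean([by_name[m].xyz for m in members], axis=0)
    return out


def cation_pi_contacts(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    cutoff: float = 6.0,
) -> list[ContactRecord]:
    """Cation-pi contacts between two chains at an inclusive cutoff.

    Distance from Lys NZ / Arg CZ to each aromatic ring centroid; Trp's
    five- and six-membered rings are tested (and reported) separately.
    """
    _require_chains(model, chain_a, chain_b)
    records: list[ContactRecord] = []
    for ca, cb in ((chain_a, chain_b), (chain_b, chain_a)):
        res_cat = model.residues(ca)
        res_aro = model.residues(cb)
        for num_c, atoms_c in sorted(res_cat.items()):
            resname_c = atoms_c[0].residue_name
            center_name = CATION_PI_CENTERS.get(resname_c)
            if center_name is None:
                continue
            centers = [a for a in atoms_c if a.atom_name == center_name]
            if not centers:
                continue
            center = centers[0].xyz
            for num_r, atoms_r in sorted(res_aro.items()):
                for ring_name, centroid in ring_centroids(atoms_r).items():
                    d = float(np.linalg.norm(center - centroid))
                    if d <= cutoff:
                        records.append(ContactRecord(
                            chain_a=ca, residue_a=num_c, resname_a=resname_c,
                            chain_b=cb, residue_b=num_r,
                            resname_b=atoms_r[0].residue_name,
                            kind="cation_pi", distance=d, detail=ring_name,
                        ))
    return records


def contacts_to_frame(records: list[ContactRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chain_a": r.chain_a, "residue_a": r.residue_a,
                "resname_a": r.resname_a,
                "chain_b": r.chain_b, "residue_b": r.residue_b,
                "resname_b": r.resname_b,
                "kind": r.kind, "distance": round(r.distance, 3),
                "detail": r.detail,
            }
            for r in records
        ]
    )
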