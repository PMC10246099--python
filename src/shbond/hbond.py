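"""Hydrogen-bond enumeration and short/normal classification.

A hydrogen bond is accepted when three geometric criteria hold: both
heteroatoms are O or N, the heavy-atom distance R lies in [2.3, 3.2] A, and
the donor-H-acceptor angle is at least 135 degrees. Bonds with R <= 2.7 A are
short hydrogen bonds (SHBs), bonds with R >= 2.8 A are normal hydrogen bonds
(NHBs); the narrow gap in between belongs to neither class and is kept out of
training data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np

from .geometry import angle_deg, distance
from .structure_io import Atom, LigandInstance, Residue, Structure

R_MIN = 2.3
R_MAX = 3.2
THETA_MIN = 135.0
SHB_MAX = 2.7
NHB_MIN = 2.8


class HBClass(str, Enum):
    SHB = "SHB"
    NHB = "NHB"
    INTERMEDIATE = "INTERMEDIATE"


class HBKind(str, Enum):
    PROTEIN_PROTEIN = "protein_protein"
    PROTEIN_LIGAND = "protein_ligand"


class ConfigurationError(RuntimeError):
    pass


class SelectionError(ValueError):
    pass


@dataclass
class DonorAcceptorSite:
    atom: Atom
    parent: Union[Residue, LigandInstance]
    can_donate: bool
    can_accept: bool
    attached_hydrogens: list[Atom] = field(default_factory=list)
    group_label: str = "other"
    group_formal_charge: int = 0

    @property
    def is_ligand(self) -> bool:
        return isinstance(self.parent, LigandInstance)

    def parent_key(self):
        return self.parent.key

    def __repr__(self) -> str:  # compact, for logs and TSV
        if self.is_ligand:
            p = f"{self.parent.component_id} {self.parent.chain_id}{self.parent.seq_number}"
        else:
            p = f"{self.parent.name} {self.parent.chain_id}{self.parent.seq_number}"
        return f"<site {p}/{self.atom.name}>"


@dataclass
class HydrogenBond:
    donor: DonorAcceptorSite
    acceptor: DonorAcceptorSite
    R: float
    theta: float
    hb_class: HBClass
    kind: HBKind

    def identity(self) -> tuple:
        return (self.donor.parent_key(), self.donor.atom.name,
                self.acceptor.parent_key(), self.acceptor.atom.name)


# side-chain polar sites of the 11 hydrogen-bonding residues:
# atom -> (can_donate, can_accept, side-chain group label, group charge)
_PROTEIN_SITES: dict[str, dict[str, tuple[bool, bool, str, int]]] = {
    "SER": {"OG": (True, True, "alkyl_hydroxyl", 0)},
    "THR": {"OG1": (True, True, "alkyl_hydroxyl", 0)},
    "TYR": {"OH": (True, True, "phenol", 0)},
    "ASP": {"OD1": (False, True, "carboxylate", -1),
            "OD2": (False, True, "carboxylate", -1)},
    "GLU": {"OE1": (False, True, "carboxylate", -1),
            "OE2": (False, True, "carboxylate", -1)},
    "ASN": {"OD1": (False, True, "amide", 0),
            "ND2": (True, False, "amide", 0)},
    "GLN": {"OE1": (False, True, "amide", 0),
            "NE2": (True, False, "amide", 0)},
    "HIS": {"ND1": (False, True, "n_aromatic_heterocycle", 0),
            "NE2": (True, False, "n_aromatic_heterocycle", 0)},
    "LYS": {"NZ": (True, False, "alkyl_amine", 1)},
    "ARG": {"NE": (True, False, "alkyl_amine", 1),
            "NH1": (True, False, "alkyl_amine", 1),
            "NH2": (True, False, "alkyl_amine", 1)},
    "TRP": {"NE1": (True, False, "n_aromatic_heterocycle", 0)},
}


def _attached_hydrogens(atom: Atom, container_atoms: Sequence[Atom]) -> list[Atom]:
    cutoff = 1.25  # covers O-H 0.96 and N-H 1.01 with margin
    return [
        a
        for a in container_atoms
        if a.element == "H" and 0.0 < distance(a.coords, atom.coords) < cutoff
    ]


def _heavy_neighbors(atom: Atom, container_atoms: Sequence[Atom]) -> list[Atom]:
    return [
        a
        for a in container_atoms
        if a is not atom
        and a.element != "H"
        and distance(a.coords, atom.coords) < 1.8
    ]


def enumerate_sites(structure: Structure) -> list[DonorAcceptorSite]:
    """List the polar donor/acceptor sites of a structure.

    Protein sites are restricted to the side-chain O/N atoms of the 11 polar
    residues; backbone amides and carbonyls are excluded. Every ligand O/N is
    a site, with donor capability read off its attached hydrogens and
    acceptor capability from element and valence (an N with no hydrogens is
    treated as an aromatic-type acceptor).
    """
    sites: list[DonorAcceptorSite] = []
    for res in structure.residues():
        table = _PROTEIN_SITES.get(res.name)
        if not table:
            continue
        for atom_name, (donate, accept, label, charge) in table.items():
            atom = res.atom(atom_name)
            if atom is None:
                continue
            hydrogens = _attached_hydrogens(atom, res.atoms)
            sites.append(
                DonorAcceptorSite(
                    atom=atom,
                    parent=res,
                    can_donate=donate and bool(hydrogens),
                    can_accept=accept,
                    attached_hydrogens=hydrogens,
                    group_label=label,
                    group_formal_charge=charge,
                )
            )
    for lig in structure.ligands:
        for atom in lig.atoms:
            if atom.element not in ("O", "N"):
                continue
            hydrogens = _attached_hydrogens(atom, lig.atoms)
            if atom.element == "O":
                accept = True
            else:
                accept = not hydrogens
            sites.append(
                DonorAcceptorSite(
                    atom=atom,
                    parent=lig,
                    can_donate=bool(hydrogens),
                    can_accept=accept,
                    attached_hydrogens=hydrogens,
                )
            )
    return sites


def _best_theta(donor: DonorAcceptorSite, acceptor: DonorAcceptorSite) -> float:
    """Largest donor-H-acceptor angle over the donor's hydrogens."""
    return max(
        angle_deg(donor.atom.coords, h.coords, acceptor.atom.coords)
        for h in donor.attached_hydrogens
    )


def detect_hbonds(
    structure: Structure,
    r_min: float = R_MIN,
    r_max: float = R_MAX,
    theta_min: float = THETA_MIN,
    sites: Optional[list[DonorAcceptorSite]] = None,
    auto_place_hydrogens: bool = True,
) -> list[HydrogenBond]:
    """Detect hydrogen bonds between polar sites of a structure.

    Each unordered site pair is reported at most once. When both sites could
    donate with an angle above the cutoff, the direction with the larger
    donor-H-acceptor angle wins; on an exact tie the protein side donates.
    Pairs within the same residue or the same ligand are skipped, as are
    ligand-ligand contacts.
    """
    if sites is None:
        if not structure.has_hydrogens:
            if not auto_place_hydrogens:
                raise ConfigurationError(
                    "structure has no hydrogens and automatic placement is disabled"
                )
            from .structure_io import place_polar_hydrogens

            structure = place_polar_hydrogens(structure)
        sites = enumerate_sites(structure)

    bonds: list[HydrogenBond] = []
    n = len(sites)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sites[i], sites[j]
            if a.parent_key() == b.parent_key():
                continue
            if a.is_ligand and b.is_ligand:
                continue
            r = distance(a.atom.coords, b.atom.coords)
            if not (r_min <= r <= r_max):
                continue
            candidates = []  # (theta, donor, acceptor)
            if a.can_donate and b.can_accept and a.attached_hydrogens:
                t = _best_theta(a, b)
                if t >= theta_min:
                    candidates.append((t, a, b))
            if b.can_donate and a.can_accept and b.attached_hydrogens:
                t = _best_theta(b, a)
                if t >= theta_min:
                    candidates.append((t, b, a))
            if not candidates:
                continue
            if len(candidates) == 2 and candidates[0][0] == candidates[1][0]:
                # tie: the protein side donates
                chosen = next(
                    (c for c in candidates if not c[1].is_ligand), candidates[0]
                )
            else:
                chosen = max(candidates, key=lambda c: c[0])
            theta, donor, acceptor = chosen
            kind = (
                HBKind.PROTEIN_LIGAND
                if donor.is_ligand or acceptor.is_ligand
                else HBKind.PROTEIN_PROTEIN
            )
            bonds.append(
                HydrogenBond(
                    donor=donor,
                    acceptor=acceptor,
                    R=r,
                    theta=theta,
                    hb_class=classify_by_distance(r),
                    kind=kind,
                )
            )
    return bonds


def classify_by_distance(R: float) -> HBClass:
    """Label a bond SHB (R <= 2.7), NHB (R >= 2.8) or INTERMEDIATE.

    Both window boundaries are inclusive; R outside [2.3, 3.2] is a domain
    error because such a contact is not a hydrogen bond here at all.
    """
    if not (R_MIN <= R <= R_MAX):
        raise ValueError(f"R={R} outside the hydrogen-bond window [{R_MIN}, {R_MAX}]")
    if R <= SHB_MAX:
        return HBClass.SHB
    if R >= NHB_MIN:
        return HBClass.NHB
    return HBClass.INTERMEDIATE


def measure_pair(
    structure: Structure,
    residue_selector: tuple[str, int, str],
    ligand_atom_selector: tuple[str, str],
) -> tuple[float, float]:
    """Measure (R, best theta) between one side-chain atom and one ligand atom.

    ``residue_selector`` is (chain_id, seq_number, atom_name);
    ``ligand_atom_selector`` is (component_id, atom_name). Either selection
    resolving to zero or several O/N atoms raises :class:`SelectionError`.
    """
    chain_id, seq, atom_name = residue_selector
    res_atoms = [
        (res, res.atom(atom_name))
        for res in structure.residues()
        if res.chain_id == chain_id and res.seq_number == seq and res.atom(atom_name)
    ]
    comp_id, lig_atom_name = ligand_atom_selector
    lig_atoms = [
        (lig, lig.atom(lig_atom_name))
        for lig in structure.ligands
        if lig.component_id == comp_id and lig.atom(lig_atom_name)
    ]
    if len(res_atoms) != 1 or len(lig_atoms) != 1:
        raise SelectionError(
            f"selection ambiguous or empty: {len(res_atoms)} residue atoms, "
            f"{len(lig_atoms)} ligand atoms"
        )
    res, ra = res_atoms[0]
    lig, la = lig_atoms[0]
    if ra.element not in ("O", "N") or la.element not in ("O", "N"):
        raise SelectionError("both selected atoms must be O or N")
    r = distance(ra.coords, la.coords)
    theta = 0.0
    for donor_atom, donor_container, acc in (
        (ra, res.atoms, la),
        (la, lig.atoms, ra),
    ):
        for h in _attached_hydrogens(donor_atom, donor_container):
            theta = max(theta, angle_deg(donor_atom.coords, h.coords, acc.coords))
    return r, theta


def bonds_to_tsv(structure_id: str, bonds: Sequence[HydrogenBond]) -> str:
    """Serialize detected bonds to the tab-separated exchange format."""
    buf = io.StringIO()
    buf.write(
        "structure_id\tdonor_parent\tdonor_atom\tacceptor_parent\t"
        "acceptor_atom\tR\ttheta\tclass\tkind\n"
    )

    def parent_str(site: DonorAcceptorSite) -> str:
        p = site.parent
        if site.is_ligand:
            return f"{p.component_id}:{p.chain_id}:{p.seq_number}"
        return f"{p.name}:{p.chain_id}:{p.seq_number}"

    for b in bonds:
        buf.write(
            f"{structure_id}\t{parent_str(b.donor)}\t{b.donor.atom.name}\t"
            f"{parent_str(b.acceptor)}\t{b.acceptor.atom.name}\t"
            f"{b.R:.4f}\t{b.theta:.2f}\t{b.hb_class.value}\t{b.kind.value}\n"
        )
    return buf.getvalue()
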