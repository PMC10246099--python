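"""Ligand bond perception, functional-group typing and descriptors.

Ligand connectivity comes from a Chemical Component Dictionary (CCD) block
when one is supplied, otherwise from interatomic distances against covalent
radii with a simple valence-satisfaction pass for bond orders. The
hydrogen-bonding functional group of a site atom is classified into ten named
groups plus a catch-all, organised in four propensity types: L1 (phenol),
L2 (alkyl hydroxyl), L3 (sulfate, phosphate, carboxyl, carboxylate) and
L4 (ester, amide, alkyl amine, N-containing aromatic heterocycle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import gemmi
import networkx as nx
import numpy as np

from .structure_io import LigandInstance

logger = logging.getLogger(__name__)

#: sentinel for molecules without an ionizable site (outside any real pKa range)
NON_IONIZABLE = 99.0

AROMATIC = "ar"

_TARGET_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 5, "H": 1,
                   "F": 1, "CL": 1, "BR": 1, "I": 1, "B": 3, "SE": 2}

# upper distance bound (A) below which a bond is taken as double: midpoints
# between typical single- and double-bond lengths for the element pair
_DOUBLE_BOND_MAX = {
    frozenset(("C", "C")): 1.43,
    frozenset(("C", "N")): 1.37,
    frozenset(("C", "O")): 1.32,
    frozenset(("C", "S")): 1.70,
    frozenset(("N", "N")): 1.32,
    frozenset(("N", "O")): 1.28,
    frozenset(("P", "O")): 1.52,
    frozenset(("S", "O")): 1.50,
}


class FunctionalGroup(str, Enum):
    PHENOL = "phenol"
    ALKYL_HYDROXYL = "alkyl_hydroxyl"
    SULFATE = "sulfate"
    PHOSPHATE = "phosphate"
    CARBOXYL = "carboxyl"
    CARBOXYLATE = "carboxylate"
    ESTER = "ester"
    AMIDE = "amide"
    ALKYL_AMINE = "alkyl_amine"
    N_AROMATIC_HETEROCYCLE = "n_aromatic_heterocycle"
    OTHER = "other"

    @property
    def type_label(self) -> str:
        return _TYPE_LABEL[self]


_TYPE_LABEL = {
    FunctionalGroup.PHENOL: "L1",
    FunctionalGroup.ALKYL_HYDROXYL: "L2",
    FunctionalGroup.SULFATE: "L3",
    FunctionalGroup.PHOSPHATE: "L3",
    FunctionalGroup.CARBOXYL: "L3",
    FunctionalGroup.CARBOXYLATE: "L3",
    FunctionalGroup.ESTER: "L4",
    FunctionalGroup.AMIDE: "L4",
    FunctionalGroup.ALKYL_AMINE: "L4",
    FunctionalGroup.N_AROMATIC_HETEROCYCLE: "L4",
    FunctionalGroup.OTHER: "other",
}


class MappingError(ValueError):
    """Dictionary atoms do not match the ligand instance."""


@dataclass
class GraphAtom:
    index: int
    name: str
    element: str
    formal_charge: int = 0
    coords: Optional[np.ndarray] = None


@dataclass
class MolecularGraph:
    atoms: list[GraphAtom]
    bonds: list[tuple[int, int, object]]  # (i, j, order in {1,2,3,"ar"})
    aromatic_rings: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._adj: dict[int, list[tuple[int, object]]] = {a.index: [] for a in self.atoms}
        for i, j, order in self.bonds:
            self._adj[i].append((j, order))
            self._adj[j].append((i, order))
        self._aromatic_atoms = {i for ring in self.aromatic_rings for i in ring}

    def neighbors(self, i: int) -> list[tuple[int, object]]:
        return self._adj[i]

    def heavy_neighbors(self, i: int) -> list[tuple[int, object]]:
        return [(j, o) for j, o in self._adj[i] if self.atoms[j].element != "H"]

    def hydrogen_count(self, i: int) -> int:
        return sum(1 for j, _ in self._adj[i] if self.atoms[j].element == "H")

    def is_aromatic_atom(self, i: int) -> bool:
        return i in self._aromatic_atoms

    def atom_by_name(self, name: str) -> GraphAtom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)


_CCD_ORDER = {"SING": 1, "DOUB": 2, "TRIP": 3, "AROM": AROMATIC,
              "1": 1, "2": 2, "3": 3, "AR": AROMATIC}


def _graph_from_dictionary(ligand: LigandInstance, block: gemmi.cif.Block) -> MolecularGraph:
    names = [row.str(0) for row in block.find("_chem_comp_atom.", ["atom_id"])]
    charges = {}
    elements = {}
    for row in block.find("_chem_comp_atom.", ["atom_id", "type_symbol", "charge"]):
        elements[row.str(0)] = row.str(1).upper().capitalize()
        try:
            charges[row.str(0)] = int(float(row.str(2)))
        except ValueError:
            charges[row.str(0)] = 0
    index_of = {}
    atoms = []
    instance_names = {a.name for a in ligand.atoms}
    for k, nm in enumerate(names):
        coords = None
        inst = ligand.atom(nm)
        if inst is not None:
            coords = inst.coords
        elif elements.get(nm) != "H":
            missing = sorted(n for n in names
                             if elements.get(n) != "H" and n not in instance_names)
            if missing and nm in missing:
                raise MappingError(
                    f"dictionary atoms absent from instance {ligand.component_id}: "
                    f"{', '.join(missing)}"
                )
        atoms.append(GraphAtom(index=k, name=nm, element=elements.get(nm, "C"),
                               formal_charge=charges.get(nm, 0), coords=coords))
        index_of[nm] = k
    bonds = []
    for row in block.find("_chem_comp_bond.", ["atom_id_1", "atom_id_2", "value_order"]):
        a1, a2 = row.str(0), row.str(1)
        order = _CCD_ORDER.get(row.str(2).upper(), 1)
        bonds.append((index_of[a1], index_of[a2], order))
    rings = _detect_aromatic_rings(atoms, bonds, use_geometry=False)
    return MolecularGraph(atoms=atoms, bonds=bonds, aromatic_rings=rings)


def _detect_aromatic_rings(atoms, bonds, use_geometry: bool) -> list[list[int]]:
    g = nx.Graph()
    g.add_nodes_from(a.index for a in atoms)
    explicit_ar = set()
    for i, j, order in bonds:
        if atoms[i].element == "H" or atoms[j].element == "H":
            continue
        g.add_edge(i, j)
        if order == AROMATIC:
            explicit_ar.add(frozenset((i, j)))
    rings = []
    for cycle in nx.cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        if not all(atoms[i].element in ("C", "N", "O", "S") for i in cycle):
            continue
        edges = [frozenset((cycle[k], cycle[(k + 1) % len(cycle)]))
                 for k in range(len(cycle))]
        if explicit_ar and all(e in explicit_ar for e in edges):
            rings.append(sorted(cycle))
            continue
        if use_geometry:
            coords = np.array([atoms[i].coords for i in cycle])
            if np.any([c is None for c in coords.ravel()]):
                continue
            centered = coords - coords.mean(axis=0)
            # planarity: smallest singular value = max out-of-plane extent
            dev = np.linalg.svd(centered, compute_uv=False)[-1] / np.sqrt(len(cycle))
            degs = [sum(1 for nb in g[i]) for i in cycle]
            bond_lengths = [
                float(np.linalg.norm(atoms[e1].coords - atoms[e2].coords))
                for e1, e2 in (tuple(e) for e in edges)
            ]
            if dev < 0.15 and max(degs) <= 3 and np.mean(bond_lengths) < 1.45:
                rings.append(sorted(cycle))
    return rings


def _graph_from_distances(ligand: LigandInstance) -> MolecularGraph:
    atoms = [
        GraphAtom(index=k, name=a.name, element=a.element, coords=a.coords)
        for k, a in enumerate(ligand.atoms)
    ]
    bonds: list[tuple[int, int, object]] = []
    pairs = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            d = float(np.linalg.norm(atoms[i].coords - atoms[j].coords))
            ri = gemmi.Element(atoms[i].element).covalent_r
            rj = gemmi.Element(atoms[j].element).covalent_r
            if 0.4 <= d <= ri + rj + 0.45:
                pairs.append((d, i, j))
    pairs.sort()
    order_of: dict[frozenset, object] = {frozenset((i, j)): 1 for _, i, j in pairs}
    bonds = [(i, j, 1) for _, i, j in pairs]
    rings = _detect_aromatic_rings(atoms, bonds, use_geometry=True)
    ring_edges = set()
    for ring in rings:
        for i in ring:
            for j in ring:
                if frozenset((i, j)) in order_of:
                    order_of[frozenset((i, j))] = AROMATIC
                    ring_edges.add(frozenset((i, j)))
    # remaining capacity assuming no implicit hydrogens (deposited X-ray
    # ligands usually carry none)
    capacity = {a.index: float(_TARGET_VALENCE.get(a.element.upper(), 4))
                for a in atoms}
    for e, o in order_of.items():
        for i in e:
            capacity[i] -= 1.5 if o == AROMATIC else 1.0
    # promote geometrically short non-ring bonds to double, shortest first
    for d, i, j in pairs:
        e = frozenset((i, j))
        if e in ring_edges or order_of[e] != 1:
            continue
        thr = _DOUBLE_BOND_MAX.get(
            frozenset((atoms[i].element.upper(), atoms[j].element.upper()))
        )
        if thr is not None and d < thr and capacity[i] >= 1 and capacity[j] >= 1:
            order_of[e] = 2
            capacity[i] -= 1
            capacity[j] -= 1
    bonds = [(i, j, order_of[frozenset((i, j))]) for _, i, j in pairs]
    return MolecularGraph(atoms=atoms, bonds=bonds, aromatic_rings=rings)


def perceive_bonds(
    ligand: LigandInstance, dictionary: Optional[gemmi.cif.Block] = None
) -> MolecularGraph:
    """Build the molecular graph of a ligand.

    With a CCD ``dictionary`` block, atoms, charges and bond orders are taken
    from it (atoms present in the dictionary but absent from the instance are
    tolerated only for hydrogens). Without one, bonds are inferred from
    distances below the covalent-radius sum plus 0.45 A and orders from a
    valence-satisfaction pass; aromatic rings are flagged on planar conjugated
    5/6-cycles.
    """
    if dictionary is not None:
        return _graph_from_dictionary(ligand, dictionary)
    return _graph_from_distances(ligand)


def _order_num(order) -> float:
    return 1.5 if order == AROMATIC else float(order)


def _carbonyl_oxygens(graph: MolecularGraph, c_idx: int) -> list[int]:
    """Terminal oxygens on a carbon (candidate C=O / C-O⁻ oxygens)."""
    out = []
    for j, _ in graph.heavy_neighbors(c_idx):
        if graph.atoms[j].element == "O" and len(graph.heavy_neighbors(j)) == 1:
            out.append(j)
    return out


def assign_functional_group(graph: MolecularGraph, site_atom: int) -> FunctionalGroup:
    """Classify the functional group containing an O/N site atom.

    Matching runs most-specific first (sulfate > phosphate > carboxylate >
    carboxyl > ester > amide > phenol > alkyl hydroxyl > aromatic ring N >
    alkyl amine) and falls back to ``other``, so the function is total on
    O/N atoms.
    """
    atom = graph.atoms[site_atom]
    if atom.element not in ("O", "N"):
        raise ValueError(f"site atom {atom.name} is {atom.element}, expected O or N")

    heavy = graph.heavy_neighbors(site_atom)
    elements = [graph.atoms[j].element for j, _ in heavy]

    if atom.element == "O":
        if "S" in elements:
            s = next(j for j, _ in heavy if graph.atoms[j].element == "S")
            n_o = sum(1 for j, _ in graph.heavy_neighbors(s)
                      if graph.atoms[j].element == "O")
            if n_o >= 3:
                return FunctionalGroup.SULFATE
        if "P" in elements:
            p = next(j for j, _ in heavy if graph.atoms[j].element == "P")
            n_o = sum(1 for j, _ in graph.heavy_neighbors(p)
                      if graph.atoms[j].element == "O")
            if n_o >= 3:
                return FunctionalGroup.PHOSPHATE
        carbons = [j for j, _ in heavy if graph.atoms[j].element == "C"]
        for c in carbons:
            terminal_o = _carbonyl_oxygens(graph, c)
            if site_atom in terminal_o and len(terminal_o) == 2:
                protonated = any(graph.hydrogen_count(o) > 0 for o in terminal_o)
                charged = any(graph.atoms[o].formal_charge < 0 for o in terminal_o)
                if charged or not protonated:
                    return FunctionalGroup.CARBOXYLATE
                return FunctionalGroup.CARBOXYL
            # ester: carbonyl C with one double-bonded O and one bridging O
            if len(terminal_o) == 1:
                bridge = [
                    j for j, _ in graph.heavy_neighbors(c)
                    if graph.atoms[j].element == "O"
                    and len(graph.heavy_neighbors(j)) == 2
                ]
                if bridge and (site_atom in terminal_o or site_atom in bridge):
                    return FunctionalGroup.ESTER
            if len(terminal_o) == 1 and site_atom in terminal_o:
                n_nb = [j for j, _ in graph.heavy_neighbors(c)
                        if graph.atoms[j].element == "N"]
                if n_nb:
                    return FunctionalGroup.AMIDE
        if len(heavy) == 1 and carbons:
            c = carbons[0]
            if graph.is_aromatic_atom(c):
                return FunctionalGroup.PHENOL
            if not _carbonyl_oxygens(graph, c) or _carbonyl_oxygens(graph, c) == [site_atom]:
                return FunctionalGroup.ALKYL_HYDROXYL
        return FunctionalGroup.OTHER

    # nitrogen site
    carbons = [j for j, _ in heavy if graph.atoms[j].element == "C"]
    for c in carbons:
        if _carbonyl_oxygens(graph, c):
            return FunctionalGroup.AMIDE
    if graph.is_aromatic_atom(site_atom):
        return FunctionalGroup.N_AROMATIC_HETEROCYCLE
    if heavy and all(graph.atoms[j].element == "C" for j, _ in heavy):
        if not any(graph.is_aromatic_atom(j) for j, _ in heavy):
            return FunctionalGroup.ALKYL_AMINE
    return FunctionalGroup.OTHER


def group_atoms(graph: MolecularGraph, site_atom: int) -> list[int]:
    """Atom indices of the functional group matched at ``site_atom``."""
    group = assign_functional_group(graph, site_atom)
    heavy = graph.heavy_neighbors(site_atom)
    members = {site_atom}
    if group in (FunctionalGroup.SULFATE, FunctionalGroup.PHOSPHATE):
        center_el = "S" if group is FunctionalGroup.SULFATE else "P"
        center = next(j for j, _ in heavy if graph.atoms[j].element == center_el)
        members.add(center)
        members.update(j for j, _ in graph.heavy_neighbors(center)
                       if graph.atoms[j].element == "O")
    elif group in (FunctionalGroup.CARBOXYL, FunctionalGroup.CARBOXYLATE,
                   FunctionalGroup.ESTER, FunctionalGroup.AMIDE):
        for c, _ in heavy:
            if graph.atoms[c].element != "C":
                continue
            members.add(c)
            members.update(j for j, _ in graph.heavy_neighbors(c)
                           if graph.atoms[j].element in ("O", "N"))
    elif group in (FunctionalGroup.PHENOL, FunctionalGroup.ALKYL_HYDROXYL,
                   FunctionalGroup.ALKYL_AMINE):
        members.update(j for j, _ in heavy)
    elif group is FunctionalGroup.N_AROMATIC_HETEROCYCLE:
        for ring in graph.aromatic_rings:
            if site_atom in ring:
                members.update(ring)
                break
    return sorted(members)


def group_formal_charge(graph: MolecularGraph, site_atom: int) -> int:
    """Formal charge of the functional group containing the site atom.

    Explicit charges (from a CCD dictionary) are summed when present;
    otherwise the pH-7 default of the matched group applies: carboxylate,
    sulfate and phosphate are anionic, an sp3 amine with a full complement of
    hydrogens is protonated, everything else neutral.
    """
    members = group_atoms(graph, site_atom)
    explicit = sum(graph.atoms[j].formal_charge for j in members)
    if explicit != 0:
        return explicit
    group = assign_functional_group(graph, site_atom)
    if group in (FunctionalGroup.CARBOXYLATE, FunctionalGroup.SULFATE,
                 FunctionalGroup.PHOSPHATE):
        return -1
    if group is FunctionalGroup.ALKYL_AMINE:
        n_h = graph.hydrogen_count(site_atom)
        n_heavy = len(graph.heavy_neighbors(site_atom))
        if n_h + n_heavy >= 4:
            return 1
    return 0


def estimate_logp(graph: MolecularGraph) -> float:
    """Atom-contribution (Crippen-type) octanol-water logP of the ligand."""
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import Crippen

        RDLogger.DisableLog("rdApp.*")
        mol = Chem.RWMol()
        for a in graph.atoms:
            at = Chem.Atom(a.element.capitalize())
            at.SetFormalCharge(a.formal_charge)
            at.SetNoImplicit(False)
            mol.AddAtom(at)
        for i, j, order in graph.bonds:
            bt = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                  3: Chem.BondType.TRIPLE, AROMATIC: Chem.BondType.AROMATIC}[order]
            mol.AddBond(i, j, bt)
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        return float(Crippen.MolLogP(m))
    except Exception as exc:  # unparameterizable graph: crude fallback sum
        logger.warning("Crippen logP failed (%s); using crude atom table", exc)
        table = {"C": 0.14, "H": 0.11, "N": -0.30, "O": -0.40, "S": 0.25,
                 "P": -0.30, "F": 0.22, "CL": 0.65, "BR": 0.86, "I": 1.10}
        total = 0.0
        for a in graph.atoms:
            c = table.get(a.element.upper())
            if c is None:
                logger.warning("no logP contribution for element %s", a.element)
                c = 0.0
            total += c
        return total


# template acidity constants of the ionizable groups (pKa of the acid, or of
# the conjugate acid for bases)
_ACID_PKA = {
    FunctionalGroup.CARBOXYL: 4.0,
    FunctionalGroup.CARBOXYLATE: 4.0,
    FunctionalGroup.PHOSPHATE: 2.0,
    FunctionalGroup.SULFATE: -3.0,
    FunctionalGroup.PHENOL: 10.0,
}
_BASE_PKAH = {
    FunctionalGroup.ALKYL_AMINE: 10.5,
    FunctionalGroup.N_AROMATIC_HETEROCYCLE: 5.0,
}


def estimate_pka_pkb(graph: MolecularGraph) -> tuple[float, float]:
    """Template (pKa, pKb) of the strongest acidic and basic sites.

    pKb is reported as 14 minus the conjugate-acid pKa of the strongest base.
    A molecule with no ionizable group returns the ``NON_IONIZABLE`` sentinel
    for the missing value.
    """
    acid = None
    base_pkah = None
    for a in graph.atoms:
        if a.element not in ("O", "N"):
            continue
        group = assign_functional_group(graph, a.index)
        if group in _ACID_PKA:
            v = _ACID_PKA[group]
            acid = v if acid is None else min(acid, v)
        if group in _BASE_PKAH:
            v = _BASE_PKAH[group]
            base_pkah = v if base_pkah is None else max(base_pkah, v)
    pka = acid if acid is not None else NON_IONIZABLE
    pkb = (14.0 - base_pkah) if base_pkah is not None else NON_IONIZABLE
    return pka, pkb


@dataclass
class LigandDescriptors:
    pka: float
    pkb: float
    logp: float
    net_charge: int

    @classmethod
    def from_graph(cls, graph: MolecularGraph) -> "LigandDescriptors":
        pka, pkb = estimate_pka_pkb(graph)
        return cls(pka=pka, pkb=pkb, logp=estimate_logp(graph),
                   net_charge=graph.net_charge)
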