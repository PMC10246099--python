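"""Structure model and PDB/mmCIF input.

Reads crystal structures into a small uniform model (chains of residues plus
ligand instances), applies the atomic-resolution filter, drops crystallization
additives, and places idealized polar hydrogens on side-chain and ligand O/N
donors when the deposited model has none.
"""

from __future__ import annotations

import copy
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from .geometry import (
    NH_BOND,
    OH_BOND,
    best_cone_azimuth,
    cone_direction,
    distance,
    unit,
)

logger = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: Crystallization additives excluded from hydrogen-bond analysis by default:
#: polyol cryoprotectants and inorganic anions, which sit in lattices for
#: crystal preparation rather than biological function.
DEFAULT_EXCLUDED_COMPONENTS = frozenset(
    {
        "GOL", "EDO", "PEG", "PGE", "PG4", "MPD",  # polyols / PEG fragments
        "SO4", "PO4", "NO3", "ACT", "CL", "BR",  # inorganic anions / acetate
    }
)

#: Default atomic-resolution cutoff in Angstrom.
RESOLUTION_CUTOFF = 1.1


class ParseError(ValueError):
    """Raised when a structure file cannot be interpreted."""


class UsageError(ValueError):
    """Raised on invalid caller-supplied options."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    name: str
    chain_id: str
    seq_number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)


@dataclass
class LigandInstance:
    component_id: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: Optional[list[tuple[Atom, Atom, str]]] = None
    chain_id: str = ""
    seq_number: int = 0

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.component_id, self.chain_id, self.seq_number)


@dataclass
class Structure:
    id: str
    chains: list[list[Residue]] = field(default_factory=list)
    ligands: list[LigandInstance] = field(default_factory=list)
    resolution: Optional[float] = None
    has_hydrogens: bool = False

    def residues(self) -> Iterable[Residue]:
        for chain in self.chains:
            yield from chain

    def all_atoms(self) -> Iterable[Atom]:
        for res in self.residues():
            yield from res.atoms
        for lig in self.ligands:
            yield from lig.atoms


def _resolve_altlocs(atoms: Sequence[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep blank-altloc atoms plus the single best alternate conformer.

    The conformer with the highest mean occupancy wins; ties go to the
    alphabetically first altloc identifier, so the choice is deterministic.
    """
    altlocs: dict[str, list[gemmi.Atom]] = {}
    plain = []
    for a in atoms:
        if a.altloc and a.altloc != "\x00":
            altlocs.setdefault(a.altloc, []).append(a)
        else:
            plain.append(a)
    if not altlocs:
        return plain
    best = min(
        sorted(altlocs),
        key=lambda k: (-float(np.mean([a.occ for a in altlocs[k]])), k),
    )
    return plain + altlocs[best]


def _is_text(source) -> bool:
    s = str(source)
    return "\n" in s or (not os.path.exists(s) and len(s) > 200)


def _read_gemmi(source, fmt: str) -> gemmi.Structure:
    try:
        if fmt == "pdb":
            if _is_text(source):
                return gemmi.read_pdb_string(str(source))
            return gemmi.read_pdb(str(source))
        # mmCIF
        if _is_text(source):
            doc = gemmi.cif.read_string(str(source))
        else:
            doc = gemmi.cif.read(str(source))
        return gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {fmt} input: {exc}") from exc


def parse_structure(source, format: str = "pdb") -> Structure:
    """Read a PDB or mmCIF file (path or text) into a :class:`Structure`.

    Polymer residues go to ``chains``; HETATM components other than water
    become :class:`LigandInstance` entries. Alternate locations are resolved
    to the highest-occupancy conformer. Only the first model of multi-model
    files is used.
    """
    fmt = format.lower()
    if fmt in ("mmcif", "cif"):
        fmt = "mmcif"
    elif fmt != "pdb":
        raise UsageError(f"unknown format {format!r}; expected 'pdb' or 'mmcif'")

    st = _read_gemmi(source, fmt)
    st.setup_entities()
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None

    out = Structure(id=st.name or "structure", resolution=resolution)
    has_h = False
    if len(st) == 0:
        raise ParseError("structure contains no models")
    model = st[0]
    if model.count_atom_sites() == 0:
        raise ParseError("no atom records found in input")
    for chain in model:
        poly: list[Residue] = []
        for res in chain:
            atoms = []
            for ga in _resolve_altlocs(list(res)):
                el = ga.element.name
                if el == "H":
                    has_h = True
                atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=ga.name,
                        element=el,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        altloc=ga.altloc if ga.altloc != "\x00" else "",
                        is_hetero=res.het_flag == "H",
                    )
                )
            if res.name in WATER_NAMES:
                continue
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            if res.het_flag == "H" and not is_aa:
                out.ligands.append(
                    LigandInstance(
                        component_id=res.name,
                        atoms=atoms,
                        chain_id=chain.name,
                        seq_number=res.seqid.num,
                    )
                )
            else:
                poly.append(
                    Residue(
                        name=res.name,
                        chain_id=chain.name,
                        seq_number=res.seqid.num,
                        insertion_code=res.seqid.icode.strip(),
                        atoms=atoms,
                    )
                )
        if poly:
            poly.sort(key=lambda r: (r.seq_number, r.insertion_code))
            out.chains.append(poly)
    out.has_hydrogens = has_h
    return out


def to_pdb_text(structure: Structure) -> str:
    """Serialize a :class:`Structure` as minimal standard PDB text."""
    lines = []
    if structure.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION. {structure.resolution:7.2f} ANGSTROMS."
        )
    serial = 0

    def record(kind: str, name: str, resname: str, chain: str, seq: int,
               icode: str, atom: Atom) -> str:
        nonlocal serial
        serial += 1
        nm = atom.name
        # PDB atom-name column convention: 1-char elements start in column 14
        if len(nm) < 4 and len(atom.element) == 1:
            nm = " " + nm
        x, y, z = atom.coords
        return (
            f"{kind:<6}{serial:>5} {nm:<4}{'':1}{resname:<3} {chain:1}"
            f"{seq:>4}{icode or ' ':1}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2}"
        )

    for chain in structure.chains:
        for res in chain:
            for atom in res.atoms:
                lines.append(
                    record("ATOM", atom.name, res.name, res.chain_id,
                           res.seq_number, res.insertion_code, atom)
                )
        lines.append("TER")
    for lig in structure.ligands:
        for atom in lig.atoms:
            lines.append(
                record("HETATM", atom.name, lig.component_id,
                       lig.chain_id or "X", lig.seq_number or 1, "", atom)
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def passes_resolution_filter(structure: Structure, cutoff: float = RESOLUTION_CUTOFF) -> bool:
    """True iff the resolution is known and at or below ``cutoff`` Angstrom.

    Unknown resolution fails the filter: without it, short and normal
    hydrogen bonds cannot be told apart reliably.
    """
    if structure.resolution is None:
        logger.warning("structure %s: resolution unknown; failing filter", structure.id)
        return False
    return structure.resolution <= cutoff


def exclude_crystallization_ligands(
    ligands: Sequence[LigandInstance],
    exclusion_list: frozenset | set = DEFAULT_EXCLUDED_COMPONENTS,
) -> list[LigandInstance]:
    """Drop crystallization additives; single-atom components (ions) always go."""
    kept = []
    for lig in ligands:
        if lig.component_id in exclusion_list:
            continue
        if exclusion_list and len(lig.atoms) == 1:
            continue
        kept.append(lig)
    return kept


# --- idealized polar-hydrogen placement -----------------------------------

# per-residue donor sites: site atom -> (bonded heavy atom, geometry, H names)
# geometry: "hydroxyl" rotatable OH; "sp3_3h" ammonium; "planar_1h" ring or
# secondary amide NH; "planar_2h" primary amide / guanidinium NH2.
_DONOR_TEMPLATES: dict[str, dict[str, tuple[str, str, tuple[str, ...]]]] = {
    "SER": {"OG": ("CB", "hydroxyl", ("HG",))},
    "THR": {"OG1": ("CB", "hydroxyl", ("HG1",))},
    "TYR": {"OH": ("CZ", "hydroxyl", ("HH",))},
    "LYS": {"NZ": ("CE", "sp3_3h", ("HZ1", "HZ2", "HZ3"))},
    "ARG": {
        "NE": ("CD", "planar_1h", ("HE",)),
        "NH1": ("CZ", "planar_2h", ("HH11", "HH12")),
        "NH2": ("CZ", "planar_2h", ("HH21", "HH22")),
    },
    "ASN": {"ND2": ("CG", "planar_2h", ("HD21", "HD22"))},
    "GLN": {"NE2": ("CD", "planar_2h", ("HE21", "HE22"))},
    "HIS": {"NE2": ("CD2", "planar_1h", ("HE2",))},  # NE2-H tautomer default
    "TRP": {"NE1": ("CD1", "planar_1h", ("HE1",))},
}

_TETRAHEDRAL = 109.5
_TRIGONAL = 120.0


def _neighbors_within(atom: Atom, atoms: Iterable[Atom], cutoff: float) -> list[Atom]:
    out = []
    for other in atoms:
        if other is atom:
            continue
        if distance(atom.coords, other.coords) <= cutoff:
            out.append(other)
    return out


def _has_hydrogen(atom: Atom, container_atoms: Sequence[Atom]) -> bool:
    return any(
        a.element == "H" and distance(a.coords, atom.coords) < 1.25
        for a in container_atoms
    )


def _acceptor_positions(structure: Structure, exclude_atoms: set[int]) -> list[np.ndarray]:
    pos = []
    for a in structure.all_atoms():
        if a.element in ("O", "N") and id(a) not in exclude_atoms:
            pos.append(a.coords)
    return pos


def _orient_hydroxyl(
    site: Atom, anchor: Atom, acceptors: list[np.ndarray], anchor_other: Optional[Atom]
) -> np.ndarray:
    """Direction for a rotatable O-H: on the tetrahedral cone about the C-O
    bond, pointing toward the nearest acceptor within 3.5 A, else staggered."""
    axis = unit(site.coords - anchor.coords)  # cone axis along C->O
    best = None
    best_d = 3.5
    for p in acceptors:
        d = distance(p, site.coords)
        if 0.1 < d <= best_d:
            best_d = d
            best = p
    if best is not None:
        az = best_cone_azimuth(axis, 180.0 - _TETRAHEDRAL, best - site.coords)
    elif anchor_other is not None:
        # anti to the anchor's other substituent (staggered)
        az = best_cone_azimuth(
            axis, 180.0 - _TETRAHEDRAL, site.coords - anchor_other.coords
        )
    else:
        az = 0.0
    # H-O-C angle = 109.5 => H direction at (180 - 109.5) from the C->O axis
    return cone_direction(axis, 180.0 - _TETRAHEDRAL, az)


def _place_site_hydrogens(
    site: Atom,
    anchor: Atom,
    geometry: str,
    h_names: tuple[str, ...],
    residue_atoms: Sequence[Atom],
    acceptors: list[np.ndarray],
    next_serial: int,
    is_hetero: bool,
) -> list[Atom]:
    bond = OH_BOND if site.element == "O" else NH_BOND
    heavy_neighbors = [
        a for a in _neighbors_within(site, residue_atoms, 1.8) if a.element != "H"
    ]
    anchor_others = [
        a
        for a in _neighbors_within(anchor, residue_atoms, 1.8)
        if a.element != "H" and a is not site
    ]
    directions: list[np.ndarray] = []
    if geometry == "hydroxyl":
        other = anchor_others[0] if anchor_others else None
        directions = [_orient_hydroxyl(site, anchor, acceptors, other)]
    elif geometry == "sp3_3h":
        axis = unit(site.coords - anchor.coords)
        base_az = 0.0
        if acceptors:
            nearest = min(acceptors, key=lambda p: distance(p, site.coords))
            base_az = best_cone_azimuth(axis, 180.0 - _TETRAHEDRAL, nearest - site.coords)
        directions = [
            cone_direction(axis, 180.0 - _TETRAHEDRAL, base_az + k * 120.0)
            for k in range(3)
        ]
    elif geometry == "planar_1h":
        # complete trigonal geometry: H opposite the bisector of the two
        # heavy neighbors
        others = [a for a in heavy_neighbors]
        if len(others) >= 2:
            d = -(
                unit(others[0].coords - site.coords)
                + unit(others[1].coords - site.coords)
            )
            directions = [unit(d)]
        else:
            directions = [unit(site.coords - anchor.coords)]
    elif geometry == "planar_2h":
        axis = unit(site.coords - anchor.coords)
        # plane defined by the anchor's substituents when available
        normal = None
        if len(anchor_others) >= 1:
            v1 = unit(site.coords - anchor.coords)
            v2 = unit(anchor_others[0].coords - anchor.coords)
            n = np.cross(v1, v2)
            if np.linalg.norm(n) > 1e-6:
                normal = unit(n)
        if normal is None:
            from .geometry import perp_basis

            normal = perp_basis(axis)[0]
        in_plane = np.cross(normal, axis)
        for sign in (1.0, -1.0):
            d = np.cos(np.radians(180.0 - _TRIGONAL)) * axis + sign * np.sin(
                np.radians(180.0 - _TRIGONAL)
            ) * in_plane
            directions.append(unit(d))
        directions = directions[: len(h_names)]
    else:  # pragma: no cover - template table controls geometry strings
        raise ValueError(f"unknown hydrogen geometry {geometry!r}")

    placed = []
    for name, d in zip(h_names, directions):
        placed.append(
            Atom(
                serial=next_serial + len(placed),
                name=name,
                element="H",
                coords=site.coords + bond * d,
                occupancy=1.0,
                is_hetero=is_hetero,
            )
        )
    return placed


def place_polar_hydrogens(structure: Structure) -> Structure:
    """Add idealized hydrogens to side-chain and ligand O/N donors.

    O-H bonds are set to 0.96 A and N-H to 1.01 A with ideal tetrahedral or
    trigonal angles. Rotatable hydroxyls point at the nearest acceptor within
    3.5 A, else sit staggered. Sites that already carry hydrogens (e.g.
    neutron structures) are left untouched. Residues missing the heavy atoms
    a template needs are skipped with a warning.

    Returns a new :class:`Structure`; the input is not modified.
    """
    st = copy.deepcopy(structure)
    serial = max((a.serial for a in st.all_atoms()), default=0) + 1

    for res in st.residues():
        templates = _DONOR_TEMPLATES.get(res.name)
        if not templates:
            continue
        for site_name, (anchor_name, geometry, h_names) in templates.items():
            site = res.atom(site_name)
            anchor = res.atom(anchor_name)
            if site is None or anchor is None:
                logger.warning(
                    "residue %s %s%d: missing %s/%s; hydrogen placement skipped",
                    res.name, res.chain_id, res.seq_number, site_name, anchor_name,
                )
                continue
            if _has_hydrogen(site, res.atoms):
                continue
            acceptors = _acceptor_positions(st, {id(site), id(anchor)})
            new_h = _place_site_hydrogens(
                site, anchor, geometry, h_names, res.atoms, acceptors, serial, False
            )
            res.atoms.extend(new_h)
            serial += len(new_h)

    for lig in st.ligands:
        heavies = [a for a in lig.atoms if a.element != "H"]
        for site in heavies:
            if site.element not in ("O", "N"):
                continue
            if _has_hydrogen(site, lig.atoms):
                continue
            neighbors = [a for a in _neighbors_within(site, heavies, 1.8)]
            if len(neighbors) != 1:
                continue  # bridging/terminal-multiply-bonded atoms keep no H
            anchor = neighbors[0]
            d = distance(site.coords, anchor.coords)
            acceptors = _acceptor_positions(st, {id(site), id(anchor)})
            if site.element == "O" and d > 1.32:
                # single-bonded terminal O: hydroxyl
                new_h = _place_site_hydrogens(
                    site, anchor, "hydroxyl", (f"H{site.name}",),
                    lig.atoms, acceptors, serial, True,
                )
            elif site.element == "N" and d > 1.40:
                # single-bonded terminal N: primary amine, two hydrogens
                new_h = _place_site_hydrogens(
                    site, anchor, "planar_2h", (f"H{site.name}A", f"H{site.name}B"),
                    lig.atoms, acceptors, serial, True,
                )
            else:
                continue
            lig.atoms.extend(new_h)
            serial += len(new_h)

    st.has_hydrogens = any(a.element == "H" for a in st.all_atoms())
    return st
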