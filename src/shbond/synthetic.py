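"""Synthetic fixtures: toy complexes with planted hydrogen bonds, fixture
ligand dictionaries, and feature tables with planted class-conditional signal.

Toy complexes are polyalanine scaffolds carrying one substituted polar
residue per planted bond, each paired with a small ligand fragment whose
acceptor heteroatom sits at exactly the prescribed donor-acceptor distance R,
with the donor hydrogen placed to realize the prescribed D-H-A angle. Plants
are spaced far apart so each is an isolated geometric test case, and the
generator emits standard PDB text (plus minimal CCD blocks for its toy
components) so fixtures exercise the real I/O path.

Feature tables draw SHB/NHB labels at a configurable imbalance and sample
the amino-acid residue and ligand functional group from class-conditional
distributions mirroring the observed propensity ordering (residue types
A1 > A2 > A3 and ligand group types L1 > L2 > L3 > L4); the remaining
features are either chemistry-determined or noise. The generating
log-likelihood ratio and a Monte-Carlo estimate of its achievable (Bayes)
AUC are returned alongside for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import AA20, AA_CHARGE, PAD, HBDataset, HBFeatureVector
from .geometry import NH_BOND, OH_BOND, hydrogen_for_theta
from .hbond import classify_by_distance, HBClass, R_MIN, R_MAX, THETA_MIN
from .ligand_chem import NON_IONIZABLE
from .structure_io import Atom, LigandInstance, Residue, Structure, to_pdb_text


class GenerationError(ValueError):
    pass


# --- toy complexes ---------------------------------------------------------

_PLANT_SPACING = 20.0  # Angstrom between planted bonds; >> r_max so plants
                       # cannot interact

# donor residue templates: site atom and the local side-chain/backbone
# geometry, coordinates relative to the site atom at the origin with the
# ligand along +x
_RESIDUE_TEMPLATES: dict[str, dict] = {
    "SER": {
        "site": "OG", "h_name": "HG", "h_bond": OH_BOND,
        "atoms": {
            "OG": (0.0, 0.0, 0.0),
            "CB": (-1.41, 0.0, 0.0),
            "CA": (-2.21, -1.30, 0.0),
            "N": (-3.67, -1.30, 0.0),
            "C": (-1.66, -2.50, 0.75),
            "O": (-0.56, -3.00, 0.75),
        },
    },
    "THR": {
        "site": "OG1", "h_name": "HG1", "h_bond": OH_BOND,
        "atoms": {
            "OG1": (0.0, 0.0, 0.0),
            "CB": (-1.43, 0.0, 0.0),
            "CG2": (-2.03, -0.80, 1.15),
            "CA": (-2.23, -1.28, -0.15),
            "N": (-3.69, -1.28, -0.15),
            "C": (-1.68, -2.48, 0.60),
            "O": (-0.58, -2.98, 0.60),
        },
    },
    "TYR": {
        "site": "OH", "h_name": "HH", "h_bond": OH_BOND,
        "atoms": {
            "OH": (0.0, 0.0, 0.0),
            "CZ": (-1.38, 0.0, 0.0),
            "CE1": (-2.08, 1.20, 0.0),
            "CE2": (-2.08, -1.20, 0.0),
            "CB": (-4.50, 0.0, 0.0),
            "CA": (-5.30, -1.30, 0.0),
            "N": (-6.76, -1.30, 0.0),
            "C": (-4.75, -2.50, 0.75),
            "O": (-3.65, -3.00, 0.75),
        },
    },
    "LYS": {
        "site": "NZ", "h_name": "HZ1", "h_bond": NH_BOND,
        "atoms": {
            "NZ": (0.0, 0.0, 0.0),
            "CE": (-1.49, 0.0, 0.0),
            "CD": (-2.12, -1.20, 0.65),
            "CG": (-3.64, -1.20, 0.65),
            "CB": (-4.27, -2.40, 1.30),
            "CA": (-5.79, -2.40, 1.30),
            "N": (-6.43, -3.55, 0.70),
            "C": (-6.33, -1.10, 0.75),
            "O": (-5.75, -0.05, 0.95),
        },
    },
}

# ligand fragments: component id, acceptor atom, atoms relative to the
# acceptor at the origin (fragment body extends along +x, away from the
# donor), explicit bonds with CCD-style orders and formal charges
_LIGAND_FRAGMENTS: dict[str, dict] = {
    "alkyl_hydroxyl": {
        "comp_id": "LOH",
        "acceptor": "O1",
        "atoms": {"O1": ("O", (0.0, 0.0, 0.0)), "C1": ("C", (1.43, 0.0, 0.0)),
                  "C2": ("C", (2.13, 1.33, 0.0))},
        "bonds": [("O1", "C1", "SING"), ("C1", "C2", "SING")],
        "charges": {},
    },
    "carboxylate": {
        "comp_id": "LCX",
        "acceptor": "O1",
        "atoms": {"O1": ("O", (0.0, 0.0, 0.0)), "C1": ("C", (1.23, 0.0, 0.0)),
                  "O2": ("O", (1.88, 1.19, 0.0)), "C2": ("C", (2.03, -1.30, 0.0))},
        "bonds": [("O1", "C1", "DOUB"), ("C1", "O2", "SING"),
                  ("C1", "C2", "SING")],
        "charges": {"O2": -1},
    },
    "amide": {
        "comp_id": "LAM",
        "acceptor": "N1",
        "atoms": {"N1": ("N", (0.0, 0.0, 0.0)), "C1": ("C", (1.38, 0.0, 0.0)),
                  "O1": ("O", (1.93, 1.10, 0.0)), "C2": ("C", (2.18, -1.30, 0.0))},
        "bonds": [("N1", "C1", "SING"), ("C1", "O1", "DOUB"),
                  ("C1", "C2", "SING")],
        "charges": {},
    },
    "phenol": {
        "comp_id": "LPH",
        "acceptor": "O1",
        "atoms": {
            "O1": ("O", (0.0, 0.0, 0.0)),
            "C1": ("C", (1.37, 0.0, 0.0)),
            "C2": ("C", (2.065, 1.204, 0.0)),
            "C3": ("C", (3.455, 1.204, 0.0)),
            "C4": ("C", (4.15, 0.0, 0.0)),
            "C5": ("C", (3.455, -1.204, 0.0)),
            "C6": ("C", (2.065, -1.204, 0.0)),
        },
        "bonds": [("O1", "C1", "SING"), ("C1", "C2", "AROM"),
                  ("C2", "C3", "AROM"), ("C3", "C4", "AROM"),
                  ("C4", "C5", "AROM"), ("C5", "C6", "AROM"),
                  ("C6", "C1", "AROM")],
        "charges": {},
    },
    "phosphate": {
        "comp_id": "LPO",
        "acceptor": "O1",
        "atoms": {
            "O1": ("O", (0.0, 0.0, 0.0)),
            "P1": ("P", (1.55, 0.0, 0.0)),
            "O2": ("O", (2.03, 1.40, 0.0)),
            "O3": ("O", (2.07, -0.73, 1.26)),
            "O4": ("O", (2.07, -0.73, -1.26)),
        },
        "bonds": [("O1", "P1", "SING"), ("P1", "O2", "DOUB"),
                  ("P1", "O3", "SING"), ("P1", "O4", "SING")],
        "charges": {"O3": -1, "O4": -1},
    },
    "n_aromatic_heterocycle": {
        "comp_id": "LPY",
        "acceptor": "N1",
        "atoms": {
            "N1": ("N", (0.0, 0.0, 0.0)),
            "C2": ("C", (0.695, 1.204, 0.0)),
            "C3": ("C", (2.085, 1.204, 0.0)),
            "C4": ("C", (2.78, 0.0, 0.0)),
            "C5": ("C", (2.085, -1.204, 0.0)),
            "C6": ("C", (0.695, -1.204, 0.0)),
        },
        "bonds": [("N1", "C2", "AROM"), ("C2", "C3", "AROM"),
                  ("C3", "C4", "AROM"), ("C4", "C5", "AROM"),
                  ("C5", "C6", "AROM"), ("C6", "N1", "AROM")],
        "charges": {},
    },
}

_ALA_ATOMS = {
    "N": (0.0, 0.0, 0.0), "CA": (1.46, 0.0, 0.0), "C": (2.0, 1.42, 0.0),
    "O": (1.25, 2.39, 0.0), "CB": (2.0, -0.75, 1.2),
}


@dataclass(frozen=True)
class Plant:
    residue: str
    ligand_group: str
    R: float
    theta: float

    def __post_init__(self) -> None:
        if self.residue not in _RESIDUE_TEMPLATES:
            raise GenerationError(
                f"unsupported donor residue {self.residue}; "
                f"choose from {sorted(_RESIDUE_TEMPLATES)}"
            )
        if self.ligand_group not in _LIGAND_FRAGMENTS:
            raise GenerationError(
                f"unsupported ligand group {self.ligand_group}; "
                f"choose from {sorted(_LIGAND_FRAGMENTS)}"
            )
        if not (2.0 <= self.R <= 4.0):
            raise GenerationError(f"R={self.R} outside [2.0, 4.0]")
        if not (90.0 <= self.theta <= 180.0):
            raise GenerationError(f"theta={self.theta} outside [90, 180]")


@dataclass(frozen=True)
class PlantSpec:
    plants: tuple[Plant, ...]
    n_decoys: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.plants:
            raise GenerationError("at least one plant required")


@dataclass(frozen=True)
class PlantedBond:
    donor_residue: tuple[str, int, str]  # (chain, seq, atom name)
    acceptor_ligand: tuple[str, int, str]  # (component, seq, atom name)
    R: float
    theta: float
    expected_class: Optional[HBClass]

    @property
    def detectable(self) -> bool:
        return (R_MIN <= self.R <= R_MAX) and self.theta >= THETA_MIN


def make_toy_complex(spec: PlantSpec) -> tuple[Structure, list[PlantedBond]]:
    """Build a toy protein-ligand complex with exactly the planted geometry.

    Returns the structure (hydrogens included on planted donors) and the
    planted-bond records; ``PlantedBond.detectable`` marks plants that meet
    the three geometric criteria and must be recovered by detection.
    """
    rng = np.random.default_rng(spec.seed)
    serial = [0]

    def atom(name: str, element: str, pos, hetero: bool = False) -> Atom:
        serial[0] += 1
        return Atom(serial=serial[0], name=name, element=element,
                    coords=np.asarray(pos, dtype=float), is_hetero=hetero)

    chain: list[Residue] = []
    ligands: list[LigandInstance] = []
    planted: list[PlantedBond] = []
    seq = 0

    for k, plant in enumerate(spec.plants):
        base = np.array([_PLANT_SPACING * k, 0.0, 0.0])
        tmpl = _RESIDUE_TEMPLATES[plant.residue]
        seq += 1
        res = Residue(name=plant.residue, chain_id="A", seq_number=seq)
        for name, rel in tmpl["atoms"].items():
            el = name[0] if name[0] in ("N", "C", "O") else "C"
            res.atoms.append(atom(name, el, base + np.array(rel)))
        site_pos = base  # site atom at the local origin
        acceptor_pos = base + np.array([plant.R, 0.0, 0.0])
        h_pos = hydrogen_for_theta(site_pos, acceptor_pos, tmpl["h_bond"], plant.theta)
        res.atoms.append(atom(tmpl["h_name"], "H", h_pos))
        chain.append(res)

        frag = _LIGAND_FRAGMENTS[plant.ligand_group]
        lig = LigandInstance(component_id=frag["comp_id"], chain_id="L",
                             seq_number=100 + k)
        for name, (el, rel) in frag["atoms"].items():
            lig.atoms.append(atom(name, el, acceptor_pos + np.array(rel), True))
        ligands.append(lig)

        planted.append(
            PlantedBond(
                donor_residue=("A", seq, tmpl["site"]),
                acceptor_ligand=(frag["comp_id"], 100 + k, frag["acceptor"]),
                R=plant.R,
                theta=plant.theta,
                expected_class=(
                    classify_by_distance(plant.R)
                    if R_MIN <= plant.R <= R_MAX else None
                ),
            )
        )

    # decoy alanines on a shifted rail, >= 4 A from every planted site
    for d in range(spec.n_decoys):
        seq += 1
        base = np.array([
            _PLANT_SPACING * (d % max(len(spec.plants), 1)) + float(rng.uniform(-2, 2)),
            9.0 + 5.0 * (d // max(len(spec.plants), 1)),
            float(rng.uniform(-1, 1)),
        ])
        res = Residue(name="ALA", chain_id="A", seq_number=seq)
        for name, rel in _ALA_ATOMS.items():
            res.atoms.append(atom(name, name[0], base + np.array(rel)))
        chain.append(res)

    st = Structure(id=f"toy-{spec.seed}", chains=[chain], ligands=ligands,
                   resolution=1.0, has_hydrogens=True)
    return st, planted


def ccd_block_text(group: str) -> str:
    """Minimal Chemical Component Dictionary CIF block for a toy component."""
    frag = _LIGAND_FRAGMENTS[group]
    comp = frag["comp_id"]
    lines = [
        f"data_{comp}",
        "loop_",
        "_chem_comp_atom.comp_id",
        "_chem_comp_atom.atom_id",
        "_chem_comp_atom.type_symbol",
        "_chem_comp_atom.charge",
    ]
    for name, (el, _) in frag["atoms"].items():
        chg = frag["charges"].get(name, 0)
        lines.append(f"{comp} {name} {el} {chg}")
    lines += [
        "loop_",
        "_chem_comp_bond.comp_id",
        "_chem_comp_bond.atom_id_1",
        "_chem_comp_bond.atom_id_2",
        "_chem_comp_bond.value_order",
    ]
    for a1, a2, order in frag["bonds"]:
        lines.append(f"{comp} {a1} {a2} {order}")
    return "\n".join(lines) + "\n"


def write_toy_fixture(spec: PlantSpec, out_dir) -> dict[str, str]:
    """Write the PDB and per-component CCD CIF files; deterministic names."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    st, _ = make_toy_complex(spec)
    paths = {}
    pdb_path = out / f"toy_{spec.seed}.pdb"
    pdb_path.write_text(to_pdb_text(st))
    paths["pdb"] = str(pdb_path)
    for group in sorted({p.ligand_group for p in spec.plants}):
        comp = _LIGAND_FRAGMENTS[group]["comp_id"]
        cif_path = out / f"ccd_{comp}.cif"
        cif_path.write_text(ccd_block_text(group))
        paths[comp] = str(cif_path)
    return paths


def make_glycerol() -> tuple[LigandInstance, str]:
    """Glycerol instance with idealized 3D coordinates plus its CCD text.

    Used as the bond-perception cross-check: the distance-derived graph must
    match the dictionary-derived one.
    """
    coords = {
        "C1": (0.00, 0.00, 0.00), "O1": (0.60, 1.25, 0.00),
        "C2": (1.25, -0.86, 0.00), "O2": (2.35, -0.01, 0.30),
        "C3": (1.45, -2.06, 0.90), "O3": (2.75, -1.66, 1.20),
    }
    lig = LigandInstance(component_id="GOL", chain_id="L", seq_number=1)
    for k, (name, pos) in enumerate(coords.items(), start=1):
        lig.atoms.append(Atom(serial=k, name=name, element=name[0],
                              coords=np.array(pos), is_hetero=True))
    ccd = "\n".join(
        [
            "data_GOL",
            "loop_",
            "_chem_comp_atom.comp_id",
            "_chem_comp_atom.atom_id",
            "_chem_comp_atom.type_symbol",
            "_chem_comp_atom.charge",
        ]
        + [f"GOL {n} {n[0]} 0" for n in coords]
        + [
            "loop_",
            "_chem_comp_bond.comp_id",
            "_chem_comp_bond.atom_id_1",
            "_chem_comp_bond.atom_id_2",
            "_chem_comp_bond.value_order",
            "GOL C1 O1 SING",
            "GOL C1 C2 SING",
            "GOL C2 O2 SING",
            "GOL C2 C3 SING",
            "GOL C3 O3 SING",
        ]
    ) + "\n"
    return lig, ccd


# --- feature tables with planted signal ------------------------------------

A1 = ("TYR", "ASP", "GLU")
A2 = ("SER", "THR", "HIS")
A3 = ("ARG", "LYS", "ASN", "GLN", "TRP")
POLAR_AA = A1 + A2 + A3

L1 = ("phenol",)
L2 = ("alkyl_hydroxyl",)
L3 = ("sulfate", "phosphate", "carboxyl", "carboxylate")
L4 = ("ester", "amide", "alkyl_amine", "n_aromatic_heterocycle")
LIGAND_GROUPS = L1 + L2 + L3 + L4


def _spread(levels_weights: Sequence[tuple[Sequence[str], float]]) -> dict[str, float]:
    table: dict[str, float] = {}
    for levels, total in levels_weights:
        for lv in levels:
            table[lv] = total / len(levels)
    return table


# class-conditional residue distributions under full signal: SHB bonds favor
# type A1 residues, NHB bonds favor type A3
_AA_SHB = _spread([(A1, 0.85), (A2, 0.13), (A3, 0.02)])
_AA_NHB = _spread([(A1, 0.06), (A2, 0.24), (A3, 0.70)])
_GROUP_SHB = _spread([(L1, 0.25), (L2, 0.55), (L3, 0.17), (L4, 0.03)])
_GROUP_NHB = _spread([(L1, 0.015), (L2, 0.135), (L3, 0.30), (L4, 0.55)])

# chemistry-determined companions of the sampled categoricals
_AA_HETEROATOM = {"TYR": "O", "SER": "O", "THR": "O", "ASP": "O", "GLU": "O",
                  "HIS": "N", "ARG": "N", "LYS": "N", "ASN": "N", "GLN": "N",
                  "TRP": "N"}
_GROUP_CHARGE = {"sulfate": -1, "phosphate": -1, "carboxylate": -1}
_GROUP_PKA = {"carboxyl": 4.0, "carboxylate": 4.0, "phosphate": 2.0,
              "sulfate": -3.0, "phenol": 10.0}
_GROUP_PKB = {"alkyl_amine": 3.5, "n_aromatic_heterocycle": 9.0}
_GROUP_LOGP_MEAN = {"phenol": 1.5, "alkyl_hydroxyl": -0.5, "sulfate": -2.0,
                    "phosphate": -2.5, "carboxyl": 0.3, "carboxylate": -1.0,
                    "ester": 1.0, "amide": -0.7, "alkyl_amine": 0.2,
                    "n_aromatic_heterocycle": 1.2}


@dataclass(frozen=True)
class SignalSpec:
    """Conditions for a synthetic feature table.

    ``strength`` interpolates the class-conditional tables between uniform
    (0: no signal, Bayes AUC 0.5) and the full propensity-ordered tables (1).
    Default sizes keep the observed ~1:2.15 SHB:NHB imbalance.
    """

    n_shb: int = 1272
    n_nhb: int = 2733
    strength: float = 1.0
    seed: int = 0
    aa_shb: Optional[dict[str, float]] = None
    aa_nhb: Optional[dict[str, float]] = None
    group_shb: Optional[dict[str, float]] = None
    group_nhb: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.strength <= 1.0):
            raise GenerationError("strength must be in [0, 1]")
        if self.n_shb < 0 or self.n_nhb < 0 or self.n_shb + self.n_nhb == 0:
            raise GenerationError("need a positive number of rows")


def _mix(table: dict[str, float], levels: Sequence[str], s: float) -> np.ndarray:
    u = 1.0 / len(levels)
    p = np.array([s * table.get(lv, 0.0) + (1.0 - s) * u for lv in levels])
    return p / p.sum()


def make_feature_table(spec: SignalSpec) -> tuple[HBDataset, dict]:
    """Sample a labeled feature table with planted class-conditional signal.

    Returns the dataset and an info dict with the generating log-likelihood
    ratio (``llr`` callable on rows) and a Monte-Carlo estimate of the
    generator's achievable AUC (``bayes_auc``).
    """
    rng = np.random.default_rng(spec.seed)
    aa_shb = spec.aa_shb or _AA_SHB
    aa_nhb = spec.aa_nhb or _AA_NHB
    group_shb = spec.group_shb or _GROUP_SHB
    group_nhb = spec.group_nhb or _GROUP_NHB

    p_aa = {"SHB": _mix(aa_shb, POLAR_AA, spec.strength),
            "NHB": _mix(aa_nhb, POLAR_AA, spec.strength)}
    p_group = {"SHB": _mix(group_shb, LIGAND_GROUPS, spec.strength),
               "NHB": _mix(group_nhb, LIGAND_GROUPS, spec.strength)}

    labels = np.array(["SHB"] * spec.n_shb + ["NHB"] * spec.n_nhb)
    rng.shuffle(labels)

    rows = []
    for lab in labels:
        aa = str(rng.choice(POLAR_AA, p=p_aa[lab]))
        group = str(rng.choice(LIGAND_GROUPS, p=p_group[lab]))
        neighbors = [str(rng.choice(AA20)) for _ in range(6)]
        rows.append((
            HBFeatureVector(
                aa_charge=AA_CHARGE.get(aa, 0),
                aa_residue=aa,
                aa_heteroatom=_AA_HETEROATOM[aa],
                lig_charge=_GROUP_CHARGE.get(group, 0),
                lig_group=group,
                lig_pka=_GROUP_PKA.get(group, NON_IONIZABLE),
                lig_pkb=_GROUP_PKB.get(group, NON_IONIZABLE),
                lig_logp=float(_GROUP_LOGP_MEAN[group] + rng.normal(0.0, 0.5)),
                neighbor_m3=neighbors[0], neighbor_m2=neighbors[1],
                neighbor_m1=neighbors[2], neighbor_p1=neighbors[3],
                neighbor_p2=neighbors[4], neighbor_p3=neighbors[5],
            ),
            str(lab),
        ))
    dataset = HBDataset(rows=rows)

    aa_index = {a: i for i, a in enumerate(POLAR_AA)}
    group_index = {g: i for i, g in enumerate(LIGAND_GROUPS)}

    def llr(aa: str, group: str) -> float:
        return float(
            np.log(p_aa["SHB"][aa_index[aa]] / p_aa["NHB"][aa_index[aa]])
            + np.log(p_group["SHB"][group_index[group]]
                     / p_group["NHB"][group_index[group]])
        )

    # Monte-Carlo Bayes AUC of the generating rule (rank statistic with ties
    # counted half)
    m = 20000
    rng_mc = np.random.default_rng(spec.seed + 1)
    def sample_scores(lab: str) -> np.ndarray:
        aas = rng_mc.choice(len(POLAR_AA), size=m, p=p_aa[lab])
        gps = rng_mc.choice(len(LIGAND_GROUPS), size=m, p=p_group[lab])
        with np.errstate(divide="ignore"):  # zero-probability levels never drawn
            log_aa_s = np.log(p_aa["SHB"]); log_aa_n = np.log(p_aa["NHB"])
            log_g_s = np.log(p_group["SHB"]); log_g_n = np.log(p_group["NHB"])
        return (log_aa_s[aas] - log_aa_n[aas]) + (log_g_s[gps] - log_g_n[gps])
    s_pos = np.sort(sample_scores("SHB"))
    s_neg = np.sort(sample_scores("NHB"))
    greater = np.searchsorted(s_neg, s_pos, side="left").sum()
    geq = np.searchsorted(s_neg, s_pos, side="right").sum()
    bayes_auc = float((greater + geq) / 2.0 / (m * m))

    return dataset, {"llr": llr, "bayes_auc": bayes_auc}
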