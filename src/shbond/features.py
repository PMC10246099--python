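"""The 14-feature representation of a protein-ligand hydrogen bond.

Each bond is described by the amino-acid side (formal charge, residue type,
heteroatom element), the ligand side (group formal charge, functional group,
pKa, pKb, logP) and the protein sequence context (the three neighboring
residues on either side of the hydrogen-bonded one). Categorical features are
encoded against fixed, versioned vocabularies so that a trained model and a
dataset can be checked for compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .hbond import HBClass, HBKind, HydrogenBond
from .ligand_chem import FunctionalGroup, LigandDescriptors, MolecularGraph, \
    assign_functional_group, group_formal_charge
from .structure_io import Residue, Structure

VOCAB_VERSION = "1"

#: padding token for sequence neighbors beyond the chain termini
PAD = "—"

AA20 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
NEIGHBOR_VOCAB = AA20 + [PAD]
HETEROATOM_VOCAB = ["O", "N"]
GROUP_VOCAB = [g.value for g in FunctionalGroup]

FEATURE_NAMES = [
    "aa_charge", "aa_residue", "aa_heteroatom",
    "lig_charge", "lig_group", "lig_pka", "lig_pkb", "lig_logp",
    "neighbor_m3", "neighbor_m2", "neighbor_m1",
    "neighbor_p1", "neighbor_p2", "neighbor_p3",
]
NEIGHBOR_FEATURES = FEATURE_NAMES[8:]
CATEGORICAL_VOCABS = {
    "aa_residue": AA20,
    "aa_heteroatom": HETEROATOM_VOCAB,
    "lig_group": GROUP_VOCAB,
    **{f: NEIGHBOR_VOCAB for f in NEIGHBOR_FEATURES},
}
LABELS = ["NHB", "SHB"]

# side-chain formal charge at pH 7; His neutral in the default tautomer
AA_CHARGE = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}


class ContractViolation(ValueError):
    pass


class StratificationError(ValueError):
    pass


@dataclass
class HBFeatureVector:
    aa_charge: int
    aa_residue: str
    aa_heteroatom: str
    lig_charge: int
    lig_group: str
    lig_pka: float
    lig_pkb: float
    lig_logp: float
    neighbor_m3: str
    neighbor_m2: str
    neighbor_m1: str
    neighbor_p1: str
    neighbor_p2: str
    neighbor_p3: str

    def __post_init__(self) -> None:
        if isinstance(self.lig_group, FunctionalGroup):
            self.lig_group = self.lig_group.value
        for name, vocab in CATEGORICAL_VOCABS.items():
            v = getattr(self, name)
            if v not in vocab:
                raise ValueError(f"{name}={v!r} not in its vocabulary")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class HBDataset:
    rows: list[tuple[HBFeatureVector, str]]
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, label in self.rows:
            if label not in LABELS:
                raise ValueError(f"label {label!r} not in {LABELS}")
        if not self.provenance:
            self.provenance = [{} for _ in self.rows]

    def __len__(self) -> int:
        return len(self.rows)

    def labels(self) -> list[str]:
        return [lab for _, lab in self.rows]

    def count(self, label: str) -> int:
        return sum(1 for _, lab in self.rows if lab == label)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for (vec, label), prov in zip(self.rows, self.provenance):
            d = vec.as_dict()
            d["label"] = label
            for k, v in prov.items():
                d[f"prov_{k}"] = v
            recs.append(d)
        return pd.DataFrame.from_records(recs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HBDataset":
        missing = [c for c in FEATURE_NAMES + ["label"] if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {', '.join(missing)}")
        rows = []
        provenance = []
        prov_cols = [c for c in df.columns if c.startswith("prov_")]
        for _, r in df.iterrows():
            vec = HBFeatureVector(**{
                k: (int(r[k]) if k in ("aa_charge", "lig_charge")
                    else float(r[k]) if k in ("lig_pka", "lig_pkb", "lig_logp")
                    else str(r[k]))
                for k in FEATURE_NAMES
            })
            rows.append((vec, str(r["label"])))
            provenance.append({c[5:]: r[c] for c in prov_cols})
        return cls(rows=rows, provenance=provenance)

    def to_tsv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "HBDataset":
        df = pd.read_csv(path_or_buf, sep="\t")
        return cls.from_frame(df)


def _neighbor_name(chain: Sequence[Residue], pos: int) -> str:
    if 0 <= pos < len(chain):
        name = chain[pos].name
        return name if name in AA20 else PAD
    return PAD


def extract_features(
    bond: HydrogenBond,
    structure: Structure,
    descriptors: LigandDescriptors,
    ligand_graph: Optional[MolecularGraph] = None,
) -> HBFeatureVector:
    """Build the 14-feature vector for one protein-ligand hydrogen bond.

    The amino-acid side of the bond must be a side-chain site; sequence
    neighbors are read from the residue's chain at offsets -3..+3 with a
    padding token past the termini. Ligand group and group charge come from
    ``ligand_graph`` when given, else from the site annotation.
    """
    if bond.kind is not HBKind.PROTEIN_LIGAND:
        raise ContractViolation("feature extraction applies to protein-ligand bonds")
    protein_site = bond.donor if not bond.donor.is_ligand else bond.acceptor
    ligand_site = bond.acceptor if protein_site is bond.donor else bond.donor
    if protein_site.is_ligand or not ligand_site.is_ligand:
        raise ContractViolation("bond does not pair a protein site with a ligand site")
    res = protein_site.parent

    chain = None
    for c in structure.chains:
        if any(r is res for r in c):
            chain = c
            break
    if chain is None:
        for c in structure.chains:
            if any(r.key == res.key for r in c):
                chain = c
                break
    if chain is None:
        raise ContractViolation("bond residue not found in any chain")
    pos = next(i for i, r in enumerate(chain)
               if r is res or r.key == res.key)

    if ligand_graph is not None:
        g_atom = ligand_graph.atom_by_name(ligand_site.atom.name)
        lig_group = assign_functional_group(ligand_graph, g_atom.index).value
        lig_charge = group_formal_charge(ligand_graph, g_atom.index)
    else:
        lig_group = ligand_site.group_label
        lig_charge = ligand_site.group_formal_charge

    return HBFeatureVector(
        aa_charge=AA_CHARGE.get(res.name, 0),
        aa_residue=res.name,
        aa_heteroatom=protein_site.atom.element,
        lig_charge=lig_charge,
        lig_group=lig_group,
        lig_pka=descriptors.pka,
        lig_pkb=descriptors.pkb,
        lig_logp=descriptors.logp,
        neighbor_m3=_neighbor_name(chain, pos - 3),
        neighbor_m2=_neighbor_name(chain, pos - 2),
        neighbor_m1=_neighbor_name(chain, pos - 1),
        neighbor_p1=_neighbor_name(chain, pos + 1),
        neighbor_p2=_neighbor_name(chain, pos + 2),
        neighbor_p3=_neighbor_name(chain, pos + 3),
    )


def dataset_from_bonds(
    structure: Structure,
    bonds: Sequence[HydrogenBond],
    descriptors_by_ligand: dict,
    graphs_by_ligand: Optional[dict] = None,
) -> HBDataset:
    """Featurize the SHB/NHB protein-ligand bonds of one structure.

    INTERMEDIATE bonds (R in the unlabeled 2.7-2.8 A gap) are dropped, and
    duplicate (donor, acceptor) identities are kept once.
    """
    rows = []
    provenance = []
    seen = set()
    for b in bonds:
        if b.kind is not HBKind.PROTEIN_LIGAND:
            continue
        if b.hb_class is HBClass.INTERMEDIATE:
            continue
        ident = b.identity()
        if ident in seen:
            continue
        seen.add(ident)
        lig_site = b.donor if b.donor.is_ligand else b.acceptor
        lig_key = lig_site.parent.key
        desc = descriptors_by_ligand[lig_key]
        graph = (graphs_by_ligand or {}).get(lig_key)
        vec = extract_features(b, structure, desc, ligand_graph=graph)
        rows.append((vec, b.hb_class.value))
        provenance.append({
            "structure": structure.id,
            "donor": repr(b.donor),
            "acceptor": repr(b.acceptor),
            "R": round(b.R, 4),
        })
    return HBDataset(rows=rows, provenance=provenance)


def split_dataset(
    data: HBDataset, test_fraction: float = 0.2, seed: int = 0
) -> tuple[HBDataset, HBDataset]:
    """Stratified, reproducible train/test split of a labeled dataset."""
    labels = data.labels()
    for lab in LABELS:
        if labels.count(lab) < 2:
            raise StratificationError(f"need at least 2 rows of class {lab}")
    idx = np.arange(len(data))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=labels
    )
    def subset(indices) -> HBDataset:
        return HBDataset(
            rows=[data.rows[i] for i in indices],
            provenance=[data.provenance[i] for i in indices],
        )
    return subset(sorted(train_idx)), subset(sorted(test_idx))


def encode_frame(df: pd.DataFrame) -> np.ndarray:
    """Encode the 14 feature columns as a float matrix for tree learners.

    Categorical columns become ordinal codes in their fixed vocabulary order
    (trees split natively on levels; the order is stable and versioned).
    """
    cols = []
    for name in FEATURE_NAMES:
        if name in CATEGORICAL_VOCABS:
            vocab = CATEGORICAL_VOCABS[name]
            codes = pd.Categorical(df[name], categories=vocab).codes.astype(float)
            if (codes < 0).any():
                bad = sorted(set(df[name]) - set(vocab))
                raise ValueError(f"{name}: levels outside vocabulary: {bad}")
            cols.append(codes)
        else:
            cols.append(df[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def encode_dataset(data: HBDataset) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) encoding; y is 1 for SHB, 0 for NHB."""
    df = data.to_frame()
    X = encode_frame(df)
    y = (df["label"] == "SHB").to_numpy(dtype=int)
    return X, y
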