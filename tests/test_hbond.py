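import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shbond.geometry import angle_deg, distance
from shbond.hbond import (
    HBClass,
    HBKind,
    R_MAX,
    R_MIN,
    THETA_MIN,
    bonds_to_tsv,
    classify_by_distance,
    detect_hbonds,
    enumerate_sites,
    measure_pair,
    SelectionError,
)
from shbond.structure_io import LigandInstance, Residue, Structure, parse_structure, to_pdb_text
from shbond.synthetic import Plant, PlantSpec, make_toy_complex

from conftest import make_atom


def brute_force_hbonds(sites):
    """Independent O(n^2) all-pairs oracle over enumerated sites."""
    found = set()
    for a, b in itertools.combinations(sites, 2):
        if a.parent_key() == b.parent_key():
            continue
        if a.is_ligand and b.is_ligand:
            continue
        r = distance(a.atom.coords, b.atom.coords)
        if not (R_MIN <= r <= R_MAX):
            continue
        ok = False
        for donor, acceptor in ((a, b), (b, a)):
            if not (donor.can_donate and acceptor.can_accept):
                continue
            for h in donor.attached_hydrogens:
                if angle_deg(donor.atom.coords, h.coords, acceptor.atom.coords) >= THETA_MIN:
                    ok = True
        if ok:
            found.add(frozenset([(a.parent_key(), a.atom.name),
                                 (b.parent_key(), b.atom.name)]))
    return found


class TestEnumerateSites:
    def test_gly_only_chain_has_no_sites(self):
        gly = Residue("GLY", "A", 1, atoms=[
            make_atom("N", "N", (0, 0, 0), 1),
            make_atom("CA", "C", (1.46, 0, 0), 2),
            make_atom("C", "C", (2, 1.4, 0), 3),
            make_atom("O", "O", (1.2, 2.4, 0), 4),
        ])
        assert enumerate_sites(Structure("t", chains=[[gly]])) == []

    def test_asp_gives_two_acceptor_only_sites(self):
        asp = Residue("ASP", "A", 1, atoms=[
            make_atom("CG", "C", (0, 0, 0), 1),
            make_atom("OD1", "O", (0.6, 1.1, 0), 2),
            make_atom("OD2", "O", (0.6, -1.1, 0), 3),
        ])
        sites = enumerate_sites(Structure("t", chains=[[asp]]))
        assert sorted(s.atom.name for s in sites) == ["OD1", "OD2"]
        assert all(s.can_accept and not s.can_donate for s in sites)
        assert all(s.group_formal_charge == -1 for s in sites)

    def test_ligand_hydroxyl_donates_and_accepts(self):
        lig = LigandInstance("LOH", atoms=[
            make_atom("O1", "O", (0, 0, 0), 1, True),
            make_atom("C1", "C", (1.43, 0, 0), 2, True),
            make_atom("HO1", "H", (-0.32, -0.9, 0), 3, True),
        ], chain_id="L", seq_number=1)
        sites = enumerate_sites(Structure("t", ligands=[lig]))
        assert len(sites) == 1
        assert sites[0].can_donate and sites[0].can_accept

    def test_backbone_excluded(self, minimal_pdb_text):
        stx = parse_structure(minimal_pdb_text, "pdb")
        names = [s.atom.name for s in enumerate_sites(stx) if not s.is_ligand]
        assert names == ["OG"]  # Ser side chain only, no backbone N/O


class TestDetection:
    def test_planted_collinear_pair_detected(self):
        stx, planted = make_toy_complex(
            PlantSpec(plants=(Plant("SER", "alkyl_hydroxyl", 2.60, 180.0),), seed=0)
        )
        bonds = detect_hbonds(stx)
        assert len(bonds) == 1
        b = bonds[0]
        assert b.R == pytest.approx(2.60, abs=1e-6)
        assert b.kind is HBKind.PROTEIN_LIGAND
        assert b.hb_class is HBClass.SHB
        assert not b.donor.is_ligand

    def test_low_angle_rejected(self):
        stx, _ = make_toy_complex(
            PlantSpec(plants=(Plant("SER", "alkyl_hydroxyl", 2.60, 90.0),), seed=0)
        )
        assert detect_hbonds(stx) == []

    def test_distance_window(self, five_plant_complex):
        stx, planted = five_plant_complex
        bonds = detect_hbonds(stx)
        assert len(bonds) == 4  # the 3.4 A plant is outside the window
        detected_r = sorted(round(b.R, 2) for b in bonds)
        assert detected_r == [2.4, 2.5, 2.6, 3.0]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        plants = tuple(
            Plant(
                str(rng.choice(["SER", "THR", "TYR", "LYS"])),
                str(rng.choice(["alkyl_hydroxyl", "carboxylate", "amide",
                                "phenol", "phosphate", "n_aromatic_heterocycle"])),
                float(rng.uniform(2.2, 3.6)),
                float(rng.uniform(100.0, 180.0)),
            )
            for _ in range(6)
        )
        stx, _ = make_toy_complex(PlantSpec(plants=plants, n_decoys=4, seed=seed))
        sites = enumerate_sites(stx)
        expected = brute_force_hbonds(sites)
        got = {
            frozenset([(b.donor.parent_key(), b.donor.atom.name),
                       (b.acceptor.parent_key(), b.acceptor.atom.name)])
            for b in detect_hbonds(stx, sites=sites)
        }
        assert got == expected

    def test_every_bond_satisfies_criteria(self, five_plant_complex):
        stx, _ = five_plant_complex
        for b in detect_hbonds(stx):
            assert R_MIN <= b.R <= R_MAX
            assert b.theta >= THETA_MIN
            assert b.donor.atom.element in ("O", "N")
            assert b.acceptor.atom.element in ("O", "N")
            assert b.donor.parent_key() != b.acceptor.parent_key()

    def test_tsv_export_row_count(self, five_plant_complex):
        stx, _ = five_plant_complex
        bonds = detect_hbonds(stx)
        text = bonds_to_tsv(stx.id, bonds)
        lines = text.strip().splitlines()
        assert len(lines) == len(bonds) + 1
        assert lines[0].startswith("structure_id\t")


class TestClassification:
    @pytest.mark.parametrize(
        "r,expected",
        [
            (2.56, HBClass.SHB),
            (3.00, HBClass.NHB),
            (2.75, HBClass.INTERMEDIATE),
            (2.70, HBClass.SHB),
            (2.80, HBClass.NHB),
            (2.30, HBClass.SHB),
            (3.20, HBClass.NHB),
        ],
    )
    def test_distance_windows(self, r, expected):
        assert classify_by_distance(r) is expected

    @pytest.mark.parametrize("r", [2.29, 3.21, 0.0, 5.0])
    def test_outside_window_raises(self, r):
        with pytest.raises(ValueError):
            classify_by_distance(r)

    @settings(derandomize=True, max_examples=100)
    @given(
        r1=st.floats(min_value=2.3, max_value=3.2),
        r2=st.floats(min_value=2.3, max_value=3.2),
    )
    def test_monotone_no_nhb_shorter_than_shb(self, r1, r2):
        c1, c2 = classify_by_distance(r1), classify_by_distance(r2)
        if c1 is HBClass.SHB and c2 is HBClass.NHB:
            assert r1 < r2


class TestMeasurePair:
    def test_hand_geometry(self):
        ser = Residue("SER", "A", 10, atoms=[make_atom("OG", "O", (0, 0, 0), 1)])
        lig = LigandInstance("XYZ", atoms=[make_atom("O1", "O", (2.7, 0, 0), 2, True)],
                             chain_id="L", seq_number=1)
        stx = Structure("t", chains=[[ser]], ligands=[lig])
        r, theta = measure_pair(stx, ("A", 10, "OG"), ("XYZ", "O1"))
        assert r == pytest.approx(2.70)
        assert theta == 0.0  # no hydrogens anywhere

    def test_planted_measurement_recovers_geometry(self):
        stx, planted = make_toy_complex(
            PlantSpec(plants=(Plant("TYR", "phenol", 2.56, 165.0),), seed=3)
        )
        chain, seq, atom = planted[0].donor_residue
        comp, _, lig_atom = planted[0].acceptor_ligand
        r, theta = measure_pair(stx, (chain, seq, atom), (comp, lig_atom))
        assert r == pytest.approx(2.56, abs=1e-6)
        assert theta == pytest.approx(165.0, abs=0.1)

    def test_empty_selection_raises(self):
        stx = Structure("t")
        with pytest.raises(SelectionError):
            measure_pair(stx, ("A", 1, "OG"), ("XYZ", "O1"))
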