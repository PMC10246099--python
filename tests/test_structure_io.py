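import itertools

import gemmi
import numpy as np
import pytest

from shbond.structure_io import (
    DEFAULT_EXCLUDED_COMPONENTS,
    Atom,
    LigandInstance,
    Residue,
    Structure,
    UsageError,
    exclude_crystallization_ligands,
    parse_structure,
    passes_resolution_filter,
    place_polar_hydrogens,
    to_pdb_text,
)
from shbond.geometry import angle_deg, distance
from shbond.synthetic import make_toy_complex

from conftest import make_atom


class TestParsing:
    def test_minimal_pdb(self, minimal_pdb_text):
        st = parse_structure(minimal_pdb_text, "pdb")
        assert len(st.chains) == 1
        assert [r.name for r in st.chains[0]] == ["GLY", "ALA", "SER"]
        assert [lig.component_id for lig in st.ligands] == ["MLA"]
        assert st.resolution == pytest.approx(1.05)
        assert not st.has_hydrogens

    def test_mmcif_equivalence(self, minimal_pdb_text):
        """The same model read from PDB and mmCIF yields identical fields."""
        st_pdb = parse_structure(minimal_pdb_text, "pdb")
        gst = gemmi.read_pdb_string(minimal_pdb_text)
        gst.setup_entities()
        cif_text = gst.make_mmcif_document().as_string()
        st_cif = parse_structure(cif_text, "mmcif")
        assert len(st_cif.chains) == len(st_pdb.chains)
        for ca, cb in zip(st_pdb.chains, st_cif.chains):
            assert [r.name for r in ca] == [r.name for r in cb]
            for ra, rb in zip(ca, cb):
                assert [a.name for a in ra.atoms] == [a.name for a in rb.atoms]
                for aa, ab in zip(ra.atoms, rb.atoms):
                    assert np.allclose(aa.coords, ab.coords, atol=1e-3)
        assert [l.component_id for l in st_cif.ligands] == ["MLA"]

    def test_waters_only_yield_no_ligands(self, waters_only_pdb_text):
        st = parse_structure(waters_only_pdb_text, "pdb")
        assert st.ligands == []

    def test_unknown_format_rejected(self, minimal_pdb_text):
        with pytest.raises(UsageError):
            parse_structure(minimal_pdb_text, "xyz")

    def test_roundtrip_serialization(self, five_plant_complex):
        """parse(serialize(parse(text))) preserves all structure fields."""
        st, _ = five_plant_complex
        text = to_pdb_text(st)
        st1 = parse_structure(text, "pdb")
        st2 = parse_structure(to_pdb_text(st1), "pdb")
        assert st1.resolution == st2.resolution
        assert len(st1.chains) == len(st2.chains)
        for ca, cb in zip(st1.chains, st2.chains):
            for ra, rb in zip(ca, cb):
                assert (ra.name, ra.seq_number) == (rb.name, rb.seq_number)
                assert [a.name for a in ra.atoms] == [a.name for a in rb.atoms]
                for aa, ab in zip(ra.atoms, rb.atoms):
                    assert np.allclose(aa.coords, ab.coords)
        for la, lb in zip(st1.ligands, st2.ligands):
            assert la.component_id == lb.component_id
            assert [a.name for a in la.atoms] == [a.name for a in lb.atoms]

    def test_altloc_resolution_keeps_best_conformer(self):
        text = (
            "ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  SER A   1       1.460   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CB ASER A   1       2.000   1.400   0.000  0.40  0.00           C\n"
            "ATOM      4  CB BSER A   1       2.000  -1.400   0.000  0.60  0.00           C\n"
            "ATOM      5  OG ASER A   1       3.400   1.400   0.000  0.40  0.00           O\n"
            "ATOM      6  OG BSER A   1       3.400  -1.400   0.000  0.60  0.00           O\n"
            "END\n"
        )
        st = parse_structure(text, "pdb")
        res = st.chains[0][0]
        # one conformer only, never a mixture
        assert sorted(a.name for a in res.atoms) == ["CA", "CB", "N", "OG"]
        assert res.atom("CB").altloc == "B"
        assert res.atom("OG").altloc == "B"

    def test_altloc_tie_prefers_alphabetical(self):
        text = (
            "ATOM      1  CB ASER A   1       2.000   1.400   0.000  0.50  0.00           C\n"
            "ATOM      2  CB BSER A   1       2.000  -1.400   0.000  0.50  0.00           C\n"
            "END\n"
        )
        st = parse_structure(text, "pdb")
        assert st.chains[0][0].atom("CB").altloc == "A"


class TestResolutionFilter:
    @pytest.mark.parametrize(
        "resolution,expected",
        [(1.05, True), (1.10, True), (1.50, False), (None, False)],
    )
    def test_cutoff(self, resolution, expected):
        st = Structure(id="x", resolution=resolution)
        assert passes_resolution_filter(st) is expected


class TestLigandExclusion:
    def _ligs(self, *component_ids, n_atoms=3):
        out = []
        for cid in component_ids:
            atoms = [make_atom(f"X{i}", "C", (i, 0, 0), serial=i + 1, hetero=True)
                     for i in range(n_atoms)]
            out.append(LigandInstance(component_id=cid, atoms=atoms))
        return out

    def test_polyol_excluded(self):
        kept = exclude_crystallization_ligands(self._ligs("GOL", "NAD"))
        assert [l.component_id for l in kept] == ["NAD"]

    def test_inorganic_anions_excluded(self):
        assert exclude_crystallization_ligands(self._ligs("SO4", "PO4")) == []

    def test_single_atom_ions_excluded(self):
        kept = exclude_crystallization_ligands(self._ligs("NA", n_atoms=1))
        assert kept == []

    def test_empty_exclusion_list_is_identity(self):
        ligs = self._ligs("GOL", "SO4", "NAD")
        assert exclude_crystallization_ligands(ligs, set()) == ligs


class TestHydrogenPlacement:
    def test_ser_hydroxyl_points_at_acceptor(self):
        """A rotatable Ser O-H orients toward a nearby carboxylate oxygen."""
        ser = Residue("SER", "A", 1, atoms=[
            make_atom("OG", "O", (0, 0, 0), 1),
            make_atom("CB", "C", (-1.41, 0, 0), 2),
            make_atom("CA", "C", (-2.2, -1.3, 0), 3),
        ])
        lig = LigandInstance("LCX", atoms=[
            make_atom("O1", "O", (0.9, 2.55, 0), 4, True),
            make_atom("C1", "C", (2.13, 2.55, 0), 5, True),
            make_atom("O2", "O", (2.8, 3.7, 0), 6, True),
        ], chain_id="L", seq_number=1)
        st = place_polar_hydrogens(Structure("t", chains=[[ser]], ligands=[lig]))
        res = st.chains[0][0]
        hg = res.atom("HG")
        assert hg is not None
        assert distance(res.atom("OG").coords, hg.coords) == pytest.approx(0.96)
        theta = angle_deg(res.atom("OG").coords, hg.coords, lig.atom("O1").coords)
        assert theta >= 135.0

    def test_lys_ammonium_gets_three_hydrogens(self):
        lys = Residue("LYS", "A", 1, atoms=[
            make_atom("NZ", "N", (0, 0, 0), 1),
            make_atom("CE", "C", (-1.49, 0, 0), 2),
        ])
        st = place_polar_hydrogens(Structure("t", chains=[[lys]]))
        hs = [a for a in st.chains[0][0].atoms if a.element == "H"]
        assert len(hs) == 3
        for h in hs:
            assert distance(h.coords, st.chains[0][0].atom("NZ").coords) == pytest.approx(1.01)

    def test_existing_hydrogens_untouched(self):
        tyr = Residue("TYR", "A", 1, atoms=[
            make_atom("OH", "O", (0, 0, 0), 1),
            make_atom("CZ", "C", (-1.38, 0, 0), 2),
            make_atom("HH", "H", (0.3, 0.9, 0), 3),
        ])
        st = place_polar_hydrogens(Structure("t", chains=[[tyr]]))
        res = st.chains[0][0]
        assert sum(1 for a in res.atoms if a.element == "H") == 1
        assert np.allclose(res.atom("HH").coords, (0.3, 0.9, 0))

    def test_missing_heavy_atoms_skipped(self, caplog):
        ser = Residue("SER", "A", 1, atoms=[make_atom("OG", "O", (0, 0, 0), 1)])
        st = place_polar_hydrogens(Structure("t", chains=[[ser]]))
        assert sum(1 for a in st.chains[0][0].atoms if a.element == "H") == 0

    def test_no_clashes_after_placement(self, five_plant_complex):
        st, _ = five_plant_complex
        placed = place_polar_hydrogens(st)
        coords = [a.coords for a in placed.all_atoms()]
        min_d = min(distance(a, b) for a, b in itertools.combinations(coords, 2))
        assert min_d > 0.5

    def test_input_structure_not_mutated(self):
        ser = Residue("SER", "A", 1, atoms=[
            make_atom("OG", "O", (0, 0, 0), 1),
            make_atom("CB", "C", (-1.41, 0, 0), 2),
        ])
        st = Structure("t", chains=[[ser]])
        place_polar_hydrogens(st)
        assert sum(1 for a in st.chains[0][0].atoms if a.element == "H") == 0
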