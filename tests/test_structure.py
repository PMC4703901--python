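import math

import numpy as np
import pytest

from halodesign import fixtures as fx
from halodesign.structure import (
    Atom,
    AtomTypingError,
    Residue,
    Structure,
    StructureError,
    classify_surface,
    read_structure,
    relative_sasa,
    residue_sasa,
    shrake_rupley,
)

R_C = 1.7  # Bondi carbon
PROBE = 1.4
R_EXP = R_C + PROBE


def carbon_structure(*coords):
    residues = []
    for i, c in enumerate(coords, start=1):
        res = Residue("A", i, "", "GLY")
        res.atoms.append(Atom("C", "C", np.asarray(c, dtype=float)))
        residues.append(res)
    return Structure(residues)


class TestShrakeRupley:
    def test_isolated_atom_matches_sphere_area(self):
        sasa = shrake_rupley(carbon_structure((0, 0, 0)))
        assert sasa[0] == pytest.approx(4 * math.pi * R_EXP**2, rel=0.01)

    def test_distant_atoms_unoccluded(self):
        sasa = shrake_rupley(carbon_structure((0, 0, 0), (100, 0, 0)))
        assert np.allclose(sasa, 4 * math.pi * R_EXP**2, rtol=0.01)

    @pytest.mark.parametrize("d", [1.0, 2.0, 3.0, 4.0, 5.0])
    def test_two_sphere_analytic_cap_formula(self, d):
        # equal spheres radius R at distance d < 2R each lose a cap 2*pi*R*h,
        # h = R - d/2
        sasa = shrake_rupley(carbon_structure((0, 0, 0), (d, 0, 0)))
        h = R_EXP - d / 2
        analytic = 2 * (4 * math.pi * R_EXP**2 - 2 * math.pi * R_EXP * h)
        assert sasa.sum() == pytest.approx(analytic, rel=0.01)

    def test_coarse_quadrature_refused(self):
        with pytest.raises(ValueError, match="n_points"):
            shrake_rupley(carbon_structure((0, 0, 0)), n_points=16)

    def test_quadrature_convergence(self, simple_peptide):
        total = shrake_rupley(simple_peptide, n_points=960).sum()
        total2 = shrake_rupley(simple_peptide, n_points=1920).sum()
        assert abs(total2 - total) / total < 0.005

    def test_occluder_never_increases_sasa(self, simple_peptide):
        before = shrake_rupley(simple_peptide)
        extra = Residue("A", 99, "", "GLY")
        # occluder next to the first CA
        extra.atoms.append(Atom("C", "C", simple_peptide.residues[0].atom("CA").coord + 2.0))
        occluded = Structure(simple_peptide.residues + [extra])
        after = shrake_rupley(occluded)[: len(before)]
        assert (after <= before + 1e-9).all()

    def test_residue_totals_partition_atom_sasa(self, simple_peptide):
        per_atom = shrake_rupley(simple_peptide)
        totals = residue_sasa(simple_peptide, per_atom)
        assert sum(totals) == pytest.approx(per_atom.sum(), abs=1e-9)
        assert len(totals) == len(simple_peptide.residues)

    def test_against_independent_implementation(self, simple_peptide):
        """Cross-check whole-structure SASA against Biopython's Shrake-Rupley."""
        from Bio.PDB.SASA import ShrakeRupley as BioSR
        from Bio.PDB import PDBParser

        path = "cross_check.pdb"
        import tempfile, os

        with tempfile.TemporaryDirectory() as tmp:
            path = os.path.join(tmp, "p.pdb")
            fx.write_pdb(simple_peptide, path)
            bio = PDBParser(QUIET=True).get_structure("s", path)
            BioSR(probe_radius=1.4, n_points=960).compute(bio, level="S")
            ours = shrake_rupley(simple_peptide).sum()
            # different radii tables (Bondi vs Biopython defaults): few-percent window
            assert ours == pytest.approx(bio.sasa, rel=0.05)


class TestPdbReading:
    def test_single_atom_file(self, tmp_path):
        pdb = tmp_path / "one.pdb"
        pdb.write_text(
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\nEND\n"
        )
        structure = read_structure(pdb)
        assert len(structure.atoms) == 1

    def test_altloc_highest_occupancy_retained(self, tmp_path):
        pdb = tmp_path / "alt.pdb"
        pdb.write_text(
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      2  CA BGLY A   1       5.000   0.000   0.000  0.40  0.00           C\n"
            "END\n"
        )
        structure = read_structure(pdb)
        assert len(structure.atoms) == 1
        assert structure.atoms[0].coord[0] == pytest.approx(0.0)

    def test_model_index_selects_block(self, tmp_path):
        pdb = tmp_path / "two.pdb"
        pdb.write_text(
            "MODEL        1\n"
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  GLY A   1       7.500   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
        )
        assert read_structure(pdb, model_index=1).atoms[0].coord[0] == pytest.approx(7.5)
        assert read_structure(pdb, model_index=0).atoms[0].coord[0] == pytest.approx(0.0)

    def test_empty_structure_rejected(self, tmp_path):
        pdb = tmp_path / "empty.pdb"
        pdb.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(StructureError):
            read_structure(pdb)

    def test_heteroatoms_dropped(self, tmp_path):
        pdb = tmp_path / "het.pdb"
        pdb.write_text(
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  O   HOH A 101       3.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        assert len(read_structure(pdb, drop_heteroatoms=True).atoms) == 1
        assert len(read_structure(pdb, drop_heteroatoms=False).atoms) == 2

    def test_unknown_element_names_atom(self, tmp_path):
        pdb = tmp_path / "bad.pdb"
        pdb.write_text(
            "ATOM      1 XX   GLY A   1       0.000   0.000   0.000  1.00  0.00          XX\n"
            "END\n"
        )
        with pytest.raises(AtomTypingError, match="XX"):
            read_structure(pdb)

    def test_fixture_pdb_round_trip(self, tmp_path, bridged_peptide):
        path = tmp_path / "fixture.pdb"
        fx.write_pdb(bridged_peptide, path)
        reread = read_structure(path)
        assert len(reread.atoms) == len(bridged_peptide.atoms)
        np.testing.assert_allclose(
            reread.coordinates(), bridged_peptide.coordinates(), atol=1e-3
        )


class TestSurfaceClassification:
    def test_zero_sasa_gives_zero_relative(self):
        assert relative_sasa(0.0, "GLY") == 0.0

    def test_nonstandard_residue_excluded(self):
        assert relative_sasa(50.0, "XYZ") is None

    def test_extended_gly_tripeptide_near_max(self):
        pep = fx.make_peptide(3, residue_names={1: "GLY", 2: "GLY", 3: "GLY"})
        records = classify_surface(pep)
        central = records[1]
        # fully extended: the central residue should be close to its
        # theoretical maximum accessibility (heavy-atom idealised geometry)
        assert 0.7 <= central.relative_sasa <= 1.2
        assert central.is_surface

    def test_all_exposed_toy_peptide_is_all_surface(self, simple_peptide):
        assert all(r.is_surface for r in classify_surface(simple_peptide))

    def test_threshold_above_max_empties_set(self, simple_peptide):
        # terminal residues of a toy peptide can slightly exceed the
        # tabulated maxima; 1.4 is above anything geometrically reachable
        records = classify_surface(simple_peptide, threshold=1.4)
        assert not any(r.is_surface for r in records)

    def test_buried_center_excluded(self):
        cluster = fx.make_buried_cluster()
        records = classify_surface(cluster)
        center = next(r for r in records if r.number == 1)
        assert center.relative_sasa < 0.25 and not center.is_surface
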