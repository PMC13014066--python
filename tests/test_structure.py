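"""Structure I/O, residue pairing and rigid superposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import loxpharm as lp
from loxpharm.errors import (
    ChainNotFoundError, DegenerateFitError, EmptyInputError,
)
from loxpharm.structure import AtomRecord, StructureModel
from loxpharm.synth import make_gapped_pair, make_toy_protein

from conftest import rigid_motion, transform_model


def _atom(serial, name, resseq, xyz, chain="A", resname="ALA", icode="",
          altloc="", element=None, het=False):
    return AtomRecord(serial, name, element or name[0], altloc, resname,
                      chain, resseq, icode, np.asarray(xyz, float), 1.0, het)


class TestPdbIO:
    def test_round_trip_preserves_atom_table(self, helix20, tmp_path):
        path = tmp_path / "m.pdb"
        lp.write_pdb(helix20, str(path))
        back = lp.read_pdb(str(path))[0]
        assert len(back.atoms) == len(helix20.atoms)
        for a, b in zip(helix20.atoms, back.atoms):
            assert (a.name, a.resname, a.chain_id, a.resseq, a.icode,
                    a.is_het) == (b.name, b.resname, b.chain_id, b.resseq,
                                  b.icode, b.is_het)
            assert np.allclose(a.xyz, b.xyz, atol=1.1e-3)

    def test_round_trip_insertion_codes_and_het(self, tmp_path):
        atoms = [
            _atom(1, "N", 5, (0, 0, 0)), _atom(2, "CA", 5, (1.4, 0, 0), element="C"),
            _atom(3, "C", 5, (2, 1, 0)),
            _atom(4, "N", 5, (3, 1, 0), icode="A"),
            _atom(5, "CA", 5, (4, 1, 0), icode="A", element="C"),
            _atom(6, "C", 5, (5, 2, 0), icode="A"),
            _atom(7, "FE", 90, (9, 9, 9), resname="FE", element="FE", het=True),
        ]
        model = StructureModel(1, atoms)
        path = tmp_path / "ic.pdb"
        lp.write_pdb(model, str(path))
        back = lp.read_pdb(str(path))[0]
        assert [a.icode for a in back.atoms] == ["", "", "", "A", "A", "A", ""]
        assert back.atoms[-1].is_het

    def test_multi_model_io(self, tmp_path):
        models = [make_toy_protein(6, "helix", seed=s) for s in range(5)]
        for i, m in enumerate(models):
            m.model_id = i + 1
        path = tmp_path / "traj.pdb"
        lp.write_pdb(models, str(path))
        back = lp.read_pdb(str(path))
        assert len(back) == 5
        single = lp.read_pdb(str(path), model_select=3)
        assert len(single) == 1 and single[0].model_id == 3

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(EmptyInputError):
            lp.read_pdb(str(path))

    def test_three_residue_handwritten_pdb(self, tmp_path):
        text = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C\n"
            "ATOM      4  N   ALA A   2       3.300   1.650   0.000  1.00  0.00           N\n"
            "ATOM      5  CA  ALA A   2       4.200   2.700   0.000  1.00  0.00           C\n"
            "ATOM      6  C   ALA A   2       5.600   2.200   0.000  1.00  0.00           C\n"
            "ATOM      7  N   ALA A   3       6.700   3.000   0.000  1.00  0.00           N\n"
            "ATOM      8  CA  ALA A   3       8.100   2.600   0.000  1.00  0.00           C\n"
            "ATOM      9  C   ALA A   3       9.000   3.800   0.000  1.00  0.00           C\n"
            "END\n")
        path = tmp_path / "three.pdb"
        path.write_text(text)
        models = lp.read_pdb(str(path))
        assert len(models) == 1
        assert len(models[0].residues()) == 3

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        text = (
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40  0.00           N\n"
            "ATOM      2  N  BALA A   1       5.000   0.000   0.000  0.60  0.00           N\n"
            "END\n")
        path = tmp_path / "alt.pdb"
        path.write_text(text)
        model = lp.read_pdb(str(path))[0]
        assert len(model.atoms) == 1
        assert model.atoms[0].xyz[0] == pytest.approx(5.0, abs=1e-3)


class TestChainsAndPairing:
    def test_extract_chain(self, helix20):
        two = StructureModel(1, [a.copy() for a in helix20.atoms])
        extra = make_toy_protein(10, "helix", chain_id="B")
        two.atoms += [a.copy() for a in extra.atoms]
        only_b = lp.extract_chain(two, "B")
        assert only_b.chains() == ["B"]
        with pytest.raises(ChainNotFoundError):
            lp.extract_chain(two, "Z")

    def test_extract_chain_het_flag(self, planted_all):
        model, _truth = planted_all
        lig = lp.extract_chain(model, "L", keep_het=True)
        assert any(a.is_het for a in lig.atoms)
        assert not lp.extract_chain(model, "L", keep_het=False).atoms

    def test_identical_sequences_pair_in_order(self, helix20):
        pairs = lp.pair_residues(helix20, helix20)
        assert len(pairs) == 20
        assert all(a == b for a, b in pairs)

    def test_deletion_skips_gap(self):
        # hand-alignment oracle: removing 4 residues pairs everything else;
        # a varied sequence anchors the alignment unambiguously
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVK"
        varied = make_toy_protein(60, "helix", sequence=seq)
        acc, _donor, _truth = make_gapped_pair(varied, [(30, 33)])
        pairs = lp.pair_residues(acc, varied)
        assert len(pairs) == 56
        paired_target = {b[1] for _a, b in pairs}
        assert paired_target == set(range(1, 61)) - {30, 31, 32, 33}
        assert all(a[1] == b[1] for a, b in pairs)

    def test_no_overlap_warns_and_returns_empty(self):
        a = make_toy_protein(6, "helix", sequence="AAAAAA")
        b = make_toy_protein(6, "helix", sequence="WWWWWW")
        with pytest.warns(UserWarning):
            pairs = lp.pair_residues(a, b)
        assert pairs == []


class TestSuperpose:
    def test_self_superposition_is_identity(self, toy60):
        pairs = lp.pair_residues(toy60, toy60)
        sp = lp.superpose(toy60, toy60, pairs)
        assert sp.rmsd_kept == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sp.rotation, np.eye(3), atol=1e-8)

    def test_known_transform_recovered(self, toy60):
        rot, trans = rigid_motion(3)
        mobile = transform_model(toy60, rot, trans)
        sp = lp.superpose(mobile, toy60, lp.pair_residues(mobile, toy60))
        assert sp.rmsd_kept < 1e-6
        assert np.allclose(sp.rotation @ rot, np.eye(3), atol=1e-6)

    def test_rotation_orthonormal_det_plus_one(self, toy60):
        rot, trans = rigid_motion(11)
        mobile = transform_model(toy60, rot, trans)
        sp = lp.superpose(mobile, toy60, lp.pair_residues(mobile, toy60))
        assert np.allclose(sp.rotation @ sp.rotation.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(sp.rotation) == pytest.approx(1.0, abs=1e-8)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_rmsd_invariant_under_rigid_pretransform(self, seed):
        base = make_toy_protein(20, "coil", seed=1)
        noisy = base.copy()
        rng = np.random.default_rng(5)
        for a in noisy.atoms:
            a.xyz = a.xyz + rng.normal(0, 0.3, 3)
        pairs = lp.pair_residues(noisy, base)
        ref = lp.superpose(noisy, base, pairs, reject_sigma=np.inf)
        rot, trans = rigid_motion(seed)
        moved = transform_model(noisy, rot, trans)
        sp = lp.superpose(moved, base, lp.pair_residues(moved, base),
                          reject_sigma=np.inf)
        assert sp.rmsd_kept == pytest.approx(ref.rmsd_kept, abs=1e-6)

    def test_rmsd_kept_le_rmsd_all_and_inf_sigma_equal(self, toy60):
        noisy = toy60.copy()
        rng = np.random.default_rng(7)
        for a in noisy.atoms:
            a.xyz = a.xyz + rng.normal(0, 0.2, 3)
        noisy.atoms[10].xyz += 5.0   # one outlier
        pairs = lp.pair_residues(noisy, toy60)
        sp = lp.superpose(noisy, toy60, pairs, cycles=5, reject_sigma=2.0)
        assert sp.rmsd_kept <= sp.rmsd_all
        sp_inf = lp.superpose(noisy, toy60, pairs, reject_sigma=np.inf)
        assert sp_inf.rmsd_kept == pytest.approx(sp_inf.rmsd_all)

    def test_outlier_rejection_reduces_kept_pairs(self, toy60):
        noisy = toy60.copy()
        noisy.atoms[10].xyz = noisy.atoms[10].xyz + 8.0
        pairs = lp.pair_residues(noisy, toy60)
        sp = lp.superpose(noisy, toy60, pairs, cycles=5, reject_sigma=2.0)
        assert sp.kept_pairs < 4 * len(pairs)
        assert sp.rmsd_kept < sp.rmsd_all

    def test_too_few_pairs_raises(self, toy60):
        with pytest.raises(DegenerateFitError):
            lp.superpose(toy60, toy60, [], atom_set="ca")

    def test_ca_only_atom_set(self, toy60):
        pairs = lp.pair_residues(toy60, toy60)
        sp = lp.superpose(toy60, toy60, pairs, atom_set="ca")
        assert sp.kept_pairs == 60


class TestApplyTransform:
    def test_identity(self, helix20):
        out = lp.apply_transform(helix20, lp.Superposition.identity())
        assert np.allclose(out.coords(), helix20.coords())

    def test_apply_then_inverse(self, helix20):
        rot, trans = rigid_motion(9)
        sp = lp.Superposition(rot, trans)
        out = lp.apply_transform(lp.apply_transform(helix20, sp), sp.inverse())
        assert np.allclose(out.coords(), helix20.coords(), atol=1e-9)

    def test_het_atoms_moved_too(self, planted_all):
        model, _ = planted_all
        rot, trans = rigid_motion(2)
        out = lp.apply_transform(model, lp.Superposition(rot, trans))
        het = [i for i, a in enumerate(model.atoms) if a.is_het]
        assert np.allclose(out.atoms[het[0]].xyz,
                           rot @ model.atoms[het[0]].xyz + trans)
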