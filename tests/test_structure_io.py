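"""Structure reading, membrane-frame derivation, layer conversion, boxes."""

import numpy as np
import pytest

from sterolsweep import structure_io as sio

from conftest import minimal_opm_atoms


class TestReadOpmPdb:
    def test_reads_atoms_and_derives_frame(self, opm_text):
        st = sio.read_opm_pdb(opm_text)
        assert len(st.dummy_indices) == 16
        assert len(st.protein_atoms()) == 24
        assert st.frame.thickness == pytest.approx(28.4, abs=1e-6)
        assert st.frame.z_upper == pytest.approx(14.2, abs=1e-6)

    def test_missing_dummies_is_an_error(self):
        atoms = [a for a in minimal_opm_atoms() if a.resname != "DUM"]
        text = sio.write_pdb(sio.OrientedStructure(atoms))
        with pytest.raises(ValueError, match="not an OPM-oriented structure"):
            sio.read_opm_pdb(text)

    def test_single_plane_cannot_define_slab(self):
        atoms = [
            a for a in minimal_opm_atoms() if not (a.resname == "DUM" and a.xyz[2] < 0)
        ]
        text = sio.write_pdb(sio.OrientedStructure(atoms))
        with pytest.raises(ValueError, match="slab|degenerate"):
            sio.read_opm_pdb(text)

    def test_heteroligand_is_present_and_strippable(self):
        atoms = minimal_opm_atoms()
        atoms.append(
            sio.Atom(999, "C1", "C", "CLR", 500, "L", (0.0, 0.0, 0.0), het=True)
        )
        st = sio.read_opm_pdb(sio.write_pdb(sio.OrientedStructure(atoms)))
        assert st.het_residues() == [("L", 500, "CLR")]

    def test_round_trip_preserves_names_and_coordinates(self, opm_text):
        st = sio.read_opm_pdb(opm_text)
        st2 = sio.read_opm_pdb(sio.write_pdb(st))
        assert len(st2.atoms) == len(st.atoms)
        assert [a.name for a in st2.atoms] == [a.name for a in st.atoms]
        assert np.allclose(st2.coords(), st.coords(), atol=1e-3)


class TestDeriveMembraneFrame:
    def test_clean_layers(self, opm_text):
        frame = sio.read_opm_pdb(opm_text).frame
        assert frame.midplane == pytest.approx(0.0, abs=1e-9)
        assert frame.thickness == pytest.approx(frame.z_upper - frame.z_lower)

    def test_jittered_layers_average_to_means(self):
        atoms = minimal_opm_atoms(dum_z=15.0, jitter=0.3)
        st = sio.OrientedStructure(
            atoms, [i for i, a in enumerate(atoms) if a.resname == "DUM"], []
        )
        frame = sio.derive_membrane_frame(st)
        z = st.coords(st.dummy_indices)[:, 2]
        assert frame.z_upper == pytest.approx(np.mean(z[z > 0]), abs=1e-12)
        assert frame.z_lower == pytest.approx(np.mean(z[z < 0]), abs=1e-12)
        # thickness stays within a few sd/sqrt(n) of the construction value
        assert frame.thickness == pytest.approx(30.0, abs=4 * 0.3 / np.sqrt(8))

    def test_merged_layer_is_degenerate(self):
        atoms = minimal_opm_atoms(dum_z=1.0)
        st = sio.OrientedStructure(
            atoms, [i for i, a in enumerate(atoms) if a.resname == "DUM"], []
        )
        with pytest.raises(ValueError, match="degenerate"):
            sio.derive_membrane_frame(st)

    def test_invariant_under_atom_permutation(self, opm_text):
        st = sio.read_opm_pdb(opm_text)
        order = np.random.default_rng(1).permutation(len(st.atoms))
        atoms = [st.atoms[i] for i in order]
        perm = sio.OrientedStructure(
            atoms, [i for i, a in enumerate(atoms) if a.resname == "DUM"], []
        )
        f1, f2 = st.frame, sio.derive_membrane_frame(perm)
        assert (f1.z_upper, f1.z_lower) == pytest.approx((f2.z_upper, f2.z_lower))


class TestDonorLayerConversion:
    def test_each_dummy_becomes_nh3(self, opm_text):
        st = sio.read_opm_pdb(opm_text)
        conv = sio.convert_dummies_to_donor_layers(st)
        pseudo = [conv.atoms[i] for i in conv.pseudo_indices]
        assert sum(a.element == "N" for a in pseudo) == 16
        assert sum(a.element == "H" for a in pseudo) == 48
        assert not any(a.resname == "DUM" for a in conv.atoms)

    def test_nitrogen_keeps_dummy_coordinate_and_nh_geometry(self, opm_text):
        st = sio.read_opm_pdb(opm_text)
        first_dum = np.asarray(st.atoms[st.dummy_indices[0]].xyz)
        conv = sio.convert_dummies_to_donor_layers(st)
        groups = {}
        for i in conv.pseudo_indices:
            a = conv.atoms[i]
            groups.setdefault(a.resseq, []).append(a)
        target = next(
            g for g in groups.values()
            if np.allclose([a.xyz for a in g if a.element == "N"][0], first_dum)
        )
        n_xyz = np.asarray([a.xyz for a in target if a.element == "N"][0])
        assert np.allclose(n_xyz, first_dum, atol=0)
        for h in (a for a in target if a.element == "H"):
            assert np.linalg.norm(np.asarray(h.xyz) - n_xyz) == pytest.approx(1.01)
            # umbrella points away from the midplane
            assert (h.xyz[2] - n_xyz[2]) * np.sign(n_xyz[2]) > 0

    def test_reconversion_is_an_error(self, opm_text):
        conv = sio.convert_dummies_to_donor_layers(sio.read_opm_pdb(opm_text))
        with pytest.raises(ValueError, match="no dummy atoms"):
            sio.convert_dummies_to_donor_layers(conv)


class TestStripHeteroligands:
    def test_ligand_residues_removed_protein_untouched(self):
        atoms = minimal_opm_atoms()
        for k, resname in enumerate(["CLR", "DGT", "HOH"]):
            atoms.append(
                sio.Atom(900 + k, "C1", "C", resname, 600 + k, "L",
                         (1.0 * k, 0.0, 0.0), het=True)
            )
        st = sio.read_opm_pdb(sio.write_pdb(sio.OrientedStructure(atoms)))
        stripped = sio.strip_heteroligands(st)
        assert stripped.het_residues() == []
        assert len(stripped.protein_atoms()) == len(st.protein_atoms())
        assert len(stripped.dummy_indices) == 16

    def test_identity_without_hetero_ligands(self, opm_text):
        st = sio.read_opm_pdb(opm_text)
        assert len(sio.strip_heteroligands(st).atoms) == len(st.atoms)


class TestSearchBoxes:
    def test_geometry_and_overlap(self, bundle):
        boxes = sio.build_search_boxes(bundle, "cytosolic")
        assert len(boxes) == 2
        frame = bundle.frame
        for b in boxes:
            assert b.size[2] == pytest.approx(frame.thickness / 2 + 6.0)
        assert boxes[0].intersection_volume(boxes[1]) > 0

    def test_half_slab_atoms_covered(self, bundle):
        frame = bundle.frame
        for half, lo, hi in [
            ("cytosolic", frame.midplane, frame.z_upper),
            ("luminal", frame.z_lower, frame.midplane),
        ]:
            boxes = sio.build_search_boxes(bundle, half)
            for a in bundle.protein_heavy():
                if lo <= a.xyz[2] <= hi:
                    assert any(b.contains(a.xyz) for b in boxes)

    def test_translation_equivariance_in_xy(self, bundle):
        boxes = sio.build_search_boxes(bundle, "cytosolic")
        shifted = sio.translate(bundle, (7.0, -3.0, 0.0))
        boxes2 = sio.build_search_boxes(shifted, "cytosolic")
        for b, b2 in zip(boxes, boxes2):
            assert np.allclose(
                np.asarray(b2.center) - np.asarray(b.center), (7.0, -3.0, 0.0)
            )
            assert b2.size == pytest.approx(b.size)

    def test_empty_half_is_an_error(self):
        atoms = minimal_opm_atoms()
        lowered = [
            a if a.resname == "DUM"
            else sio.Atom(a.serial, a.name, a.element, a.resname, a.resseq,
                          a.chain, (a.xyz[0], a.xyz[1], a.xyz[2] - 30.0))
            for a in atoms
        ]
        st = sio.OrientedStructure(
            lowered, [i for i, a in enumerate(lowered) if a.resname == "DUM"], []
        )
        st.frame = sio.derive_membrane_frame(st)
        with pytest.raises(ValueError, match="no protein atoms"):
            sio.build_search_boxes(st, "cytosolic")
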