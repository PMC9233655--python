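"""Contact counting, ring tilt, pose assessment, matching, energy summaries."""

import numpy as np
import pytest

from sterolsweep import selection as sel
from sterolsweep import synthetic_data as sd
from sterolsweep.structure_io import MembraneFrame

FRAME = MembraneFrame(z_upper=14.2, z_lower=-14.2)


def brute_force_contacts(pose, structure, cutoff):
    residues = set()
    for a in structure.protein_atoms():
        if a.is_hydrogen:
            continue
        for i in pose.heavy_indices:
            if np.linalg.norm(np.asarray(a.xyz) - pose.coords[i]) <= cutoff:
                residues.add((a.chain, a.resseq, a.resname))
                break
    return residues


class TestContactResidues:
    def test_matches_brute_force_oracle(self, prepared_bundle):
        pose = sd.make_sterol_pose((3.8, 11.38, 7.1), 5.0, 30.0)
        fast = sel.contact_residues(pose, prepared_bundle, 4.0)
        assert fast == brute_force_contacts(pose, prepared_bundle, 4.0)
        assert len(fast) >= 8

    def test_far_pose_has_no_contacts(self, prepared_bundle):
        pose = sd.make_sterol_pose((60.0, 0.0, 7.0), 0.0)
        assert sel.contact_residues(pose, prepared_bundle, 4.0) == set()

    def test_monotone_in_cutoff(self, prepared_bundle):
        pose = sd.make_sterol_pose((12.0, 5.0, 7.1), 10.0, 120.0)
        c4 = sel.contact_residues(pose, prepared_bundle, 4.0)
        c5 = sel.contact_residues(pose, prepared_bundle, 5.0)
        assert c4 <= c5

    def test_pseudo_layers_never_count(self, prepared_bundle):
        # a pose lying in the interface plane, away from the bundle, touches
        # only pseudo-atoms of the donor layer
        pose = sd.make_sterol_pose((18.0, 18.0, 14.2), 90.0, azimuth_deg=45.0)
        assert sel.contact_residues(pose, prepared_bundle, 4.0) == set()


class TestTiltAngle:
    def test_upright_template_is_zero(self):
        pose = sd.make_sterol_pose((0, 0, 0), 0.0)
        assert sel.tilt_angle(pose, FRAME) == pytest.approx(0.0, abs=1e-9)

    def test_in_plane_template_is_ninety(self):
        pose = sd.make_sterol_pose((0, 0, 0), 90.0)
        assert sel.tilt_angle(pose, FRAME) == pytest.approx(90.0, abs=1e-9)

    @pytest.mark.parametrize("tilt", [5.0, 25.0, 45.0, 60.0, 89.0])
    def test_rotation_by_known_angle(self, tilt):
        pose = sd.make_sterol_pose((2.0, -3.0, 5.0), tilt, azimuth_deg=77.0)
        assert sel.tilt_angle(pose, FRAME) == pytest.approx(tilt, abs=1e-6)

    def test_invariant_under_rotation_about_normal(self):
        for azim in (0.0, 45.0, 211.0):
            pose = sd.make_sterol_pose((0, 0, 0), 25.0, azimuth_deg=azim)
            assert sel.tilt_angle(pose, FRAME) == pytest.approx(25.0, abs=1e-6)

    def test_degenerate_ring_is_an_error(self):
        pose = sd.make_sterol_pose((0, 0, 0), 0.0)
        collinear = pose.coords.copy()
        collinear[:, :2] = 0.0
        bad = sd.Pose(
            ligand_name="x",
            atom_names=pose.atom_names,
            elements=pose.elements,
            coords=collinear,
            energy=-10.0,
        )
        with pytest.raises(ValueError, match="collinear|degenerate"):
            sel.tilt_angle(bad, FRAME)


class TestAssessPose:
    def test_threshold_pass_and_fail_matrix(self, prepared_bundle):
        crit = sel.SelectionCriteria.tm()
        good = sd.make_sterol_pose((3.8, 11.38, 7.1), 29.0, 345.0)
        v = sel.assess_pose(good, prepared_bundle, crit)
        assert v.n_contacts >= 8 and v.tilt_deg < 30 and v.passes
        tilted = sd.make_sterol_pose((3.8, 11.38, 7.1), 31.0, 345.0)
        v_tilted = sel.assess_pose(tilted, prepared_bundle, crit)
        assert v_tilted.n_contacts >= 8 and not v_tilted.passes
        lonely = sd.make_sterol_pose((40.0, 0.0, 7.1), 5.0)
        assert not sel.assess_pose(lonely, prepared_bundle, crit).passes

    def test_disabled_criteria_pass_everything(self, prepared_bundle):
        tilted = sd.make_sterol_pose((3.8, 11.38, 7.1), 31.0, 345.0)
        v = sel.assess_pose(tilted, prepared_bundle, sel.SelectionCriteria.aqueous())
        assert v.passes

    def test_half_assignment_by_ring_centroid(self, prepared_bundle):
        up = sd.make_sterol_pose((12, 5, 7.0), 5.0)
        down = sd.make_sterol_pose((12, 5, -7.0), 5.0)
        assert sel.assess_pose(up, prepared_bundle).half == "cytosolic"
        assert sel.assess_pose(down, prepared_bundle).half == "luminal"

    def test_selection_is_a_pure_idempotent_filter(self, prepared_bundle):
        poses = [
            sd.make_sterol_pose((3.8, 11.38, 7.1), t, 345.0, model=i + 1)
            for i, t in enumerate([5.0, 20.0, 40.0, 70.0])
        ]
        selected = [a.pose for a in sel.select_poses(poses, prepared_bundle) if a.passes]
        assert set(p.key for p in selected) <= set(p.key for p in poses)
        again = [a.pose for a in sel.select_poses(selected, prepared_bundle) if a.passes]
        assert [p.key for p in again] == [p.key for p in selected]


class TestMatchToResolved:
    def test_identical_ring_matches_at_zero(self):
        pose = sd.make_sterol_pose((0, 0, 0), 10.0)
        result = sel.match_to_resolved([pose], [pose.ring_coords.copy()])
        assert result["per_ligand"][0]["best_distance"] == pytest.approx(0.0)
        assert result["matched_fraction"] == 1.0

    def test_distant_pose_is_unmatched(self):
        pose = sd.make_sterol_pose((0, 0, 0), 0.0)
        far = pose.ring_coords + np.array([20.0, 0.0, 0.0])
        result = sel.match_to_resolved([pose], [far])
        assert not result["per_ligand"][0]["matched"]

    def test_planted_sites_with_small_jitter_all_match(self):
        rng = np.random.default_rng(4)
        centers = [(0, 0, 0), (15, 0, 3), (0, 15, -3), (15, 15, 0)]
        resolved = [sd.make_sterol_pose(c, 5.0).ring_coords for c in centers]
        poses = [
            sd.make_sterol_pose(c, 5.0, jitter_sd=0.3, rng=rng, model=i + 1)
            for i, c in enumerate(centers)
        ]
        assert sel.match_to_resolved(poses, resolved)["matched_fraction"] == 1.0

    def test_empty_resolved_set_is_an_error(self):
        with pytest.raises(ValueError, match="no resolved"):
            sel.match_to_resolved([], [])


class TestSummarizeEnergies:
    def test_hand_computed_mean_and_sd(self):
        poses = [
            sd.make_sterol_pose((0, 0, 0), 0.0, energy=e, model=i + 1)
            for i, e in enumerate([-15.0, -14.0, -13.0])
        ]
        mean, sd_, single = sel.summarize_energies(poses)
        assert (mean, sd_) == pytest.approx((-14.0, 1.0))
        assert not single

    def test_single_pose_flagged(self):
        pose = sd.make_sterol_pose((0, 0, 0), 0.0, energy=-16.8)
        assert sel.summarize_energies([pose]) == (-16.8, 0.0, True)

    def test_mean_translation_equivariance(self):
        es = [-15.2, -14.1, -12.7, -13.3]
        poses = [
            sd.make_sterol_pose((0, 0, 0), 0.0, energy=e, model=i + 1)
            for i, e in enumerate(es)
        ]
        shifted = [
            sd.make_sterol_pose((0, 0, 0), 0.0, energy=e + 2.5, model=i + 1)
            for i, e in enumerate(es)
        ]
        m1, _, _ = sel.summarize_energies(poses)
        m2, _, _ = sel.summarize_energies(shifted)
        assert m2 == pytest.approx(m1 + 2.5)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            sel.summarize_energies([])
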