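import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from corrdock.interaction_profile import (InteractionParams, LigandPose,
                                          binding_profile, detect_clashes,
                                          detect_contacts, detect_hbonds)
from corrdock.synthetic import PosePlanting, synth_docked_pose

from conftest import make_structure


def single_pair(protein_element, ligand_element, distance, protein_name="O"):
    protein = make_structure([
        (protein_name, protein_element, "SER", "A", 10, (0.0, 0.0, 0.0)),
    ])
    pose = LigandPose(np.array([[distance, 0.0, 0.0]]), [ligand_element])
    return protein, pose


class TestDetectors:
    def test_backbone_oxygen_to_ligand_nitrogen_is_hbond(self):
        protein, pose = single_pair("O", "N", 2.8)
        hbonds = detect_hbonds(protein, pose)
        assert len(hbonds) == 1
        assert hbonds[0].distance == pytest.approx(2.8)

    def test_distance_beyond_cutoff_is_not_hbond(self):
        protein, pose = single_pair("O", "N", 4.5)
        assert detect_hbonds(protein, pose) == []

    def test_carbon_cannot_hydrogen_bond(self):
        protein, pose = single_pair("C", "O", 2.8, protein_name="CB")
        assert detect_hbonds(protein, pose) == []
        assert len(detect_contacts(protein, pose)) == 1  # still a contact

    def test_fluorine_is_weak_acceptor(self):
        protein, pose = single_pair("N", "F", 3.0, protein_name="NZ")
        assert len(detect_hbonds(protein, pose)) == 1

    @pytest.mark.parametrize("distance,expected", [(3.5, 1), (4.5, 0)])
    def test_contact_cutoff(self, distance, expected):
        protein, pose = single_pair("C", "C", distance, protein_name="CB")
        assert len(detect_contacts(protein, pose)) == expected

    def test_hbonded_residue_not_duplicated_in_contacts(self):
        protein, pose = single_pair("O", "N", 2.8)
        assert len(detect_hbonds(protein, pose)) == 1
        assert detect_contacts(protein, pose) == []

    @pytest.mark.parametrize("distance,expected", [(1.4, 1), (2.5, 0)])
    def test_clash_cutoff(self, distance, expected):
        protein, pose = single_pair("C", "C", distance, protein_name="CB")
        assert len(detect_clashes(protein, pose)) == expected

    def test_params_ordering_enforced(self):
        with pytest.raises(ValueError):
            InteractionParams(hbond_da_max=4.0, contact_max=3.9)


class TestPlantedPoses:
    def test_planted_counts_recovered_exactly(self):
        protein, pose = synth_docked_pose(PosePlanting(n_hbonds=2, n_contacts=3, n_clashes=1))
        report = binding_profile(protein, pose)
        assert report.totals() == (2, 3, 1)
        assert report.bridging_residues == []

    def test_planted_bridge_detected(self):
        protein, pose = synth_docked_pose(PosePlanting(n_hbonds=1, bridge=True))
        report = binding_profile(protein, pose)
        assert len(report.hbonds) == 3  # 1 planted + 2 from the bridging residue
        assert len(report.bridging_residues) == 1
        assert "LYS" in report.bridging_residues[0]

    def test_single_hbond_is_not_a_bridge(self):
        protein, pose = synth_docked_pose(PosePlanting(n_hbonds=1))
        assert binding_profile(protein, pose).bridging_residues == []

    def test_short_span_double_hbond_is_not_a_bridge(self):
        protein, pose = synth_docked_pose(PosePlanting(bridge=True, bridge_span=5.0))
        assert binding_profile(protein, pose).bridging_residues == []
        assert len(binding_profile(protein, pose).hbonds) == 2

    def test_empty_planting_empty_report(self):
        protein, pose = synth_docked_pose(PosePlanting())
        assert binding_profile(protein, pose).totals() == (0, 0, 0)

    def test_report_totals_equal_detector_totals(self):
        protein, pose = synth_docked_pose(
            PosePlanting(n_hbonds=2, n_contacts=2, n_clashes=1, bridge=True))
        report = binding_profile(protein, pose)
        assert len(report.hbonds) == len(detect_hbonds(protein, pose))
        assert len(report.contacts) == len(detect_contacts(protein, pose))
        assert len(report.clashes) == len(detect_clashes(protein, pose))


class TestInvariants:
    def _random_scene(self, seed=0, n_protein=30, n_ligand=8):
        rng = np.random.default_rng(seed)
        elements = ["C", "N", "O", "S"]
        protein = make_structure([
            (f"{elements[i % 4]}{i}", elements[i % 4], "ALA", "A", i + 1,
             rng.uniform(0, 12, size=3))
            for i in range(n_protein)
        ])
        lig_elements = [["C", "N", "O", "F"][i % 4] for i in range(n_ligand)]
        pose = LigandPose(rng.uniform(0, 12, size=(n_ligand, 3)), lig_elements)
        return protein, pose

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_shrinking_hbond_cutoff_never_adds_hbonds(self, seed):
        protein, pose = self._random_scene(seed)
        wide = detect_hbonds(protein, pose, InteractionParams(hbond_da_max=3.35))
        narrow = detect_hbonds(protein, pose, InteractionParams(hbond_da_max=2.6))
        wide_keys = {(h.residue, h.protein_atom, h.ligand_index) for h in wide}
        narrow_keys = {(h.residue, h.protein_atom, h.ligand_index) for h in narrow}
        assert narrow_keys <= wide_keys

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_interaction_classes_disjoint_at_atom_pair_level(self, seed):
        protein, pose = self._random_scene(seed)
        params = InteractionParams()
        hbonds = detect_hbonds(protein, pose, params)
        contacts = detect_contacts(protein, pose, params)
        clashes = detect_clashes(protein, pose, params)
        # distance windows per class
        assert all(params.clash_max < h.distance <= params.hbond_da_max for h in hbonds)
        assert all(params.clash_max < c.distance <= params.contact_max for c in contacts)
        assert all(c.distance <= params.clash_max for c in clashes)
        # no atom pair (residue, protein atom, ligand atom) in two classes
        pairs = [(x.residue, x.protein_atom, x.ligand_atom)
                 for group in (hbonds, contacts, clashes) for x in group]
        assert len(pairs) == len(set(pairs))

    def test_profile_invariant_under_common_rigid_motion(self):
        protein, pose = synth_docked_pose(
            PosePlanting(n_hbonds=2, n_contacts=1, n_clashes=1, bridge=True))
        before = binding_profile(protein, pose)
        rot = Rotation.from_euler("zyx", [30, 60, 15], degrees=True).as_matrix()
        shift = np.array([5.0, -3.0, 12.0])
        moved_protein = protein.with_coords(protein.coords @ rot.T + shift)
        moved_pose = LigandPose(pose.coords @ rot.T + shift, pose.elements, pose.names)
        after = binding_profile(moved_protein, moved_pose)
        assert after.totals() == before.totals()
        assert after.bridging_residues == before.bridging_residues
        np.testing.assert_allclose([h.distance for h in after.hbonds],
                                   [h.distance for h in before.hbonds], atol=1e-9)
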