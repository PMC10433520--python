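import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from corrdock import synthetic
from corrdock.ensemble_metrics import (BFACTOR_PREFACTOR, bfactor_per_residue,
                                       kabsch_superpose, pairwise_rmsf,
                                       rmsd_trace)
from corrdock.errors import StructureError
from corrdock.structure_io import Ensemble

from conftest import make_structure


def brute_force_rmsd(mobile, reference, n_rot=10_000, seed=0):
    """Independent oracle: best RMSD over random rotations + optimal translation."""
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_rot, rng=rng).as_matrix()
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    rotated = np.einsum("kij,nj->kni", rots, mc)
    return float(np.sqrt(np.mean(np.sum((rotated - rc) ** 2, axis=-1), axis=-1)).min())


class TestKabsch:
    def test_identity_and_pure_translation_give_zero(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(6, 3))
        for mobile in (ref, ref + np.array([5.0, 0.0, 0.0])):
            _r, _t, rmsd = kabsch_superpose(mobile, ref)
            assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(5, 3))
        mob = ref[::-1] + rng.normal(scale=0.5, size=(5, 3))
        rot, _t, _ = kabsch_superpose(mob, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rmsd_invariant_under_common_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(7, 3))
        mob = ref + rng.normal(scale=0.3, size=(7, 3))
        _r, _t, rmsd0 = kabsch_superpose(mob, ref)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(scale=10.0, size=3)
        _r, _t, rmsd1 = kabsch_superpose(mob @ rot.T + shift, ref @ rot.T + shift)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 3, 7])
    def test_beats_brute_force_rotation_sampling(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(4, 3))
        rot = Rotation.random(rng=rng).as_matrix()
        mob = ref @ rot.T + rng.normal(scale=0.1, size=(4, 3))
        _r, _t, rmsd = kabsch_superpose(mob, ref)
        assert rmsd <= brute_force_rmsd(mob, ref, seed=seed) + 1e-12

    def test_degenerate_inputs_rejected(self):
        line = np.outer(np.arange(4.0), [1.0, 0.0, 0.0])
        with pytest.raises(StructureError, match="collinear"):
            kabsch_superpose(line, line)
        with pytest.raises(StructureError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def _four_point_residue(extra_z=None):
    pos = {"N": (1, 0, 0), "CA": (-1, 0, 0), "C": (0, 1, 0), "O": (0, -1, 0)}
    z = dict(zip(pos, extra_z or [0, 0, 0, 0]))
    return make_structure([
        (name, name[0], "GLY", "A", 1, (x, y, z[name])) for name, (x, y, _z) in pos.items()
    ])


class TestRmsdTrace:
    def test_copies_and_rigid_moves_are_zero(self, chain10):
        rng = np.random.default_rng(0)
        frames = [chain10]
        for _ in range(3):
            frames.append(chain10.with_coords(chain10.coords + rng.normal(scale=4.0, size=3)))
        trace = rmsd_trace(Ensemble(frames), chain10)
        np.testing.assert_allclose(trace.values, 0.0, atol=1e-8)

    def test_planted_rotation_free_displacement_is_recovered(self):
        # displacement pattern with zero net translation and zero net torque,
        # so superposition leaves it intact and RMSD = d
        d = 0.2
        ref = _four_point_residue()
        moved = _four_point_residue(extra_z=[d, d, -d, -d])
        trace = rmsd_trace(Ensemble([ref, moved]), ref)
        assert trace.values[0] == pytest.approx(0.0, abs=1e-10)
        assert trace.values[1] == pytest.approx(d, rel=0.01)
        # cross-check against the rotation-sampling oracle
        oracle = brute_force_rmsd(moved.coords, ref.coords)
        assert trace.values[1] <= oracle + 1e-9

    def test_mismatch_names_the_frame(self, chain10):
        short = synthetic.synth_chain(9)
        with pytest.raises(StructureError, match="frame 0"):
            rmsd_trace(Ensemble([short]), chain10)


class TestBfactor:
    def test_static_ensemble_is_zero(self, chain10):
        ens = synthetic.synth_ensemble(chain10, 5, 0.0, seed=0)
        series = bfactor_per_residue(ens)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)

    def test_single_frame_rejected(self, chain10):
        with pytest.raises(StructureError, match="2 frames"):
            bfactor_per_residue(Ensemble([chain10]))

    def test_alternating_displacement_closed_form(self):
        # one atom alternating +/- d along x; MSF = d^2, residue mean over
        # its 4 backbone atoms gives B = (8 pi^2 / 3) d^2 / 4
        base = synthetic.synth_chain(50)
        d = 1.0
        frames = []
        for k in range(40):
            coords = base.coords
            coords[0, 0] += d if k % 2 == 0 else -d
            frames.append(base.with_coords(coords))
        series = bfactor_per_residue(Ensemble(frames))
        expected = BFACTOR_PREFACTOR * d**2 / 4
        assert series.values[0] == pytest.approx(expected, rel=0.02)
        np.testing.assert_allclose(series.values[1:], 0.0, atol=0.05 * expected)

    def test_planted_sigma_recovered(self):
        sigma = 0.5
        base = synthetic.synth_chain(30)
        ens = synthetic.synth_ensemble(base, 500, sigma, seed=42)
        series = bfactor_per_residue(ens)
        expected = 8 * np.pi**2 * sigma**2  # (8 pi^2 / 3) * 3 sigma^2
        assert np.mean(series.values) == pytest.approx(expected, rel=0.10)

    def test_quadratic_scaling_in_displacement(self):
        base = synthetic.synth_chain(20)
        small = synthetic.synth_ensemble(base, 200, 0.3, seed=9)
        large = synthetic.synth_ensemble(base, 200, 0.6, seed=9)
        ratio = np.mean(bfactor_per_residue(large).values) / \
            np.mean(bfactor_per_residue(small).values)
        assert ratio == pytest.approx(4.0, rel=0.10)


class TestPairwiseRmsf:
    def test_identical_and_rigidly_moved_structures_are_zero(self, chain10):
        np.testing.assert_allclose(pairwise_rmsf(chain10, chain10).values, 0.0, atol=1e-12)
        rot = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
        moved = chain10.with_coords(chain10.coords @ rot.T + np.array([3.0, -2.0, 1.0]))
        np.testing.assert_allclose(pairwise_rmsf(chain10, moved).values, 0.0, atol=1e-8)

    def test_localizes_planted_displacement(self):
        a = synthetic.synth_chain(50)
        coords = a.coords
        target = a.residue_atoms("A", 25)
        coords[target] += np.array([0.0, 0.0, 2.0])
        b = a.with_coords(coords)
        series = pairwise_rmsf(a, b)
        values = dict(zip(series.labels, series.values))
        assert values["A/25"] == pytest.approx(2.0, abs=0.2)
        others = [v for k, v in values.items() if k != "A/25"]
        assert max(others) <= 0.2

    def test_selection_mismatch_raises(self, chain10):
        with pytest.raises(StructureError, match="mismatch"):
            pairwise_rmsf(chain10, synthetic.synth_chain(9))
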