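"""Kabsch superposition, RMSD/RMSF/Rg, PCA and porcupine export."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from lamindyn.ensemble import (
    CoordinateEnsemble,
    kabsch_superpose,
    pca,
    porcupine_export,
    radius_of_gyration,
    rmsd_series,
    rmsf,
)
from lamindyn.synthetic import (
    EnsembleSpec,
    make_ensemble,
    planted_mode_spec,
    random_orthonormal_modes,
)


def jitter_ensemble(n_frames, n_atoms, sigma, seed=0):
    rng = np.random.default_rng(seed)
    ref = rng.uniform(-1, 1, (n_atoms, 3))
    coords = ref[None] + rng.normal(0.0, sigma, (n_frames, n_atoms, 3))
    return CoordinateEnsemble(
        coords=coords,
        residue_numbers=np.arange(n_atoms),
        atom_names=np.array(["CA"] * n_atoms),
    )


def brute_force_rmsd(mobile, target):
    """Independent oracle: minimise RMSD over rotation space directly.

    Coarse quaternion grid followed by local refinement of the rotation
    vector; translation handled by centering.
    """
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)

    def cost(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((mc @ r.T - tc) ** 2, axis=1)))

    rng = np.random.default_rng(7)
    starts = [Rotation.from_quat(q / np.linalg.norm(q)).as_rotvec()
              for q in rng.standard_normal((40, 4))]
    best = np.inf
    for start in starts:
        res = minimize(cost, start, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identical_structures(self, rng):
        x = rng.uniform(-1, 1, (10, 3))
        rot, trans, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-10)
        assert np.allclose(trans, 0.0, atol=1e-10)

    def test_rigid_motion_removed(self, rng):
        x = rng.uniform(-1, 1, (15, 3))
        r_true = Rotation.from_rotvec([0.3, -1.2, 0.7]).as_matrix()
        y = x @ r_true.T + np.array([1.0, -2.0, 0.5])
        rot, trans, rmsd = kabsch_superpose(x, y)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rot, r_true, atol=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_rotation_search(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.uniform(-1, 1, (10, 3))
        target = rng.uniform(-1, 1, (10, 3))
        _, _, rmsd = kabsch_superpose(mobile, target)
        assert rmsd == pytest.approx(brute_force_rmsd(mobile, target), abs=1e-9)

    def test_proper_rotation_enforced_on_mirrored_target(self, rng):
        x = rng.uniform(-1, 1, (12, 3))
        mirrored = x * np.array([-1.0, 1.0, 1.0])
        rot, _, _ = kabsch_superpose(x, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)

    def test_collinear_configuration_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line + 1.0)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def test_identical_frames_zero(self, rng):
        frame = rng.uniform(-1, 1, (8, 3))
        ens = CoordinateEnsemble(
            coords=np.repeat(frame[None], 5, axis=0),
            residue_numbers=np.arange(8),
            atom_names=np.array(["CA"] * 8),
        )
        assert np.allclose(rmsd_series(ens, reference=0), 0.0, atol=1e-12)

    def test_translated_frames_zero(self, rng):
        frame = rng.uniform(-1, 1, (8, 3))
        coords = np.stack([frame + k for k in range(4)])
        ens = CoordinateEnsemble(
            coords=coords,
            residue_numbers=np.arange(8),
            atom_names=np.array(["CA"] * 8),
        )
        assert np.allclose(rmsd_series(ens, frame), 0.0, atol=1e-10)

    def test_jittered_mean_matches_analytic_expectation(self):
        # E[rmsd^2] after fitting n_atoms iid-jittered atoms is
        # ~ 3 sigma^2 (1 - 1/n_atoms) (translation absorbs 3 DOF/atom share)
        sigma, n_atoms = 0.05, 200
        ens = jitter_ensemble(n_frames=400, n_atoms=n_atoms, sigma=sigma, seed=5)
        mean_rmsd = float(np.mean(rmsd_series(ens, reference=ens.coords[0] * 0 + ens.coords.mean(0))))
        expected = sigma * np.sqrt(3.0 * (1.0 - 1.0 / n_atoms))
        assert mean_rmsd == pytest.approx(expected, rel=0.02)


class TestRmsf:
    def test_rigid_ensemble_zero(self, rng):
        frame = rng.uniform(-1, 1, (10, 3))
        ens = CoordinateEnsemble(
            coords=np.repeat(frame[None], 6, axis=0),
            residue_numbers=np.arange(10),
            atom_names=np.array(["CA"] * 10),
        )
        assert np.allclose(rmsf(ens), 0.0, atol=1e-12)

    def test_isotropic_jitter_approaches_sigma_sqrt3(self):
        # superposition absorbs 6 of the 3N noise DOF, hence the (1 - 2/N)
        sigma, n_atoms = 0.04, 60
        ens = jitter_ensemble(n_frames=3000, n_atoms=n_atoms, sigma=sigma, seed=9)
        fluct = rmsf(ens)
        expected = sigma * np.sqrt(3.0 * (1.0 - 2.0 / n_atoms))
        assert np.mean(fluct) == pytest.approx(expected, rel=0.02)

    def test_single_frame_rejected(self, rng):
        ens = CoordinateEnsemble(
            coords=rng.uniform(-1, 1, (1, 10, 3)),
            residue_numbers=np.arange(10),
            atom_names=np.array(["CA"] * 10),
        )
        with pytest.raises(ValueError, match="two frames"):
            rmsf(ens)


class TestRadiusOfGyration:
    def test_two_point_dumbbell(self):
        frame = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert radius_of_gyration(frame) == pytest.approx(1.0)

    def test_coincident_atoms_zero(self):
        assert radius_of_gyration(np.zeros((5, 3))) == pytest.approx(0.0)

    def test_uniform_ring(self):
        theta = np.linspace(0, 2 * np.pi, 500, endpoint=False)
        a = 1.7
        ring = np.column_stack([a * np.cos(theta), a * np.sin(theta), np.zeros_like(theta)])
        assert radius_of_gyration(ring) == pytest.approx(a, rel=1e-12)

    def test_mass_weighting(self):
        frame = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0.0, 0, 0]])
        # heavy central atom pulls Rg down relative to unit masses
        light = radius_of_gyration(frame, masses=np.ones(3))
        heavy = radius_of_gyration(frame, masses=np.array([1.0, 1.0, 100.0]))
        assert heavy < light

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            radius_of_gyration(np.ones((3, 3)), masses=np.zeros(3))


class TestPca:
    def test_planted_mode_dominates_with_expected_fraction(self):
        spec = planted_mode_spec(n_atoms=50, n_frames=1000, seed=3)
        result = pca(make_ensemble(spec))
        assert result.variance_fractions[0] == pytest.approx(0.75, abs=0.03)

    def test_planted_mode_direction_recovered(self):
        spec = planted_mode_spec(n_atoms=40, n_frames=1500, seed=4)
        result = pca(make_ensemble(spec))
        mode = spec.modes[0].ravel()
        cosine = abs(np.dot(result.eigenvectors[0], mode))
        assert cosine > 0.99

    def test_two_planted_modes_variance_split(self):
        from lamindyn.synthetic import rigid_body_basis

        reference = np.random.default_rng(1).uniform(-1, 1, (30, 3))
        modes = random_orthonormal_modes(
            30, 2, seed=11, exclude=rigid_body_basis(reference)
        )
        spec = EnsembleSpec(
            reference=reference,
            modes=modes,
            mode_variances=np.array([3.0, 1.0]),
            jitter_sigma=0.0,
            n_frames=10000,
            seed=12,
        )
        result = pca(make_ensemble(spec))
        assert result.variance_fractions[0] == pytest.approx(0.75, abs=0.02)

    def test_eigenvalue_sum_equals_total_variance(self):
        ens = jitter_ensemble(n_frames=50, n_atoms=12, sigma=0.1, seed=2)
        result = pca(ens)
        from lamindyn.ensemble import superpose_to_mean

        aligned, _ = superpose_to_mean(ens)
        flat = aligned.reshape(50, -1)
        total = np.sum(np.var(flat, axis=0, ddof=1))
        assert result.eigenvalues.sum() == pytest.approx(total, rel=1e-9)

    def test_isotropic_jitter_fractions_nearly_flat(self):
        ens = jitter_ensemble(n_frames=4000, n_atoms=10, sigma=0.05, seed=6)
        result = pca(ens)
        # 3N - 6 quasi-degenerate directions after removing rigid-body fit;
        # no direction should dominate
        assert result.variance_fractions[0] < 3.0 / (3 * 10)

    def test_orthonormal_eigenvectors(self):
        ens = jitter_ensemble(n_frames=40, n_atoms=8, sigma=0.1, seed=3)
        result = pca(ens)
        gram = result.eigenvectors @ result.eigenvectors.T
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_too_few_frames_rejected(self):
        ens = jitter_ensemble(n_frames=3, n_atoms=8, sigma=0.1)
        with pytest.raises(ValueError, match="more than 3 frames"):
            pca(ens)


class TestRigidMotionInvariance:
    def test_all_statistics_invariant(self):
        ens = jitter_ensemble(n_frames=60, n_atoms=15, sigma=0.08, seed=8)
        rot = Rotation.from_rotvec([0.5, 0.2, -0.9]).as_matrix()
        shift = np.array([3.0, -1.0, 2.0])
        moved = CoordinateEnsemble(
            coords=ens.coords @ rot.T + shift,
            residue_numbers=ens.residue_numbers,
            atom_names=ens.atom_names,
        )
        assert np.allclose(
            rmsd_series(ens, reference=0), rmsd_series(moved, reference=0), atol=1e-9
        )
        assert np.allclose(rmsf(ens), rmsf(moved), atol=1e-9)
        assert np.allclose(
            radius_of_gyration(ens), radius_of_gyration(moved), atol=1e-9
        )
        e1, e2 = pca(ens), pca(moved)
        assert np.allclose(e1.eigenvalues, e2.eigenvalues, atol=1e-9)


class TestPorcupine:
    def test_zero_scale_identical_models(self):
        spec = planted_mode_spec(n_atoms=20, n_frames=200, seed=1)
        result = pca(make_ensemble(spec))
        m1, m2 = porcupine_export(result, component=0, scale=0.0)
        assert np.allclose(m1, m2)

    def test_displacement_norm_is_scaled_sigma(self):
        spec = planted_mode_spec(n_atoms=20, n_frames=200, seed=1)
        result = pca(make_ensemble(spec))
        m1, m2 = porcupine_export(result, component=0, scale=2.5)
        norm = np.linalg.norm((m2 - m1).ravel())
        assert norm == pytest.approx(2.5 * np.sqrt(result.eigenvalues[0]), rel=1e-9)

    def test_displacement_direction_matches_planted_mode(self):
        spec = planted_mode_spec(n_atoms=30, n_frames=1500, seed=2)
        result = pca(make_ensemble(spec))
        m1, m2 = porcupine_export(result, component=0, scale=1.0)
        d = (m2 - m1).ravel()
        cosine = abs(np.dot(d / np.linalg.norm(d), spec.modes[0].ravel()))
        assert cosine > 0.99

    def test_component_out_of_range(self):
        spec = planted_mode_spec(n_atoms=10, n_frames=50, seed=0)
        result = pca(make_ensemble(spec))
        with pytest.raises(ValueError, match="out of range"):
            porcupine_export(result, component=10**6)
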