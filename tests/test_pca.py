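import numpy as np
import pytest

from conformap.pca import (align_ensemble, build_ensemble_core, fit_pca,
                           project, significant_modes, training_scores)
from conformap.structure import Selection, Structure
from conformap.superpose import CoreMap, InsufficientCoreError
from conformap.synth import TwoLobeParams, make_ensemble, make_two_lobe

from conftest import ca_structure, random_rigid_transform

FULL = Selection(ranges=((1, 180),))


def drop_residues(s, missing):
    atoms = [a for a in s.atoms if a.residue_number not in missing]
    return Structure(s.identifier, atoms)


@pytest.fixture(scope="module")
def theta_grid_ensemble():
    structures, truth = make_ensemble(list(range(0, 50, 5)), [0.0],
                                      noise_sd=0.0, seed=0)
    return structures, truth


@pytest.fixture(scope="module")
def two_param_ensemble():
    rng = np.random.default_rng(11)
    theta = rng.normal(0, 15, 30)
    phi = rng.normal(0, 4, 30)
    structures, truth = make_ensemble(theta, phi, noise_sd=0.2, seed=11)
    return structures, truth


class TestBuildEnsembleCore:
    def test_identical_members_full_selection(self):
        s, _ = make_two_lobe(TwoLobeParams())
        members = [Structure(f"m{i}", s.atoms) for i in range(5)]
        core = build_ensemble_core(members, FULL)
        assert core.size == 180

    def test_missing_residues_excluded_for_all(self):
        s, _ = make_two_lobe(TwoLobeParams())
        members = [Structure(f"m{i}", s.atoms) for i in range(4)]
        members[2] = drop_residues(Structure("m2", s.atoms), set(range(50, 56)))
        core = build_ensemble_core(members, FULL)
        assert core.size == 174
        for cm in core.cores.values():
            assert all(50 > k[1] or k[1] > 55 for k, _ in cm.pairs)

    def test_too_few_members(self):
        s, _ = make_two_lobe(TwoLobeParams())
        with pytest.raises(ValueError):
            build_ensemble_core([s, Structure("b", s.atoms)], FULL)

    def test_insufficient_core_lists_members(self):
        s, _ = make_two_lobe(TwoLobeParams())
        members = [Structure(f"m{i}", s.atoms) for i in range(3)]
        members[1] = drop_residues(Structure("m1", s.atoms), set(range(1, 176)))
        with pytest.raises(InsufficientCoreError, match="m1"):
            build_ensemble_core(members, FULL)


class TestAlignEnsemble:
    def test_rigid_copies_collapse_to_identical_rows(self):
        s, _ = make_two_lobe(TwoLobeParams(theta_open=20.0))
        rng = np.random.default_rng(0)
        members = []
        for i in range(5):
            R, t = random_rigid_transform(rng)
            members.append(Structure(f"m{i}", s.transformed(R, t).atoms))
        core = build_ensemble_core(members, FULL)
        matrix, converged = align_ensemble(core, members)
        assert converged
        spread = matrix.max(axis=0) - matrix.min(axis=0)
        assert spread.max() < 1e-6

    def test_two_members_equidistant_from_mean(self):
        from conformap.pca import EnsembleCore

        a, _ = make_two_lobe(TwoLobeParams(theta_open=0.0))
        b, _ = make_two_lobe(TwoLobeParams(theta_open=25.0))
        b = Structure("b", b.atoms)
        three = build_ensemble_core([a, b, Structure("c", a.atoms)], FULL)
        core = EnsembleCore(reference_id=a.identifier,
                            members=(a.identifier, "b"),
                            cores={a.identifier: three.cores[a.identifier],
                                   "b": three.cores["b"]},
                            selection=FULL)
        matrix, _ = align_ensemble(core, [a, b])
        mean = matrix.mean(axis=0)
        d = np.sqrt(((matrix - mean) ** 2).reshape(2, -1, 3).sum(-1).mean(1))
        assert d[0] == pytest.approx(d[1], abs=1e-9)

    def test_synthetic_ensemble_converges_quickly(self, two_param_ensemble):
        structures, _ = two_param_ensemble
        core = build_ensemble_core(structures, FULL)
        matrix, converged = align_ensemble(core, structures, max_iter=4)
        assert converged


class TestFitPCA:
    def test_identical_rows_zero_variance(self):
        row = np.arange(30.0)
        model = fit_pca(np.tile(row, (5, 1)))
        assert np.allclose(model.variances, 0.0)

    def test_single_dof_dominant_mode(self, theta_grid_ensemble):
        structures, truth = theta_grid_ensemble
        core = build_ensemble_core(structures, FULL)
        matrix, _ = align_ensemble(core, structures)
        model = fit_pca(matrix, opening=truth["theta_open"].to_numpy())
        frac = model.variances[0] / model.variances.sum()
        # one rigid degree of freedom; the rotation manifold's curvature
        # leaves a small second mode at this 45-degree spread
        assert frac >= 0.95
        assert model.variances[0] / model.variances[1] > 50

    def test_two_parameter_recovery(self, two_param_ensemble):
        structures, truth = two_param_ensemble
        core = build_ensemble_core(structures, FULL)
        matrix, _ = align_ensemble(core, structures)
        theta = truth["theta_open"].to_numpy()
        phi = truth["phi_twist"].to_numpy()
        model = fit_pca(matrix, opening=theta)
        scores = training_scores(model, matrix)
        assert significant_modes(model.variances) == 2
        assert abs(np.corrcoef(scores[:, 0], theta)[0, 1]) >= 0.95
        assert abs(np.corrcoef(scores[:, 1], phi)[0, 1]) >= 0.9

    def test_modes_orthonormal_and_variances_sorted(self, two_param_ensemble):
        structures, _ = two_param_ensemble
        core = build_ensemble_core(structures, FULL)
        matrix, _ = align_ensemble(core, structures)
        model = fit_pca(matrix)
        gram = model.modes @ model.modes.T
        np.testing.assert_allclose(gram, np.eye(len(model.modes)), atol=1e-8)
        assert np.all(np.diff(model.variances) <= 1e-9)
        total = ((matrix - matrix.mean(0)) ** 2).sum() / (len(matrix) - 1)
        assert model.variances.sum() == pytest.approx(total, rel=1e-6)

    def test_opening_sign_convention(self, theta_grid_ensemble):
        structures, truth = theta_grid_ensemble
        core = build_ensemble_core(structures, FULL)
        matrix, _ = align_ensemble(core, structures)
        theta = truth["theta_open"].to_numpy()
        model = fit_pca(matrix, opening=theta)
        scores = training_scores(model, matrix)
        assert scores[np.argmax(theta), 0] > 0

    def test_reconstruction_with_all_modes(self, two_param_ensemble):
        structures, _ = two_param_ensemble
        core = build_ensemble_core(structures, FULL)
        matrix, _ = align_ensemble(core, structures)
        model = fit_pca(matrix)
        scores = training_scores(model, matrix)
        recon = model.mean_coords.reshape(-1) + scores @ model.modes
        np.testing.assert_allclose(recon, matrix, atol=1e-6)

    def test_training_scores_zero_mean(self, two_param_ensemble):
        structures, _ = two_param_ensemble
        core = build_ensemble_core(structures, FULL)
        matrix, _ = align_ensemble(core, structures)
        model = fit_pca(matrix)
        scores = training_scores(model, matrix)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-8)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((2, 9)))


@pytest.fixture(scope="module")
def fitted(two_param_ensemble):
    structures, truth = two_param_ensemble
    core = build_ensemble_core(structures, FULL)
    matrix, _ = align_ensemble(core, structures)
    model = fit_pca(matrix, opening=truth["theta_open"].to_numpy())
    return structures, truth, core, matrix, model


class TestProject:
    def test_training_member_reproduced(self, fitted):
        structures, _, core, matrix, model = fitted
        scores = training_scores(model, matrix)
        i = 7
        proj = project(model, structures[i], core.cores[structures[i].identifier])
        np.testing.assert_allclose(proj.pc_values[:len(scores[i])], scores[i],
                                   atol=1e-6)

    def test_mean_projects_to_zero(self, fitted):
        *_, core, matrix, model = fitted
        from conformap.structure import AtomRecord
        pairs = core.cores[core.reference_id].pairs
        atoms = [AtomRecord("A", k[1], k[2], "ALA", "CA", "C", "", 1.0, 0.0,
                            tuple(model.mean_coords[i]))
                 for i, (k, _) in enumerate(pairs)]
        mean_structure = Structure("mean", atoms)
        proj = project(model, mean_structure, core.cores[core.reference_id])
        np.testing.assert_allclose(proj.pc_values, 0.0, atol=1e-9)

    def test_rigid_transform_invariance(self, fitted):
        structures, _, core, _, model = fitted
        s = structures[3]
        cm = core.cores[s.identifier]
        base = project(model, s, cm).pc_values
        rng = np.random.default_rng(9)
        R, t = random_rigid_transform(rng)
        moved = Structure(s.identifier, s.transformed(R, t).atoms)
        np.testing.assert_allclose(project(model, moved, cm).pc_values, base,
                                   atol=1e-6)

    def test_missing_core_residue_listed(self, fitted):
        structures, *_ , model = fitted
        _, _, core, _, _ = fitted
        s = structures[0]
        atoms = [a for a in s.atoms if a.residue_number != 90]
        broken = Structure(s.identifier, atoms)
        with pytest.raises(KeyError, match="90"):
            project(model, broken, core.cores[s.identifier])

    def test_held_out_theta_interpolates_on_pc1(self):
        structures, truth = make_ensemble(list(range(0, 44, 4)), [0.0],
                                          noise_sd=0.0, seed=3)
        core = build_ensemble_core(structures, FULL)
        matrix, _ = align_ensemble(core, structures)
        theta = truth["theta_open"].to_numpy()
        model = fit_pca(matrix, opening=theta)
        scores = training_scores(model, matrix)
        held, _ = make_two_lobe(TwoLobeParams(theta_open=22.0))
        held = Structure(structures[0].identifier, held.atoms)
        proj = project(model, held, core.cores[core.reference_id])
        lo = scores[theta == 20.0, 0][0]
        hi = scores[theta == 24.0, 0][0]
        assert min(lo, hi) < proj.pc_values[0] < max(lo, hi)


class TestSignificantModes:
    def test_pure_noise_reports_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 0.2, (30, 300))
        model = fit_pca(X)
        assert significant_modes(model.variances) == 0

    def test_clear_two_mode_spectrum(self):
        v = np.array([100.0, 40.0, 1.0, 0.9, 0.8, 0.7])
        assert significant_modes(v) == 2

    def test_all_zero(self):
        assert significant_modes(np.zeros(5)) == 0
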