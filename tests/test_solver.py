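"""Finite-element solver: patch tests, tangents, stages, constraints."""

import numpy as np
import pytest

from atflap.fixtures import patch_meshes
from atflap.material import FACIAL_SKIN, OgdenParameters, uniaxial_cauchy_stress
from atflap.solver import (
    RankDeficiencyError,
    SolverConfig,
    StageDefinition,
    count_zero_energy_modes,
    internal_forces,
    solve_stage,
    tangent_stiffness,
    von_mises,
)


@pytest.fixture(scope="module")
def single():
    return patch_meshes()["single"]


@pytest.fixture(scope="module")
def two_by_two():
    return patch_meshes()["two_by_two"]


class TestVonMises:
    def test_uniaxial(self):
        assert von_mises(np.diag([2.5, 0.0])) == pytest.approx(2.5)

    def test_pure_shear(self):
        s = np.array([[0.0, 1.2], [1.2, 0.0]])
        assert von_mises(s) == pytest.approx(1.2 * np.sqrt(3.0))

    def test_equibiaxial(self):
        assert von_mises(np.diag([3.0, 3.0])) == pytest.approx(3.0)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            von_mises(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestRigidMotion:
    def test_translation_force_free(self, two_by_two):
        u = np.tile([1.7, -2.3], (two_by_two.n_nodes, 1))
        f = internal_forces(two_by_two, u, FACIAL_SKIN)
        assert np.abs(f).max() < 1e-9

    def test_rotation_force_free(self, two_by_two):
        th = 0.4
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        u = two_by_two.nodes @ R.T - two_by_two.nodes
        f = internal_forces(two_by_two, u, FACIAL_SKIN)
        assert np.abs(f).max() < 1e-9

    def test_rotation_stress_free(self, single):
        th = -0.6
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        u = single.nodes @ R.T - single.nodes
        _, sig = internal_forces(single, u, FACIAL_SKIN, want_stress=True)
        assert np.abs(sig).max() < 1e-9


class TestTangent:
    def test_fd_consistency(self, single, rng):
        u = 0.05 * rng.standard_normal((single.n_nodes, 2))
        K = tangent_stiffness(single, u, FACIAL_SKIN).toarray()
        v = rng.standard_normal(u.size)
        h = 1e-4
        fp = internal_forces(single, u + h * v.reshape(-1, 2), FACIAL_SKIN)
        fm = internal_forces(single, u - h * v.reshape(-1, 2), FACIAL_SKIN)
        fd = (fp - fm).ravel() / (2 * h)
        Kv = K @ v
        scale = max(np.abs(Kv).max(), np.abs(fd).max(), 1e-12)
        assert np.abs(Kv - fd).max() / scale < 1e-5

    def test_symmetry(self, two_by_two, rng):
        u = 0.02 * rng.standard_normal((two_by_two.n_nodes, 2))
        K = tangent_stiffness(two_by_two, u, FACIAL_SKIN).toarray()
        assert np.abs(K - K.T).max() < 1e-8 * np.abs(K).max()

    def test_unconstrained_rank_deficiency(self, single):
        K = tangent_stiffness(
            single, np.zeros((single.n_nodes, 2)), FACIAL_SKIN
        )
        assert count_zero_energy_modes(K) == 3

    def test_stiffness_scales_with_modulus(self, single, rng):
        u = 0.03 * rng.standard_normal((single.n_nodes, 2))
        soft = FACIAL_SKIN
        stiff = OgdenParameters(
            mu=tuple(10.0 * m for m in soft.mu), alpha=soft.alpha
        )
        f1 = internal_forces(single, u, soft)
        f10 = internal_forces(single, u, stiff)
        assert np.allclose(f10, 10.0 * f1, rtol=1e-12, atol=1e-15)


def _uniaxial_stage(mesh, lam):
    """Stretch the square patch along x; free lateral contraction."""
    x = mesh.nodes[:, 0]
    x0, x1 = x.min(), x.max()
    y0 = mesh.nodes[:, 1].min()
    prescribed = {}
    for n in np.flatnonzero(np.isclose(x, x0)):
        prescribed[(int(n), 0)] = 0.0
    for n in np.flatnonzero(np.isclose(x, x1)):
        prescribed[(int(n), 0)] = (lam - 1.0) * (x1 - x0)
    for n in np.flatnonzero(np.isclose(mesh.nodes[:, 1], y0)):
        prescribed[(int(n), 1)] = 0.0
    return StageDefinition(tag="suture", prescribed=prescribed)


class TestPatchUniaxial:
    @pytest.mark.parametrize("lam", [1.15, 1.4])
    def test_single_element_matches_closed_form(self, single, lam):
        sol = solve_stage(single, FACIAL_SKIN, _uniaxial_stage(single, lam))
        assert sol.converged
        expected = float(uniaxial_cauchy_stress(lam, FACIAL_SKIN))
        sig = sol.gauss_stress.reshape(-1, 2, 2)
        assert np.allclose(sig[:, 0, 0], expected, rtol=1e-8)
        assert np.abs(sig[:, 1, 1]).max() < 1e-8 * expected
        assert np.abs(sig[:, 0, 1]).max() < 1e-8 * expected

    def test_patch_field_homogeneous(self, two_by_two):
        lam = 1.25
        sol = solve_stage(
            two_by_two, FACIAL_SKIN, _uniaxial_stage(two_by_two, lam)
        )
        expected = float(uniaxial_cauchy_stress(lam, FACIAL_SKIN))
        sig = sol.gauss_stress.reshape(-1, 2, 2)
        # homogeneous state reproduced across a multi-element patch
        assert sig[:, 0, 0].std() < 1e-8 * expected
        assert np.allclose(sol.nodal_von_mises, expected, rtol=1e-7)

    def test_compression_side(self, single):
        lam = 0.9
        sol = solve_stage(single, FACIAL_SKIN, _uniaxial_stage(single, lam))
        expected = float(uniaxial_cauchy_stress(lam, FACIAL_SKIN))
        assert expected < 0.0
        assert sol.gauss_stress.reshape(-1, 2, 2)[:, 0, 0] == pytest.approx(
            expected, rel=1e-8
        )


class TestStages:
    def test_stage_validation(self):
        with pytest.raises(ValueError):
            StageDefinition(tag="suture", ties=[(0, 1)]).validate()
        with pytest.raises(ValueError):
            StageDefinition(
                tag="release", prescribed={(0, 0): 1.0}
            ).validate()

    def test_unconstrained_stage_rank_deficient(self, single):
        with pytest.raises(RankDeficiencyError):
            solve_stage(single, FACIAL_SKIN, StageDefinition(tag="suture"))

    def test_tie_transform_binds_current_positions(self, two_by_two):
        # the constrained displacement map u = T q + u_tie makes any slave
        # node share its master's *current position*, even when the two
        # reference positions differ (stitched pairs are not coincident)
        from atflap.solver import _build_transform

        m = two_by_two
        x, y = m.nodes[:, 0], m.nodes[:, 1]
        corner00 = int(np.flatnonzero(np.isclose(x, 0) & np.isclose(y, 0))[0])
        corner01 = int(
            np.flatnonzero(np.isclose(x, 0) & np.isclose(y, y.max()))[0]
        )
        corner10 = int(
            np.flatnonzero(np.isclose(x, x.max()) & np.isclose(y, 0))[0]
        )
        stage = StageDefinition(
            tag="release",
            ties=[(corner10, corner01)],
            fixed_nodes=np.array([corner00]),
        )
        T, _, u_tie, _, _ = _build_transform(m, stage)
        rng = np.random.default_rng(5)
        for _ in range(3):
            q = rng.standard_normal(T.shape[1])
            u = (T @ q + u_tie).reshape(-1, 2)
            pa = m.nodes[corner10] + u[corner10]
            pb = m.nodes[corner01] + u[corner01]
            assert np.allclose(pa, pb, atol=1e-12)
            assert np.allclose(u[corner00], 0.0)


class TestMiniAT:
    def test_two_stage_run(self, mini_mesh):
        from atflap.solver import run_suture_then_release

        sut, rel = run_suture_then_release(
            mini_mesh, FACIAL_SKIN, SolverConfig()
        )
        assert sut.converged and rel.converged
        # release relaxes the peak stress reached under full prescription
        assert rel.max_von_mises < sut.max_von_mises
        # tied pairs stay closed
        from atflap.mesh import closure_plan

        plan = closure_plan(mini_mesh)
        X = mini_mesh.nodes
        for a, b in plan.ties:
            gap = np.linalg.norm(
                (X[a] + rel.u[a]) - (X[b] + rel.u[b])
            )
            assert gap < 1e-6
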