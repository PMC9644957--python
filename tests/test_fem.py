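"""Tet4 elasticity solver verification: patch test, oracles, invariants."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ichthyofea import fem, skull


MAT = fem.Material()


def _linear_field(nodes: np.ndarray, A: np.ndarray) -> np.ndarray:
    return nodes @ A.T


def _voigt_from_gradient(A: np.ndarray, material: fem.Material) -> np.ndarray:
    eps = 0.5 * (A + A.T)
    strain = np.array([eps[0, 0], eps[1, 1], eps[2, 2], 2 * eps[0, 1], 2 * eps[1, 2], 2 * eps[2, 0]])
    return fem.isotropic_elasticity_matrix(material) @ strain


class TestAssembly:
    def test_translation_invariance_row_sums_zero(self):
        mesh = skull.box_mesh((1, 1, 1))
        K = fem.assemble_stiffness(mesh, MAT)
        assert np.abs(K.sum(axis=1)).max() < 1e-9 * abs(K.diagonal()).max()

    def test_exactly_six_rigid_body_modes(self):
        mesh = skull.box_mesh((2, 2, 2), perturb=0.15, seed=3)
        K = fem.assemble_stiffness(mesh, MAT).toarray()
        w = np.linalg.eigvalsh(K)
        scale = w.max()
        assert (np.abs(w[:6]) < 1e-9 * scale).all()
        assert w[6] > 1e-6 * scale

    def test_stiffness_linear_in_youngs_modulus(self):
        mesh = skull.box_mesh((2, 1, 1))
        K1 = fem.assemble_stiffness(mesh, fem.Material(1000.0, 0.3))
        K2 = fem.assemble_stiffness(mesh, fem.Material(2000.0, 0.3))
        assert abs(K2 - 2 * K1).max() < 1e-9 * abs(K1).max()

    def test_inverted_element_detected(self):
        mesh = skull.box_mesh((1, 1, 1))
        mesh.elements[0] = mesh.elements[0][[1, 0, 2, 3]]
        with pytest.raises(fem.SolverError, match="element 0"):
            fem.assemble_stiffness(mesh, MAT)


class TestPatchTest:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_linear_field_reproduced_exactly(self, seed):
        """tet4 must be exact for any linear displacement field (patch test)."""
        rng = np.random.default_rng(seed)
        A = rng.uniform(-1e-3, 1e-3, (3, 3))
        mesh = skull.box_mesh((3, 3, 3), perturb=0.2, seed=7)
        u_exact = _linear_field(mesh.nodes, A)
        surf = mesh.surface_nodes()
        case = fem.LoadCase(
            nodal_forces={},
            fixed_nodes=np.array([], dtype=int),
            prescribed={int(n): u_exact[n] for n in surf},
        )
        sol = fem.solve(mesh, MAT, case)
        np.testing.assert_allclose(sol.displacements, u_exact, atol=1e-12)
        expected = np.broadcast_to(_voigt_from_gradient(A, MAT), sol.element_stress.shape)
        np.testing.assert_allclose(sol.element_stress, expected, atol=1e-9 * MAT.youngs_E)


class TestSolveOracles:
    def test_dense_solve_oracle_small_mesh(self):
        """Sparse path matches a dense direct solve on a <=500-freedom mesh."""
        mesh = skull.box_mesh((4, 3, 3), (4.0, 1.0, 1.0), perturb=0.1, seed=2)
        assert 3 * mesh.n_nodes <= 500 + 3 * 16  # mesh is small; oracle on reduced system
        wall = np.flatnonzero(mesh.nodes[:, 0] < 1e-12)
        tip = np.flatnonzero(mesh.nodes[:, 0] > 4.0 - 1e-12)
        forces = {int(n): np.array([0.0, 0.0, -1.0 / len(tip)]) for n in tip}
        case = fem.LoadCase(nodal_forces=forces, fixed_nodes=wall)
        sol = fem.solve(mesh, MAT, case)

        K = fem.assemble_stiffness(mesh, MAT).toarray()
        f = case.force_array(mesh.n_nodes).ravel()
        fixed = (3 * wall[:, None] + np.arange(3)).ravel()
        free = np.setdiff1d(np.arange(3 * mesh.n_nodes), fixed)
        u_dense = np.zeros(3 * mesh.n_nodes)
        u_dense[free] = np.linalg.solve(K[np.ix_(free, free)], f[free])
        scale = np.abs(u_dense).max()
        assert np.abs(sol.displacements.ravel() - u_dense).max() < 1e-8 * scale

    def test_iterative_path_matches_direct(self):
        mesh = skull.box_mesh((4, 2, 2), (4.0, 1.0, 1.0))
        wall = np.flatnonzero(mesh.nodes[:, 0] < 1e-12)
        tip = np.flatnonzero(mesh.nodes[:, 0] > 4.0 - 1e-12)
        forces = {int(n): np.array([0.0, 0.0, -0.1]) for n in tip}
        case = fem.LoadCase(nodal_forces=forces, fixed_nodes=wall)
        direct = fem.solve(mesh, MAT, case)
        iterative = fem.solve(mesh, MAT, case, use_iterative=True)
        np.testing.assert_allclose(
            iterative.displacements, direct.displacements, atol=1e-8 * np.abs(direct.displacements).max()
        )

    def test_axial_bar_stress_approaches_f_over_a(self):
        """Prismatic bar under axial end load: mid-bar von Mises -> F/A."""
        F, area = 10.0, 1.0
        errs = []
        for n in (2, 4):
            mesh = skull.box_mesh((6 * n, n, n), (6.0, 1.0, 1.0))
            wall = np.flatnonzero(mesh.nodes[:, 0] < 1e-12)
            tip = np.flatnonzero(mesh.nodes[:, 0] > 6.0 - 1e-12)
            forces = {int(nd): np.array([F / len(tip), 0.0, 0.0]) for nd in tip}
            sol = fem.solve(mesh, MAT, fem.LoadCase(nodal_forces=forces, fixed_nodes=wall))
            mid = np.abs(mesh.element_centroids()[:, 0] - 3.0) < 0.5
            errs.append(abs(np.mean(sol.von_mises[mid]) - F / area) / (F / area))
        assert errs[-1] < 0.02
        assert errs[-1] <= errs[0]

    def test_global_equilibrium(self, comparison_default):
        """Reactions balance applied loads on the production skull solves."""
        _, results = comparison_default
        for res in results.values():
            for pos, sol in res["fields"].items():
                case = res["cases"][pos]
                total = np.sum(list(case.nodal_forces.values()), axis=0)
                resid = np.abs(sol.reactions.sum(axis=0) + total)
                assert resid.max() <= 1e-6 * np.abs(
                    np.linalg.norm(list(case.nodal_forces.values()), axis=1)
                ).sum()

    def test_bilateral_load_gives_mirror_symmetric_von_mises(self, mini_params, mini_policy):
        """Paired elements across the symmetry plane agree within 1%."""
        from ichthyofea import pipeline

        res = pipeline.simulate_morphotype(mini_params, "M1399", ("mid",), policy=mini_policy)
        mesh, sol = res["mesh"], res["fields"]["mid"]
        cent = mesh.element_centroids()
        # pair elements by mirrored centroid
        from scipy.spatial import cKDTree

        d, idx = cKDTree(cent).query(cent * [1, -1, 1], k=1)
        ok = d < 1e-6
        assert ok.mean() > 0.99  # nearly all elements have a mirror partner
        vm = sol.von_mises
        lateral = ok & (np.abs(cent[:, 1]) > 1e-9)
        # guard the denominator with the field scale so roundoff noise in
        # essentially unstressed tip elements does not masquerade as asymmetry
        denom = np.maximum(np.maximum(vm[lateral], vm[idx[lateral]]), 1e-6 * vm.max())
        rel = np.abs(vm[lateral] - vm[idx[lateral]]) / denom
        assert rel.max() < 0.01


class TestVonMises:
    def test_pure_shear_identity(self):
        """A pure shear state tau gives von Mises sqrt(3)*tau."""
        tau = 0.7
        vm = fem.von_mises(np.array([0.0, 0.0, 0.0, tau, 0.0, 0.0]))
        assert vm == pytest.approx(np.sqrt(3.0) * tau, rel=1e-12)

    def test_imposed_shear_displacement_field(self):
        mesh = skull.box_mesh((2, 2, 2))
        gamma = 1e-3
        u = np.zeros((mesh.n_nodes, 3))
        u[:, 0] = gamma * mesh.nodes[:, 2]
        stress = fem.stress_from_displacement(mesh, MAT, u)
        mu = MAT.youngs_E / (2 * (1 + MAT.poisson_nu))
        tau = mu * gamma
        np.testing.assert_allclose(fem.von_mises(stress), np.sqrt(3) * tau, rtol=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=6, max_size=6))
    def test_von_mises_nonnegative(self, voigt):
        assert fem.von_mises(np.array(voigt)) >= 0.0


class TestConstraintErrors:
    def test_too_few_fixed_nodes(self):
        mesh = skull.box_mesh((1, 1, 1))
        case = fem.LoadCase(nodal_forces={0: np.ones(3)}, fixed_nodes=np.array([7]))
        with pytest.raises(fem.SolverError, match="fixed nodes"):
            fem.solve(mesh, MAT, case)

    def test_collinear_fixed_nodes(self):
        mesh = skull.box_mesh((3, 1, 1), (3.0, 1.0, 1.0))
        on_axis = np.flatnonzero((np.abs(mesh.nodes[:, 1]) < 1e-12) & (np.abs(mesh.nodes[:, 2]) < 1e-12))
        assert len(on_axis) >= 3
        case = fem.LoadCase(nodal_forces={}, fixed_nodes=on_axis, prescribed={})
        case.nodal_forces = {int(np.flatnonzero(mesh.nodes[:, 2] > 0.99)[0]): np.array([0, 1.0, 0])}
        with pytest.raises(fem.SolverError, match="collinear"):
            fem.solve(mesh, MAT, case)

    def test_loaded_and_fixed_overlap_rejected(self):
        with pytest.raises(ValueError, match="loaded and fixed"):
            fem.LoadCase(nodal_forces={0: np.ones(3)}, fixed_nodes=np.array([0, 1, 2]))


class TestRegionSummary:
    def test_uniform_bar_all_regions_identical(self):
        mesh = skull.box_mesh((6, 2, 2), (6.0, 1.0, 1.0))
        # split elements into two artificial regions along x
        mesh.region_ids = (mesh.element_centroids()[:, 0] > 3.0).astype(np.int8)
        wall = np.flatnonzero(mesh.nodes[:, 0] < 1e-12)
        tip = np.flatnonzero(mesh.nodes[:, 0] > 6.0 - 1e-12)
        forces = {int(n): np.array([1.0 / len(tip), 0, 0]) for n in tip}
        case = fem.LoadCase(nodal_forces=forces, fixed_nodes=wall)
        sol = fem.solve(mesh, MAT, case)
        summary = fem.region_summary(sol, mesh, case)
        means = [s["mean"] for s in (summary["rostrum"], summary["nasal"]) if s]
        assert len(means) == 2
        assert means[0] == pytest.approx(means[1], rel=0.02)

    def test_doubling_loads_doubles_statistics(self, mini_params, mini_policy):
        from ichthyofea import pipeline

        res = pipeline.simulate_morphotype(mini_params, "M1399", ("posterior",), policy=mini_policy)
        mesh, case = res["mesh"], res["cases"]["posterior"]
        base = res["summaries"]["posterior"]
        doubled_case = fem.LoadCase(
            nodal_forces={n: 2.0 * v for n, v in case.nodal_forces.items()},
            fixed_nodes=case.fixed_nodes,
            label="x2",
        )
        sol2 = fem.solve(mesh, fem.Material(), doubled_case)
        s2 = fem.region_summary(sol2, mesh, doubled_case)
        for region, s in base.items():
            if s is None:
                continue
            for stat in ("mean", "median", "p95", "max"):
                assert s2[region][stat] == pytest.approx(2.0 * s[stat], rel=1e-9)

    def test_empty_region_reported_absent(self):
        mesh = skull.box_mesh((2, 2, 2))
        mesh.region_ids[:] = 0  # everything in region 0; others empty
        wall = np.flatnonzero(mesh.nodes[:, 0] < 1e-12)
        forces = {int(np.flatnonzero(mesh.nodes[:, 0] > 0.99)[0]): np.array([1.0, 0, 0])}
        sol = fem.solve(mesh, fem.Material(), fem.LoadCase(nodal_forces=forces, fixed_nodes=wall))
        summary = fem.region_summary(sol, mesh)
        assert summary["nasal"] is None
        assert summary["rostrum"] is not None
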