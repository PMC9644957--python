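"""Parametric skull generator: geometry, node sets, symmetry, truncation."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ichthyofea import skull


def _with(params, **kw):
    return dataclasses.replace(params, **kw)


class TestParamsValidation:
    def test_rejects_non_positive_dimensions(self, mini_params):
        with pytest.raises(skull.MeshingError, match="cranium_height"):
            _with(mini_params, cranium_height=-1.0)

    def test_rejects_orbit_wider_than_cranium(self, mini_params):
        with pytest.raises(skull.MeshingError, match="orbit_diameter"):
            _with(mini_params, orbit_diameter=40.0)

    def test_too_coarse_edge_cites_thickness_invariant(self, mini_params):
        with pytest.raises(skull.MeshingError, match="three\\s+elements thick"):
            _with(mini_params, target_edge_length=10.0)

    def test_rostrum_wider_than_cranium_rejected(self, mini_params):
        with pytest.raises(skull.MeshingError, match="rostrum_base_width"):
            _with(mini_params, rostrum_base_width=50.0)


class TestMeshGeometry:
    def test_positive_volumes_and_connected(self, mini_mesh):
        assert (mini_mesh.element_volumes() > 0).all()
        assert mini_mesh.is_connected()

    def test_default_meshes_meet_element_budget(self, robust_params, gracile_params):
        for p in (robust_params, gracile_params):
            mesh = skull.build_skull_mesh(p)
            assert mesh.n_elements >= 20_000

    def test_volume_matches_analytic_within_2pct(self, robust_params, gracile_params):
        # at default preset granularity (the orbital-void staircase dominates
        # the residual; finer meshes reduce it, see the convergence test)
        for p in (robust_params, gracile_params):
            va = skull.analytic_volume(p)
            mesh = skull.build_skull_mesh(p)
            assert abs(mesh.total_volume() - va) / va < 0.02

    def test_volume_converges_monotonically(self, mini_params):
        # without the orbital voids the boundary is smooth and the inscribed
        # polyhedron deficit must shrink monotonically under refinement
        errs = []
        va = None
        for h in (4.0, 3.0, 2.2):
            p = _with(mini_params, target_edge_length=h)
            if va is None:
                va = skull.analytic_volume(p)
            m = skull.build_skull_mesh(p, carve_orbits=False)
            # reference without voids: full ellipse integral
            xs = (np.arange(50_000) + 0.5) * (p.total_skull_length / 50_000)
            a, b = p.half_dims(xs)
            v_ref = np.pi * float((a * b).sum()) * (p.total_skull_length / 50_000)
            errs.append(abs(m.total_volume() - v_ref) / v_ref)
        assert errs[0] > errs[1] > errs[2]

    def test_watertight_boundary(self, mini_mesh):
        # every boundary edge is shared by exactly two boundary triangles and
        # the surface integral of x.n recovers the volume (divergence theorem)
        tris = mini_mesh.surface_triangles()
        edges = np.sort(tris[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert (counts == 2).all()
        v = mini_mesh.nodes[tris]
        cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])  # 2*area*normal
        flux = (v.mean(axis=1) * cross / 2.0).sum() / 3.0
        assert flux == pytest.approx(mini_mesh.total_volume(), rel=1e-9)

    def test_aspect_ratio_bound_reported(self, mini_mesh):
        q = mini_mesh.quality_report(aspect_bound=8.0)
        assert q["n_aspect_violations"] == 0
        # violations are reported, not silently accepted
        q_tight = mini_mesh.quality_report(aspect_bound=1.2)
        assert q_tight["n_aspect_violations"] > 0
        assert len(q_tight["aspect_violations"]) == q_tight["n_aspect_violations"]

    def test_determinism(self, mini_params):
        m1 = skull.build_skull_mesh(mini_params)
        m2 = skull.build_skull_mesh(mini_params)
        np.testing.assert_array_equal(m1.nodes, m2.nodes)
        np.testing.assert_array_equal(m1.elements, m2.elements)
        for name in m1.node_sets:
            np.testing.assert_array_equal(m1.node_sets[name], m2.node_sets[name])


class TestMorphotypePresets:
    def test_robust_rostrum_longer_than_posterior_cranium(self, robust_params):
        mesh = skull.build_skull_mesh(robust_params)
        cx = mesh.element_centroids()[:, 0]
        rost = np.concatenate([mesh.region_elements("rostrum"), mesh.region_elements("nasal")])
        cran = np.concatenate(
            [mesh.region_elements(r) for r in ("posterior_cranium", "orbital", "palate")]
        )
        rost_extent = cx[rost].max() - cx[rost].min()
        cran_extent = cx[cran].max() - cx[cran].min()
        assert rost_extent > cran_extent

    def test_gracile_rostrum_relatively_more_slender(self, robust_params, gracile_params):
        ratio_robust = robust_params.rostrum_base_height / robust_params.cranium_height
        ratio_gracile = gracile_params.rostrum_base_height / gracile_params.cranium_height
        assert ratio_gracile < ratio_robust


class TestNodeSets:
    def test_bite_sets_have_exactly_twenty_nodes(self, mini_mesh):
        for name in ("bite_anterior", "bite_mid", "bite_posterior"):
            assert len(mini_mesh.node_sets[name]) == 20

    def test_basicranium_ten_per_side(self, mini_mesh):
        assert len(mini_mesh.node_sets["basicranium_left"]) == 10
        assert len(mini_mesh.node_sets["basicranium_right"]) == 10

    def test_bilateral_sets_paired_with_equal_cardinality(self, mini_mesh):
        lefts = [n for n in mini_mesh.node_sets if n.endswith("_left")]
        assert lefts
        for name in lefts:
            right = name[: -len("_left")] + "_right"
            assert right in mini_mesh.node_sets
            assert len(mini_mesh.node_sets[right]) == len(mini_mesh.node_sets[name])

    def test_every_set_node_exists_and_mirrors_onto_mesh_node(self, mini_mesh):
        mirror = mini_mesh.mirror_map()
        for name, ids in mini_mesh.node_sets.items():
            assert ids.max() < mini_mesh.n_nodes
            mirrored = mirror[ids]
            np.testing.assert_allclose(
                mini_mesh.nodes[mirrored] * [1, -1, 1], mini_mesh.nodes[ids], atol=1e-9
            )

    def test_all_regions_populated(self, mini_mesh):
        for region in skull.REGION_NAMES:
            assert len(mini_mesh.region_elements(region)) > 0


class TestTruncation:
    def test_keep_one_is_identity(self, mini_mesh):
        out = skull.truncate_rostrum(mini_mesh, 1.0)
        assert out.n_elements == mini_mesh.n_elements

    def test_truncation_removes_anterior_elements_only(self, mini_params, mini_mesh):
        keep = 0.75
        out = skull.truncate_rostrum(mini_mesh, keep)
        assert out.n_elements < mini_mesh.n_elements
        x_cut = keep * mini_params.total_skull_length
        assert out.element_centroids()[:, 0].max() < x_cut
        # the count matches a direct census of centroids on both sides of the cut
        expected = int((mini_mesh.element_centroids()[:, 0] < x_cut).sum())
        assert out.n_elements == expected

    def test_posterior_sets_unchanged_and_anterior_bite_relocated(self, mini_params, mini_mesh):
        out = skull.truncate_rostrum(mini_mesh, 0.75)
        for name in ("basicranium_left", "basicranium_right"):
            before = np.sort(mini_mesh.nodes[mini_mesh.node_sets[name]], axis=0)
            after = np.sort(out.nodes[out.node_sets[name]], axis=0)
            np.testing.assert_allclose(before, after)
        tip_before = mini_mesh.nodes[mini_mesh.node_sets["bite_anterior"], 0].max()
        tip_after = out.nodes[out.node_sets["bite_anterior"], 0].max()
        assert tip_after < tip_before
        # relocated within one element of the new anterior limit
        assert tip_after <= 0.75 * mini_params.total_skull_length + mini_params.target_edge_length

    def test_cut_through_cranium_rejected(self, mini_mesh):
        with pytest.raises(ValueError, match="cranium"):
            skull.truncate_rostrum(mini_mesh, 0.3)

    def test_bad_fraction_rejected(self, mini_mesh):
        with pytest.raises(ValueError):
            skull.truncate_rostrum(mini_mesh, 0.0)


class TestBoxMesh:
    def test_box_volume_exact(self):
        m = skull.box_mesh((3, 2, 2), (3.0, 1.0, 2.0))
        assert m.total_volume() == pytest.approx(6.0, rel=1e-12)

    def test_perturbed_box_keeps_positive_volumes(self):
        m = skull.box_mesh((3, 3, 3), perturb=0.2, seed=1)
        assert (m.element_volumes() > 0).all()
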