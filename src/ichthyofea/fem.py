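"""Small-deformation linear-elastic finite-element solver on tet4 meshes.

Constant-strain (linear, 4-node) tetrahedra, homogeneous isotropic material,
constraints by freedom elimination so reaction forces are recovered exactly.
Stress is evaluated per element (single-point, exact for the constant strain
of a tet4) and summarised as the von Mises scalar

    s_vm = sqrt(0.5*[(s11-s22)^2 + (s22-s33)^2 + (s33-s11)^2]
                + 3*(s12^2 + s23^2 + s31^2)).

Units follow the consistent mm-N-MPa system used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "Material",
    "LoadCase",
    "StressField",
    "SolverError",
    "assemble_stiffness",
    "solve",
    "region_summary",
    "von_mises",
    "isotropic_elasticity_matrix",
    "make_bite_load_case",
]

# Voigt strain order: (e_xx, e_yy, e_zz, g_xy, g_yz, g_zx), engineering shears.
VOIGT = ((0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (2, 0))


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class Material:
    """Homogeneous isotropic linear-elastic material.

    Defaults are cortical-bone values used for comparative cranial models:
    E = 15,000 MPa, nu = 0.29.
    """

    youngs_E: float = 15_000.0
    poisson_nu: float = 0.29

    def __post_init__(self) -> None:
        if not self.youngs_E > 0:
            raise ValueError(f"Young's modulus must be > 0, got {self.youngs_E!r}")
        if not -1.0 < self.poisson_nu < 0.5:
            raise ValueError(f"Poisson's ratio must lie in (-1, 0.5), got {self.poisson_nu!r}")


@dataclass
class LoadCase:
    """Nodal forces plus fully fixed node sets for one bite simulation."""

    nodal_forces: dict[int, np.ndarray]
    fixed_nodes: np.ndarray
    label: str = ""
    prescribed: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fixed_nodes = np.unique(np.asarray(self.fixed_nodes, dtype=np.int64))
        if self.fixed_nodes.size == 0 and not self.prescribed:
            raise ValueError("load case must fix at least one node")
        overlap = set(int(n) for n in self.fixed_nodes) & set(self.nodal_forces)
        if overlap:
            raise ValueError(f"nodes both loaded and fixed: {sorted(overlap)[:10]}")

    @property
    def loaded_nodes(self) -> np.ndarray:
        return np.array(sorted(self.nodal_forces), dtype=np.int64)

    def force_array(self, n_nodes: int) -> np.ndarray:
        f = np.zeros((n_nodes, 3))
        for node, vec in self.nodal_forces.items():
            f[node] += vec
        return f


@dataclass
class StressField:
    """Solution of one load case."""

    displacements: np.ndarray  # (N, 3) mm
    element_stress: np.ndarray  # (M, 6) MPa, Voigt order
    von_mises: np.ndarray  # (M,) MPa
    reaction_nodes: np.ndarray  # (k,)
    reactions: np.ndarray  # (k, 3) N
    label: str = ""

    def stress_tensor(self) -> np.ndarray:
        """Per-element symmetric 3x3 stress tensors."""
        s = self.element_stress
        t = np.zeros((len(s), 3, 3))
        t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = s[:, 0], s[:, 1], s[:, 2]
        t[:, 0, 1] = t[:, 1, 0] = s[:, 3]
        t[:, 1, 2] = t[:, 2, 1] = s[:, 4]
        t[:, 2, 0] = t[:, 0, 2] = s[:, 5]
        return t


def isotropic_elasticity_matrix(material: Material) -> np.ndarray:
    E, nu = material.youngs_E, material.poisson_nu
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def von_mises(stress_voigt: np.ndarray) -> np.ndarray:
    s = np.asarray(stress_voigt, dtype=float)
    sx, sy, sz, txy, tyz, tzx = (s[..., i] for i in range(6))
    return np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2) + 3.0 * (txy**2 + tyz**2 + tzx**2)
    )


def _element_b_matrices(nodes: np.ndarray, elements: np.ndarray):
    """Strain-displacement matrices and volumes for all tets (vectorised)."""
    x = nodes[elements]  # (M, 4, 3)
    d = np.swapaxes(x[:, 1:] - x[:, :1], 1, 2)  # (M, 3, 3), columns = edges
    det = np.linalg.det(d)
    if (det <= 0).any():
        bad = int(np.argmin(det))
        raise SolverError(f"inverted element {bad}: non-positive Jacobian ({det[bad] / 6.0:.3g} mm^3)")
    vol = det / 6.0
    dinv = np.linalg.inv(d)  # rows are grad(lambda_1..3)
    grads = np.empty((len(elements), 4, 3))
    grads[:, 1:] = dinv
    grads[:, 0] = -dinv.sum(axis=1)

    B = np.zeros((len(elements), 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        B[:, 0, 3 * a + 0] = gx
        B[:, 1, 3 * a + 1] = gy
        B[:, 2, 3 * a + 2] = gz
        B[:, 3, 3 * a + 0] = gy
        B[:, 3, 3 * a + 1] = gx
        B[:, 4, 3 * a + 1] = gz
        B[:, 4, 3 * a + 2] = gy
        B[:, 5, 3 * a + 0] = gz
        B[:, 5, 3 * a + 2] = gx
    return B, vol


def assemble_stiffness(mesh, material: Material) -> sp.csr_matrix:
    """Global stiffness matrix (3N x 3N), symmetric positive-semidefinite with
    exactly the six rigid-body zero-energy modes before constraints."""
    B, vol = _element_b_matrices(mesh.nodes, mesh.elements)
    C = isotropic_elasticity_matrix(material)
    Ke = np.einsum("mia,ij,mjb,m->mab", B, C, B, vol, optimize=True)  # (M, 12, 12)

    dof = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


def _check_constraints(mesh, fixed: np.ndarray) -> None:
    if fixed.size < 3:
        raise SolverError(
            f"only {fixed.size} fixed nodes: the constrained system is singular; "
            "at least three non-collinear fully fixed nodes are required"
        )
    pts = mesh.nodes[fixed]
    centred = pts - pts.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[1] < 1e-9 * max(1.0, s[0]):
        raise SolverError("all fixed nodes are collinear: rigid rotation about their axis is unconstrained")


def solve(mesh, material: Material, load_case: LoadCase, use_iterative: bool | None = None) -> StressField:
    """Solve K u = f with fixed freedoms eliminated; return displacements,
    per-element stress tensors, von Mises field and reaction forces."""
    n = mesh.n_nodes
    K = assemble_stiffness(mesh, material)
    f = load_case.force_array(n).ravel()

    fixed_nodes = load_case.fixed_nodes
    prescribed = np.zeros(3 * n)
    pre_nodes = np.array(sorted(load_case.prescribed), dtype=np.int64)
    for node, u in load_case.prescribed.items():
        prescribed[3 * node : 3 * node + 3] = u
    all_fixed = np.unique(np.concatenate([fixed_nodes, pre_nodes])) if pre_nodes.size else fixed_nodes
    _check_constraints(mesh, all_fixed)

    fixed_dofs = (3 * all_fixed[:, None] + np.arange(3)).ravel()
    free = np.ones(3 * n, dtype=bool)
    free[fixed_dofs] = False

    Kff = K[free][:, free].tocsc()
    rhs = f[free] - K[free][:, ~free] @ prescribed[~free]

    u = prescribed.copy()
    if use_iterative:
        diag = Kff.diagonal()
        M = sp.diags(1.0 / np.where(diag > 0, diag, 1.0))
        uf, info = spla.cg(Kff, rhs, rtol=1e-10, atol=0.0, maxiter=20 * Kff.shape[0], M=M)
        if info != 0:
            res = np.linalg.norm(Kff @ uf - rhs) / max(np.linalg.norm(rhs), 1e-30)
            raise SolverError(f"conjugate-gradient solver did not converge (info={info}, residual {res:.3g})")
    else:
        try:
            lu = spla.splu(Kff)
            uf = lu.solve(rhs)
        except RuntimeError as exc:  # singular factor
            raise SolverError(
                f"constrained system is singular ({exc}); check that the load case "
                "constrains all rigid-body modes"
            ) from exc
        if use_iterative is None and not np.isfinite(uf).all():
            raise SolverError("direct solve produced non-finite displacements")
    u[free] = uf

    # reactions at fixed freedoms
    r = (K @ u - f)[fixed_dofs].reshape(-1, 3)

    B, _ = _element_b_matrices(mesh.nodes, mesh.elements)
    ue = u.reshape(n, 3)[mesh.elements].reshape(-1, 12)
    strain = np.einsum("mij,mj->mi", B, ue)
    stress = strain @ isotropic_elasticity_matrix(material).T

    return StressField(
        displacements=u.reshape(n, 3),
        element_stress=stress,
        von_mises=von_mises(stress),
        reaction_nodes=all_fixed,
        reactions=r,
        label=load_case.label,
    )


def stress_from_displacement(mesh, material: Material, u: np.ndarray) -> np.ndarray:
    """Per-element Voigt stress for an imposed displacement field (N, 3)."""
    B, _ = _element_b_matrices(mesh.nodes, mesh.elements)
    ue = np.asarray(u).reshape(mesh.n_nodes, 3)[mesh.elements].reshape(-1, 12)
    return np.einsum("mij,mj->mi", B, ue) @ isotropic_elasticity_matrix(material).T


def region_summary(
    field_: StressField,
    mesh,
    load_case: LoadCase | None = None,
    exclude_touching: bool = True,
) -> dict[str, dict | None]:
    """Volume-weighted von Mises statistics per labelled anatomical region.

    Elements touching loaded or fixed nodes are excluded from the statistics
    (and counted separately) to avoid constraint-singularity artefacts; an
    empty region reports ``None`` rather than zeros.
    """
    vols = mesh.element_volumes()
    vm = field_.von_mises

    excluded = np.zeros(mesh.n_elements, dtype=bool)
    if exclude_touching and load_case is not None:
        special = np.zeros(mesh.n_nodes, dtype=bool)
        special[load_case.fixed_nodes] = True
        if load_case.nodal_forces:
            special[list(load_case.nodal_forces)] = True
        excluded = special[mesh.elements].any(axis=1)

    out: dict[str, dict | None] = {}
    for name in mesh.region_names:
        idx = mesh.region_elements(name)
        if idx.size == 0:
            out[name] = None
            continue
        use = idx[~excluded[idx]]
        n_excl = int(idx.size - use.size)
        if use.size == 0:
            out[name] = None
            continue
        w = vols[use]
        v = vm[use]
        order = np.argsort(v)
        cw = np.cumsum(w[order]) / w.sum()
        out[name] = {
            "mean": float(np.average(v, weights=w)),
            "median": float(v[order][np.searchsorted(cw, 0.5)]),
            "p95": float(v[order][min(np.searchsorted(cw, 0.95), len(v) - 1)]),
            "max": float(v.max()),
            "volume": float(w.sum()),
            "n_elements": int(use.size),
            "n_excluded": n_excl,
        }
    return out


def make_bite_load_case(mesh, force_vectors, bite_set: str, label: str = "") -> LoadCase:
    """Combine muscle force vectors with the constraint sets of one bite position.

    Constraints: both basicranium patches plus the named bite node set, all
    with zero degrees of freedom (fully fixed), simulating bilateral biting.
    """
    for required in ("basicranium_left", "basicranium_right", bite_set):
        if required not in mesh.node_sets:
            raise KeyError(f"mesh lacks node set {required!r}")
    forces: dict[int, np.ndarray] = {}
    for node, vec in force_vectors:
        node = int(node)
        forces[node] = forces.get(node, np.zeros(3)) + np.asarray(vec, dtype=float)
    fixed = np.concatenate(
        [mesh.node_sets["basicranium_left"], mesh.node_sets["basicranium_right"], mesh.node_sets[bite_set]]
    )
    # a loaded node that ends up constrained would be silently zeroed; forbid it
    return LoadCase(nodal_forces=forces, fixed_nodes=fixed, label=label or bite_set)
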