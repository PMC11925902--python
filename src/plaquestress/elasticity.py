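"""Static small-strain linear elasticity on labelled tetrahedral meshes.

This is the in-package replacement for a commercial FE solver. Plain
linear tetrahedra lock volumetrically at the nearly incompressible
Poisson ratio used for arterial tissue (nu = 0.49); the solver therefore
uses linear tets with a *nodally averaged volumetric strain* (node-based
mean dilatation): the deviatoric response is integrated element-wise as
usual, while the volumetric strain entering both the stiffness and the
stress is averaged over the elements sharing each node. The scheme passes
the uniform-strain patch test exactly and converges on smooth benchmarks
(see the thick-walled-cylinder validation in the test suite).

The vessel load case applies a uniform normal traction of magnitude
``pressure`` on the lumen surface patch (pointing from the lumen into the
wall) with the vessel end cross-sections fully constrained, mirroring a
static analysis of the differential (systolic minus diastolic) carotid
pressure.

Unit system: mm - kPa - mN. One stress tensor is reported per element,
which is what the cumulative-volume stress indexes consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.sparse import bmat, coo_matrix, diags
from scipy.sparse.linalg import splu

from .labels import Label
from .meshing import TetMesh, _face_geometry


class SolverError(RuntimeError):
    """Raised when the linear system cannot be solved reliably."""


# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------


@dataclass
class MaterialTable:
    """Young's moduli per tissue label (kPa) and the shared Poisson ratio.

    Defaults are the literature-average values used for carotid plaque FE
    models: calcific 20,000 kPa, lipid 4 kPa, fibrous 400 kPa, healthy wall
    550 kPa, with nu = 0.49 (nearly incompressible).
    """

    young: dict[Label, float] = field(
        default_factory=lambda: {
            Label.CALCIFIC: 20000.0,
            Label.LIPID: 4.0,
            Label.FIBROUS: 400.0,
            Label.HEALTHY_WALL: 550.0,
        }
    )
    poisson: float = 0.49

    def __post_init__(self) -> None:
        if not (0 < self.poisson < 0.5):
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        for lab, e in self.young.items():
            if e <= 0:
                raise ValueError(f"Young's modulus for {Label(lab).name} must be positive")


def assign_materials(mesh: TetMesh, table: MaterialTable | None = None) -> tuple[np.ndarray, float]:
    """Per-element Young's modulus (kPa) and the shared Poisson ratio."""
    table = table or MaterialTable()
    young = {int(k): float(v) for k, v in table.young.items()}
    missing = sorted(set(int(l) for l in np.unique(mesh.labels)) - set(young))
    if missing:
        names = ", ".join(Label(m).name for m in missing)
        raise KeyError(f"no material defined for label(s): {names}")
    lut = np.zeros(max(young) + 1)
    for k, v in young.items():
        lut[k] = v
    return lut[mesh.labels], table.poisson


# ---------------------------------------------------------------------------
# Stress invariants
# ---------------------------------------------------------------------------


def stress_invariants(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Von Mises and maximum principal stress of symmetric tensors.

    Accepts one ``(3, 3)`` tensor or a stack ``(..., 3, 3)``; returns
    scalars/arrays in the input units.
    """
    s = np.asarray(sigma, float)
    if s.shape[-2:] != (3, 3):
        raise ValueError("expected (..., 3, 3) stress tensors")
    scale = np.maximum(np.abs(s).max(axis=(-2, -1)), 1e-30)
    asym = np.abs(s - np.swapaxes(s, -1, -2)).max(axis=(-2, -1))
    if np.any(asym > 1e-8 * scale):
        raise ValueError("stress tensor is not symmetric")
    tr = np.trace(s, axis1=-2, axis2=-1)
    dev = s - (tr / 3.0)[..., None, None] * np.eye(3)
    vm = np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))
    mps = np.linalg.eigvalsh(s)[..., -1]
    return vm, mps


# ---------------------------------------------------------------------------
# Element machinery (linear tets)
# ---------------------------------------------------------------------------


def _element_gradients(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients G (m, 4, 3) and element volumes V (m,)."""
    p = mesh.nodes[mesh.elems]
    J = np.swapaxes(p[:, 1:] - p[:, :1], 1, 2)  # columns p_i - p0
    V = np.linalg.det(J) / 6.0
    Jinv = np.linalg.inv(J)
    G = np.empty((len(p), 4, 3))
    G[:, 1:, :] = Jinv  # rows of J^-1 = grad of barycentric coords 1..3
    G[:, 0, :] = -Jinv.sum(axis=1)
    return G, V


def _b_matrix(G: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices B (m, 6, 12), Voigt engineering shear."""
    m = len(G)
    B = np.zeros((m, 6, 12))
    for n in range(4):
        dx, dy, dz = G[:, n, 0], G[:, n, 1], G[:, n, 2]
        B[:, 0, 3 * n + 0] = dx
        B[:, 1, 3 * n + 1] = dy
        B[:, 2, 3 * n + 2] = dz
        B[:, 3, 3 * n + 0] = dy
        B[:, 3, 3 * n + 1] = dx
        B[:, 4, 3 * n + 1] = dz
        B[:, 4, 3 * n + 2] = dy
        B[:, 5, 3 * n + 0] = dz
        B[:, 5, 3 * n + 2] = dx
    return B


# deviatoric projector in Voigt notation (engineering shear):
# sigma_dev = 2 mu * P_dev @ strain
_P_DEV = np.block(
    [
        [np.eye(3) - np.ones((3, 3)) / 3.0, np.zeros((3, 3))],
        [np.zeros((3, 3)), 0.5 * np.eye(3)],
    ]
)

_DIV_ROW = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])


def _assemble(mesh: TetMesh, E: np.ndarray, nu: float):
    """Deviatoric stiffness plus the nodal volumetric-strain operator.

    The volumetric energy 1/2 sum_a kappa_a V_a theta_a^2 (theta_a the
    volume-weighted average dilatation of the elements sharing node a) is
    kept in mixed form: the condensed stiffness would be
    ``K_dev + Q^T diag(kappa_a / V_a) Q`` with ``Q`` the raw (volume-
    scaled) nodal divergence operator, but the solver factors the sparser
    equivalent saddle-point system instead.
    """
    G, V = _element_gradients(mesh)
    B = _b_matrix(G)
    m = len(mesh.elems)
    n_nodes = len(mesh.nodes)
    ndof = 3 * n_nodes
    mu = E / (2.0 * (1.0 + nu))
    kappa = E / (3.0 * (1.0 - 2.0 * nu))

    # deviatoric part (compact element stencil)
    DB = np.einsum("ab,mbj->maj", _P_DEV, B)
    Ke = np.einsum("mai,maj->mij", B, DB) * (2.0 * mu * V)[:, None, None]
    dof = (mesh.elems[:, :, None] * 3 + np.arange(3)).reshape(m, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K_dev = coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()

    # raw nodal divergence: (Q u)_a = sum_{e owning a} (V_e/4) div(u)_e
    d = _DIV_ROW @ B  # (m, 12): element divergence operator
    r_idx = np.repeat(mesh.elems, 12, axis=1).ravel()
    c_idx = np.tile(dof, (1, 4)).ravel()
    vals = (np.tile(d, (1, 4)) * (V / 4.0)[:, None]).ravel()
    Q = coo_matrix((vals, (r_idx, c_idx)), shape=(n_nodes, ndof)).tocsr()

    node_vol = np.zeros(n_nodes)
    np.add.at(node_vol, mesh.elems.ravel(), np.repeat(V / 4.0, 4))
    kappa_node = np.zeros(n_nodes)
    np.add.at(kappa_node, mesh.elems.ravel(), np.repeat(kappa * V / 4.0, 4))
    kappa_node /= node_vol

    return K_dev, Q, node_vol, kappa_node, B, V, dof, mu, kappa


# ---------------------------------------------------------------------------
# Result container
# ---------------------------------------------------------------------------


@dataclass
class FEAResult:
    """Equilibrium solution: nodal displacements and per-element stresses."""

    displacements: np.ndarray  # (n_nodes, 3), mm
    stress: np.ndarray  # (m, 3, 3), kPa, one tensor per element
    element_volumes: np.ndarray  # (m,), mm^3
    element_labels: np.ndarray  # (m,)

    @cached_property
    def von_mises(self) -> np.ndarray:
        return stress_invariants(self.stress)[0]

    @cached_property
    def max_principal(self) -> np.ndarray:
        return stress_invariants(self.stress)[1]


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------


def _patch_node_dofs(mesh: TetMesh, patch: str, mode: str) -> np.ndarray:
    faces = mesh.patches.get(patch)
    if faces is None or len(faces) == 0:
        raise SolverError(f"constraint patch '{patch}' is empty or missing")
    nodes = np.unique(faces)
    if mode == "fixed":
        return (nodes[:, None] * 3 + np.arange(3)).ravel()
    if mode == "normal":
        _, _, normal = _face_geometry(mesh.nodes, faces)
        axis = int(np.argmax(np.abs(normal.mean(axis=0))))
        return nodes * 3 + axis
    raise ValueError(f"unknown constraint mode '{mode}'")


def solve_elasticity(
    mesh: TetMesh,
    materials: MaterialTable | None = None,
    pressure: float = 0.0,
    constraints: dict[str, str] | None = None,
    tractions: dict[str, np.ndarray] | None = None,
    extra_fixed_dofs: np.ndarray | None = None,
) -> FEAResult:
    """Solve the static elasticity problem on a labelled vessel mesh.

    Parameters
    ----------
    pressure
        Uniform normal traction magnitude (kPa) on the ``lumen`` patch,
        pointing from the lumen into the wall.
    constraints
        Patch name -> ``"fixed"`` (all components zero) or ``"normal"``
        (only the patch-normal component zero). Defaults to fully fixed
        proximal and distal vessel ends.
    tractions
        Optional constant traction vectors (kPa) per patch, added to the
        pressure load (used by validation problems).
    extra_fixed_dofs
        Additional global DOF indices to pin (validation problems need a
        few to remove rigid-body modes).
    """
    if pressure < 0:
        raise ValueError("pressure must be non-negative")
    E, nu = assign_materials(mesh, materials)
    if constraints is None:
        constraints = {"proximal_end": "fixed", "distal_ends": "fixed"}

    ndof = 3 * len(mesh.nodes)
    fixed = [np.asarray([], dtype=np.int64)]
    for patch, mode in constraints.items():
        fixed.append(_patch_node_dofs(mesh, patch, mode))
    if extra_fixed_dofs is not None:
        fixed.append(np.asarray(extra_fixed_dofs, np.int64))
    fixed_dofs = np.unique(np.concatenate(fixed))
    if len(fixed_dofs) == 0:
        raise SolverError("no constrained degrees of freedom: system is singular")

    # load vector: consistent linear-triangle load for a constant traction
    # is one third of the face force at each vertex
    f = np.zeros(ndof)
    loads: list[tuple[np.ndarray, np.ndarray]] = []
    if pressure > 0:
        faces = mesh.patches.get("lumen")
        if faces is None or len(faces) == 0:
            raise SolverError("pressure load requested but the lumen patch is empty")
        _, area, normal = _face_geometry(mesh.nodes, faces)
        # boundary normals point out of the solid, i.e. into the lumen;
        # the blood pressure pushes the wall the opposite way
        loads.append((faces, -pressure * normal * area[:, None]))
    for patch, t in (tractions or {}).items():
        faces = mesh.patches[patch]
        _, area, _ = _face_geometry(mesh.nodes, faces)
        loads.append((faces, np.broadcast_to(np.asarray(t, float), (len(faces), 3)) * area[:, None]))
    for faces, force in loads:
        for j in range(3):
            for c in range(3):
                np.add.at(f, faces[:, j] * 3 + c, force[:, c] / 3.0)

    K_dev, Q, node_vol, kappa_node, B, V, dof, mu, kappa = _assemble(mesh, E, nu)

    u = np.zeros(ndof)
    if np.any(f != 0.0):
        free = np.ones(ndof, bool)
        free[fixed_dofs] = False
        n_free = int(free.sum())
        # mixed system: [[K_dev, Q^T], [Q, -diag(V_a / kappa_a)]];
        # eliminating the nodal pressure p_a recovers the condensed
        # stiffness, but this form keeps the factorization sparse
        A = bmat(
            [
                [K_dev[free][:, free], Q[:, free].T],
                [Q[:, free], -diags(node_vol / kappa_node)],
            ],
            format="csc",
        )
        rhs = np.concatenate([f[free], np.zeros(len(node_vol))])
        try:
            lu = splu(A)
            sol = lu.solve(rhs)
        except RuntimeError as exc:  # singular factorization
            raise SolverError(f"sparse factorization failed: {exc}") from exc
        if not np.all(np.isfinite(sol)):
            raise SolverError("solver produced non-finite displacements")
        resid = np.linalg.norm(A @ sol - rhs) / max(np.linalg.norm(rhs), 1e-30)
        if resid > 1e-8:
            raise SolverError(f"solution residual too large: {resid:.2e}")
        u[free] = sol[:n_free]

    # per-element stress: deviatoric from the element strain, volumetric
    # from the nodal-averaged dilatation (mean over the element's nodes)
    ue = u[dof]  # (m, 12)
    strain = np.einsum("maj,mj->ma", B, ue)
    dev = strain @ _P_DEV.T * (2.0 * mu)[:, None]
    theta_node = (Q @ u) / node_vol  # nodal volumetric strain
    theta_e = theta_node[mesh.elems].mean(axis=1)
    p_vol = kappa * theta_e
    sxx = dev[:, 0] + p_vol
    syy = dev[:, 1] + p_vol
    szz = dev[:, 2] + p_vol
    sxy, syz, szx = dev[:, 3], dev[:, 4], dev[:, 5]
    stress = np.empty((len(strain), 3, 3))
    stress[:, 0, 0], stress[:, 1, 1], stress[:, 2, 2] = sxx, syy, szz
    stress[:, 0, 1] = stress[:, 1, 0] = sxy
    stress[:, 1, 2] = stress[:, 2, 1] = syz
    stress[:, 0, 2] = stress[:, 2, 0] = szx

    return FEAResult(
        displacements=u.reshape(-1, 3),
        stress=stress,
        element_volumes=V,
        element_labels=mesh.labels.copy(),
    )
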