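"""Solver validation benchmarks with closed-form oracles.

Two classical problems exercise the elasticity solver end to end:

* the uniform-strain patch test (a block under uniaxial traction must
  reproduce the constant stress state exactly, to solver precision);
* the Lamé thick-walled cylinder under internal pressure, whose hoop
  stress sigma_theta(r) = p a^2 / (b^2 - a^2) (1 + b^2 / r^2) is exact in
  plane strain and independent of the elastic constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elasticity import MaterialTable, solve_elasticity
from .meshing import box_mesh, cylinder_mesh


def patch_test_error(n: tuple[int, int, int] = (2, 2, 2), traction: float = 2.5) -> float:
    """Max relative stress error of the uniaxial patch test.

    A unit block is rolled on its bottom face (normal displacement fixed),
    loaded with a uniform traction on the top face, and pinned against
    in-plane rigid motion; every element must carry the uniform uniaxial
    stress exactly.
    """
    h = 1.0 / n[2]
    mesh = box_mesh(n, h)
    nodes = mesh.nodes
    i000 = int(np.argmin(np.linalg.norm(nodes - [0.0, 0.0, 0.0], axis=1)))
    i100 = int(np.argmin(np.linalg.norm(nodes - [1.0, 0.0, 0.0], axis=1)))
    extra = np.array([3 * i000, 3 * i000 + 1, 3 * i100 + 1])
    res = solve_elasticity(
        mesh,
        MaterialTable(),
        constraints={"zmin": "normal"},
        tractions={"zmax": np.array([0.0, 0.0, traction])},
        extra_fixed_dofs=extra,
    )
    target = np.zeros((3, 3))
    target[2, 2] = traction
    return float(np.abs(res.stress - target).max() / traction)


@dataclass
class LameResult:
    """One Lamé-cylinder run: inner-wall hoop stress and error measures."""

    nr: int
    ntheta: int
    nz: int
    hoop_inner: float  # extrapolated sigma_theta at r = a, kPa
    hoop_exact: float  # closed form at r = a, kPa
    rel_error: float  # |hoop_inner - exact| / exact
    rms_error: float  # volume-weighted RMS relative hoop-stress error


def lame_benchmark(
    nr: int = 8,
    ntheta: int = 64,
    nz: int = 2,
    a: float = 3.0,
    b: float = 4.0,
    pressure: float = 5.33,
    length: float = 1.0,
) -> LameResult:
    """Solve the pressurised thick cylinder and compare with the closed form.

    Plane strain is enforced by constraining the axial displacement on both
    end faces; three tangential point constraints remove the in-plane rigid
    modes without perturbing the (purely radial) exact solution. The
    inner-wall hoop stress is linearly extrapolated to r = a from the ring
    averages of the two innermost element rings.
    """
    mesh = cylinder_mesh(a, b, length, nr, ntheta, nz)
    nodes = mesh.nodes
    pins = []
    for pos, axis in (([a, 0, 0], 1), ([-a, 0, 0], 1), ([0, a, 0], 0)):
        i = int(np.argmin(np.linalg.norm(nodes - pos, axis=1)))
        pins.append(3 * i + axis)
    res = solve_elasticity(
        mesh,
        MaterialTable(),
        pressure=pressure,
        constraints={"proximal_end": "normal", "distal_ends": "normal"},
        extra_fixed_dofs=np.array(pins),
    )

    def exact(r):
        return pressure * a**2 / (b**2 - a**2) * (1.0 + b**2 / r**2)

    cent = nodes[mesh.elems].mean(axis=1)
    r = np.hypot(cent[:, 0], cent[:, 1])
    th = np.arctan2(cent[:, 1], cent[:, 0])
    tvec = np.stack([-np.sin(th), np.cos(th), np.zeros_like(th)], axis=1)
    s_tt = np.einsum("mi,mij,mj->m", tvec, res.stress, tvec)

    edges = np.linspace(a, b, nr + 1)
    rc, sc = [], []
    for i in range(2):
        sel = (r >= edges[i]) & (r < edges[i + 1])
        rc.append(r[sel].mean())
        sc.append(s_tt[sel].mean())
    hoop_inner = sc[0] + (sc[1] - sc[0]) / (rc[1] - rc[0]) * (a - rc[0])
    rel = (s_tt - exact(r)) / exact(r)
    rms = float(np.sqrt(np.average(rel**2, weights=res.element_volumes)))
    return LameResult(
        nr=nr,
        ntheta=ntheta,
        nz=nz,
        hoop_inner=float(hoop_inner),
        hoop_exact=float(exact(a)),
        rel_error=float(abs(hoop_inner - exact(a)) / exact(a)),
        rms_error=rms,
    )


def lame_convergence(
    refinements: tuple[tuple[int, int, int], ...] = ((4, 32, 2), (8, 64, 2), (16, 128, 2)),
) -> list[LameResult]:
    """Lamé benchmark under successive uniform in-plane refinements."""
    return [lame_benchmark(nr, nt, nz) for nr, nt, nz in refinements]
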