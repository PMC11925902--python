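"""Labelled tetrahedral meshes for the vessel finite-element model.

The reconstructed wall is meshed by splitting every solid voxel into six
tetrahedra (the Freudenthal decomposition, which is conforming across
neighbouring voxels), inheriting the voxel's tissue label. Boundary
triangles are classified into surface patches: the ``lumen`` (pressure)
patch, the ``proximal_end``/``distal_ends`` (constrained) patches and the
traction-free ``outer`` surface.

A body-fitted structured cylinder mesh (:func:`cylinder_mesh`) and a voxel
box (:func:`box_mesh`) are provided for solver validation against closed
forms; they share all downstream machinery with the vessel meshes.

Linear (4-node) connectivity is the stored form; the quadratic (10-node)
view used by the solver is derived on demand and cached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import VesselModel
from .labels import Label, LabelVolume, WALL_LABELS

# Freudenthal 6-tet split of a hexahedron whose corners are numbered by
# binary offsets (bit0 = x, bit1 = y, bit2 = z): each tet follows a
# monotone vertex path 0 -> 7.
_FREUDENTHAL = np.array(
    [
        [0, 1, 3, 7],
        [0, 1, 5, 7],
        [0, 2, 3, 7],
        [0, 2, 6, 7],
        [0, 4, 5, 7],
        [0, 4, 6, 7],
    ]
)

# local edges of a TET10 in Abaqus/VTK order: nodes 4..9
_TET_EDGES = np.array([[0, 1], [1, 2], [0, 2], [0, 3], [1, 3], [2, 3]])

# outward-oriented faces of a positively oriented tet
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


@dataclass
class TetMesh:
    """Labelled tetrahedral mesh (mm).

    ``patches`` maps a patch name to outward-oriented boundary triangles
    given as vertex-node triples.
    """

    nodes: np.ndarray  # (n, 3) float
    elems: np.ndarray  # (m, 4) int
    labels: np.ndarray  # (m,) uint8
    patches: dict[str, np.ndarray] = field(default_factory=dict)
    _quad: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, float)
        self.elems = np.asarray(self.elems, np.int64)
        self.labels = np.asarray(self.labels, np.uint8)
        if len(self.labels) != len(self.elems):
            raise ValueError("one label per element required")
        vols = self.element_volumes()
        if np.any(vols <= 0):
            raise ValueError("mesh contains non-positive-volume elements")

    @property
    def n_elements(self) -> int:
        return len(self.elems)

    def element_volumes(self) -> np.ndarray:
        p = self.nodes[self.elems]
        return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0

    def total_volume(self) -> float:
        return float(self.element_volumes().sum())

    def label_volume(self, label: Label) -> float:
        return float(self.element_volumes()[self.labels == int(label)].sum())

    # -- quadratic view ------------------------------------------------------

    def quadratic(self) -> tuple[np.ndarray, np.ndarray]:
        """(nodes10, elems10): vertex nodes first, then unique edge midpoints."""
        if self._quad is None:
            pairs = self.elems[:, _TET_EDGES]  # (m, 6, 2)
            pairs = np.sort(pairs.reshape(-1, 2), axis=1)
            uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
            n_v = len(self.nodes)
            mid = 0.5 * (self.nodes[uniq[:, 0]] + self.nodes[uniq[:, 1]])
            nodes10 = np.vstack([self.nodes, mid])
            elems10 = np.hstack([self.elems, n_v + inverse.reshape(-1, 6)])
            edge_ids = {(int(a), int(b)): n_v + i for i, (a, b) in enumerate(uniq)}
            self._quad = (nodes10, elems10, edge_ids)
        return self._quad[0], self._quad[1]

    def face_midside_nodes(self, faces: np.ndarray) -> np.ndarray:
        """Quadratic 6-node faces for the given vertex-node triangles."""
        self.quadratic()
        edge_ids = self._quad[2]

        def mid(a: int, b: int) -> int:
            return edge_ids[(a, b) if a < b else (b, a)]

        out = np.empty((len(faces), 6), np.int64)
        for i, (a, b, c) in enumerate(np.asarray(faces)):
            out[i] = (a, b, c, mid(a, b), mid(b, c), mid(c, a))
        return out


# ---------------------------------------------------------------------------
# Hex -> tet machinery
# ---------------------------------------------------------------------------


def _hexes_to_tets(corner_ids: np.ndarray) -> np.ndarray:
    """Split hexes (m, 8 corner node ids, binary order) into 6m tets."""
    return corner_ids[:, _FREUDENTHAL].reshape(-1, 4)


def _fix_orientation(nodes: np.ndarray, elems: np.ndarray) -> np.ndarray:
    p = nodes[elems]
    neg = np.linalg.det(p[:, 1:] - p[:, :1]) < 0
    elems = elems.copy()
    elems[neg, 2], elems[neg, 3] = elems[neg, 3], elems[neg, 2].copy()
    return elems


def _boundary_faces(elems: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary triangles of the tet mesh."""
    faces = elems[:, _TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inverse] == 1]


def _face_geometry(nodes: np.ndarray, faces: np.ndarray):
    p = nodes[faces]
    cent = p.mean(axis=1)
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    area = 0.5 * np.linalg.norm(cross, axis=1)
    normal = cross / np.linalg.norm(cross, axis=1, keepdims=True)
    return cent, area, normal


# ---------------------------------------------------------------------------
# Vessel meshing
# ---------------------------------------------------------------------------


def _resample_labels(vol: LabelVolume, factor: int) -> LabelVolume:
    """Block-majority downsampling by an integer factor."""
    data = vol.data
    shape = np.array(data.shape)
    new = shape // factor
    data = data[: new[0] * factor, : new[1] * factor, : new[2] * factor]
    blocks = data.reshape(new[0], factor, new[1], factor, new[2], factor)
    counts = np.stack(
        [(blocks == lab).sum(axis=(1, 3, 5)) for lab in range(6)], axis=-1
    )
    out = counts.argmax(axis=-1).astype(np.uint8)
    origin = vol.origin + 0.5 * (factor - 1) * vol.voxel_size
    return LabelVolume(out, vol.voxel_size * factor, origin)


def mesh_vessel(model: VesselModel | LabelVolume, target_edge: float | None = None) -> TetMesh:
    """Conforming labelled tet mesh of the reconstructed wall.

    Every solid voxel becomes six tetrahedra carrying the voxel's label.
    ``target_edge`` (mm) requests a coarser mesh via integer-factor
    block-majority resampling of the label grid; ``None`` meshes at the
    native voxel size.
    """
    vol = model.volume if isinstance(model, VesselModel) else model
    if target_edge is not None:
        factor = max(1, int(round(target_edge / vol.voxel_size)))
        if factor > 1:
            vol = _resample_labels(vol, factor)
    h = vol.voxel_size
    wall = vol.mask(*WALL_LABELS)
    if not wall.any():
        raise ValueError("model contains no wall voxels to mesh")
    vox = np.argwhere(wall)
    nx, ny, nz = vol.data.shape

    # corner ids on the (nx+1, ny+1, nz+1) grid
    strides = np.array([(ny + 1) * (nz + 1), nz + 1, 1], np.int64)
    # binary corner order bit0=x, bit1=y, bit2=z
    offsets = np.array([[b & 1, (b >> 1) & 1, (b >> 2) & 1] for b in range(8)])
    corner_idx = vox[:, None, :] + offsets[None, :, :]
    corner_lin = corner_idx @ strides
    uniq, inv = np.unique(corner_lin, return_inverse=True)
    corner_ids = inv.reshape(-1, 8)

    gi = np.empty((len(uniq), 3), float)
    gi[:, 0] = uniq // ((ny + 1) * (nz + 1))
    gi[:, 1] = (uniq // (nz + 1)) % (ny + 1)
    gi[:, 2] = uniq % (nz + 1)
    nodes = (gi - 0.5) * h + vol.origin

    elems = _hexes_to_tets(corner_ids)
    labels = np.repeat(vol.data[wall], 6)
    elems = _fix_orientation(nodes, elems)

    mesh = TetMesh(nodes, elems, labels)
    # classify boundary faces by the voxel on the other side
    faces = _boundary_faces(elems)
    cent, _, normal = _face_geometry(nodes, faces)
    probe = cent + normal * (0.25 * h)
    pidx = np.round((probe - vol.origin) / h).astype(int)
    out_lo = pidx < 0
    out_hi = pidx >= np.array([nx, ny, nz])
    outside = out_lo.any(axis=1) | out_hi.any(axis=1)
    adj = np.full(len(faces), int(Label.BACKGROUND), np.uint8)
    inside = ~outside
    adj[inside] = vol.data[pidx[inside, 0], pidx[inside, 1], pidx[inside, 2]]

    proximal = out_lo[:, 2]
    distal = out_hi[:, 2]
    lumen = (adj == int(Label.LUMEN)) & ~proximal & ~distal
    outer = ~(proximal | distal | lumen)
    mesh.patches = {
        "proximal_end": faces[proximal],
        "distal_ends": faces[distal],
        "lumen": faces[lumen],
        "outer": faces[outer],
    }
    return mesh


# ---------------------------------------------------------------------------
# Validation meshes
# ---------------------------------------------------------------------------


def cylinder_mesh(
    r_in: float,
    r_out: float,
    length: float,
    nr: int = 8,
    ntheta: int = 64,
    nz: int = 2,
    label: Label = Label.HEALTHY_WALL,
) -> TetMesh:
    """Body-fitted structured tet mesh of a thick-walled cylinder.

    Patches: ``lumen`` (inner surface), ``proximal_end`` (z=0),
    ``distal_ends`` (z=length), ``outer``. Used to validate the elasticity
    solver against the Lamé closed form on a smooth boundary.
    """
    r = np.linspace(r_in, r_out, nr + 1)
    th = np.arange(ntheta) * (2 * np.pi / ntheta)
    z = np.linspace(0.0, length, nz + 1)

    def nid(i, j, k):
        return (i * ntheta + (j % ntheta)) * (nz + 1) + k

    nodes = np.empty(((nr + 1) * ntheta * (nz + 1), 3))
    ridx = np.empty(len(nodes), int)
    zidx = np.empty(len(nodes), int)
    for i in range(nr + 1):
        for j in range(ntheta):
            for k in range(nz + 1):
                n = nid(i, j, k)
                nodes[n] = (r[i] * np.cos(th[j]), r[i] * np.sin(th[j]), z[k])
                ridx[n], zidx[n] = i, k

    hexes = []
    for i in range(nr):
        for j in range(ntheta):
            for k in range(nz):
                # binary corner order bit0=r, bit1=theta, bit2=z
                hexes.append(
                    [
                        nid(i + b0, j + b1, k + b2)
                        for b2 in (0, 1)
                        for b1 in (0, 1)
                        for b0 in (0, 1)
                    ]
                )
    elems = _hexes_to_tets(np.asarray(hexes))
    elems = _fix_orientation(nodes, elems)
    labels = np.full(len(elems), int(label), np.uint8)
    mesh = TetMesh(nodes, elems, labels)

    faces = _boundary_faces(elems)
    on_inner = (ridx[faces] == 0).all(axis=1)
    on_z0 = (zidx[faces] == 0).all(axis=1)
    on_z1 = (zidx[faces] == nz).all(axis=1)
    mesh.patches = {
        "lumen": faces[on_inner & ~on_z0 & ~on_z1],
        "proximal_end": faces[on_z0],
        "distal_ends": faces[on_z1],
        "outer": faces[~(on_inner | on_z0 | on_z1)],
    }
    return mesh


def box_mesh(n: tuple[int, int, int], h: float, label: Label = Label.HEALTHY_WALL) -> TetMesh:
    """Voxel box of ``n`` cells with face patches xmin..zmax (patch test)."""
    data = np.full(n, int(label), np.uint8)
    vol = LabelVolume(data, h, origin=np.full(3, 0.5 * h))
    mesh = mesh_vessel(vol)
    faces = np.vstack(list(mesh.patches.values()))
    cent, _, normal = _face_geometry(mesh.nodes, faces)
    patches = {}
    names = [("xmin", 0, -1), ("xmax", 0, 1), ("ymin", 1, -1), ("ymax", 1, 1), ("zmin", 2, -1), ("zmax", 2, 1)]
    for name, axis, sign in names:
        sel = normal[:, axis] * sign > 0.9
        patches[name] = faces[sel]
    mesh.patches = patches
    return mesh
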