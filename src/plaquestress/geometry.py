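"""Semi-automatic atherosclerotic wall reconstruction.

A CTA segmentation only shows the lumen and the calcific/lipid plaque
components; the vessel wall and the fibrous plaque matrix are not visible.
This module rebuilds the full wall: per centerline station (one station per
axial voxel slice) the outer wall contour is the larger of (lumen radius +
healthy wall thickness) and (furthest component extent + fibrous cap
margin), smoothed along the vessel. Within the stenotic extent every wall
voxel that is not calcific or lipid is filled with fibrous tissue; outside
it the wall is a uniform-thickness healthy rim.

The operation is idempotent: feeding an already reconstructed model back in
changes no labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .labels import COMPONENT_NAMES, Label, LabelVolume


# ---------------------------------------------------------------------------
# Centerline
# ---------------------------------------------------------------------------


@dataclass
class Centerline:
    """Ordered polyline through the lumen (world mm)."""

    points: np.ndarray  # (n, 3)
    arclength: np.ndarray  # (n,), cumulative, strictly increasing
    tangents: np.ndarray  # (n, 3), unit vectors
    slice_index: np.ndarray  # (n,), axial voxel slice of each station


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(x) < 3:
        return x.copy()
    w = min(window, len(x) if len(x) % 2 else len(x) - 1)
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    kernel = np.ones(w) / w
    return np.convolve(xp, kernel, mode="valid")


def extract_centerline(labelmap: LabelVolume, smooth_window: int = 5) -> Centerline:
    """Per-slice lumen centroid polyline, smoothed along the axis.

    The vessel is assumed roughly aligned with the third voxel axis; for a
    tube-like lumen the slice centroid deviates from the true medial axis
    by O(r^2 * curvature), below one voxel for realistic carotid bends.
    """
    lumen = labelmap.mask(Label.LUMEN)
    if not lumen.any():
        raise ValueError("labelmap contains no lumen")
    n_comp = ndimage.label(lumen)[1]
    if n_comp != 1:
        raise ValueError(f"lumen must be a single connected component (found {n_comp})")

    h = labelmap.voxel_size
    slices = np.flatnonzero(lumen.any(axis=(0, 1)))
    pts = []
    for k in slices:
        idx = np.argwhere(lumen[:, :, k])
        cx, cy = idx.mean(axis=0)
        pts.append((cx, cy, float(k)))
    pts = np.asarray(pts, float)
    pts[:, 0] = _moving_average(pts[:, 0], smooth_window)
    pts[:, 1] = _moving_average(pts[:, 1], smooth_window)
    world = pts * h + labelmap.origin

    seg = np.diff(world, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(seglen)])
    tangents = np.empty_like(world)
    tangents[1:-1] = world[2:] - world[:-2]
    tangents[0] = world[1] - world[0]
    tangents[-1] = world[-1] - world[-2]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return Centerline(world, arclength, tangents, slices)


# ---------------------------------------------------------------------------
# Wall reconstruction
# ---------------------------------------------------------------------------


@dataclass
class ReconstructionConfig:
    """Tunables of the wall reconstruction (lengths in mm)."""

    wall_thickness: float = 1.0  # healthy wall rim
    cap_margin: float = 0.3  # fibrous cap beyond segmented components
    smoothing_window: int = 5  # stations, outer-radius moving average
    stenosis_area_ratio: float = 0.9  # lumen area below this x reference => stenotic
    max_component_gap: float = 6.0  # components further from the lumen surface are orphans


@dataclass
class VesselModel:
    """Reconstructed atherosclerotic vessel: full label set + metadata."""

    volume: LabelVolume
    centerline: Centerline
    config: ReconstructionConfig

    def surface(self, label: Label) -> tuple[np.ndarray, np.ndarray]:
        """Marching-cubes surface (verts mm, faces) of one label's mask."""
        from skimage import measure

        mask = self.volume.mask(label).astype(np.uint8)
        verts, faces, _, _ = measure.marching_cubes(mask, level=0.5)
        verts = verts * self.volume.voxel_size + self.volume.origin
        return verts, faces


@dataclass
class VolumeReport:
    """Absolute (mm^3) and relative (% of plaque) component volumes."""

    absolute: dict[str, float]
    relative: dict[str, float]
    total_plaque: float
    plaque_defined: bool

    def __post_init__(self) -> None:
        if self.plaque_defined:
            s = sum(self.relative.values())
            if abs(s - 100.0) > 0.1:
                raise ValueError(f"relative volumes sum to {s:.3f}%, expected 100%")


def _check_orphans(labelmap: LabelVolume, config: ReconstructionConfig) -> None:
    comp_mask = labelmap.mask(Label.CALCIFIC, Label.LIPID)
    if not comp_mask.any():
        return
    lumen = labelmap.mask(Label.LUMEN)
    # distance (mm) from every voxel to the nearest lumen voxel
    dist = ndimage.distance_transform_edt(~lumen) * labelmap.voxel_size
    lab_arr, n = ndimage.label(comp_mask)
    orphans = []
    for i in range(1, n + 1):
        d = dist[lab_arr == i].min()
        if d > config.max_component_gap:
            orphans.append((i, float(d)))
    if orphans:
        desc = ", ".join(f"component {i} at {d:.1f} mm" for i, d in orphans)
        raise ValueError(f"plaque components disconnected from the vessel: {desc}")


def reconstruct_atherosclerotic_wall(
    labelmap: LabelVolume, config: ReconstructionConfig | None = None
) -> VesselModel:
    """Build the full atherosclerotic wall from a lumen+components labelmap.

    See the module docstring for the two reconstruction rules. Calcific and
    lipid voxels of the input always keep their labels.
    """
    config = config or ReconstructionConfig()
    centerline = extract_centerline(labelmap)
    vol = labelmap.copy()
    data = vol.data
    h = vol.voxel_size

    already = bool(vol.mask(Label.FIBROUS, Label.HEALTHY_WALL).any())
    if not already:
        _check_orphans(labelmap, config)

    lumen = vol.mask(Label.LUMEN)
    comp = vol.mask(Label.CALCIFIC, Label.LIPID)

    slices = centerline.slice_index
    centers_vox = (centerline.points - vol.origin) / h  # station centres, voxel units

    nx, ny, _ = data.shape
    ix = np.arange(nx)[:, None]
    iy = np.arange(ny)[None, :]

    lumen_area = np.array([lumen[:, :, k].sum() for k in slices], float) * h * h
    ref_area = float(np.median(lumen_area[: min(5, len(lumen_area))]))

    # per-station lumen equivalent radius and furthest component extent
    r_lum = np.sqrt(lumen_area / np.pi)
    extent = np.full(len(slices), -np.inf)
    has_comp = np.zeros(len(slices), bool)
    for j, k in enumerate(slices):
        cm = comp[:, :, k]
        if cm.any():
            has_comp[j] = True
            cx, cy = centers_vox[j, 0], centers_vox[j, 1]
            rr = np.sqrt((ix - cx) ** 2 + (iy - cy) ** 2)[cm] * h
            extent[j] = rr.max() + 0.5 * h  # to the far voxel face

    if already:
        # idempotent path: the wall region is whatever is already labelled;
        # only the fibrous/healthy partition is recomputed (and reproduces)
        wall_any = vol.mask(*[l for l in (Label.CALCIFIC, Label.LIPID, Label.FIBROUS, Label.HEALTHY_WALL)])
        stenotic = (lumen_area < config.stenosis_area_ratio * ref_area) | np.array(
            [vol.mask(Label.CALCIFIC, Label.LIPID, Label.FIBROUS)[:, :, k].any() for k in slices]
        )
        for j, k in enumerate(slices):
            ring = wall_any[:, :, k] & ~comp[:, :, k]
            data[:, :, k][ring] = int(Label.FIBROUS if stenotic[j] else Label.HEALTHY_WALL)
        return VesselModel(vol, centerline, config)

    stenotic = (lumen_area < config.stenosis_area_ratio * ref_area) | has_comp

    # outer-wall radius per station: the vessel's outer wall does not pinch
    # inward at a stenosis (the plaque grows from the wall into the lumen),
    # so the healthy rim rides on the proximal reference radius wherever the
    # lumen is narrowed, and expands further to cap any component
    r_ref = float(np.sqrt(ref_area / np.pi))
    r_base = np.maximum(r_lum, r_ref)
    R = np.maximum(r_base + config.wall_thickness, extent + config.cap_margin)
    R_s = _moving_average(R, config.smoothing_window)
    # smoothing must never cut into components or the minimum healthy rim
    R_s = np.maximum.reduce([R_s, r_base + config.wall_thickness, extent + config.cap_margin])

    for j, k in enumerate(slices):
        cx, cy = centers_vox[j, 0], centers_vox[j, 1]
        rr = np.sqrt((ix - cx) ** 2 + (iy - cy) ** 2) * h
        ring = (rr <= R_s[j]) & ~lumen[:, :, k] & ~comp[:, :, k]
        data[:, :, k][ring] = int(Label.FIBROUS if stenotic[j] else Label.HEALTHY_WALL)

    return VesselModel(vol, centerline, config)


# ---------------------------------------------------------------------------
# Component volumes
# ---------------------------------------------------------------------------


def compute_component_volumes(model: VesselModel | LabelVolume) -> VolumeReport:
    """Voxel-counting volumes per plaque component.

    Absolute volumes are voxel count x voxel volume (mm^3); relative volumes
    are percentages of the calcific+lipid+fibrous total. With no plaque at
    all the relative volumes are undefined and flagged.
    """
    vol = model.volume if isinstance(model, VesselModel) else model
    absolute = {
        COMPONENT_NAMES[lab]: vol.count(lab) * vol.voxel_volume
        for lab in (Label.CALCIFIC, Label.LIPID, Label.FIBROUS)
    }
    absolute["healthy_wall"] = vol.count(Label.HEALTHY_WALL) * vol.voxel_volume
    total = absolute["calcific"] + absolute["lipid"] + absolute["fibrous"]
    if total <= 0:
        relative = {k: float("nan") for k in ("calcific", "lipid", "fibrous")}
        return VolumeReport(absolute, relative, 0.0, plaque_defined=False)
    relative = {k: 100.0 * absolute[k] / total for k in ("calcific", "lipid", "fibrous")}
    return VolumeReport(absolute, relative, total, plaque_defined=True)
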