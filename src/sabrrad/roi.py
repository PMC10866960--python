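"""The six regions of interest built from a RECIST line, an image and a lung mask.

All ROIs are restricted to the lung volume and constructed directly on the
working grid from mm-space geometry (masks are never interpolated). Inclusion
is by voxel center: a voxel belongs to a region iff its center does.

Kinds
-----
``lung_slice``   lung voxels of the axial slice holding the RECIST line (2D)
``solid_ggo``    seeded min-cut solid component + a 16 mm concentric GGO shell
``cylinder``     10 mm-radius cylinder with the RECIST line as rotation axis
``sphere20/40``  fixed-diameter spheres centered on the RECIST midpoint
``sphere_recist`` sphere whose diameter is the RECIST line length
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import igraph as ig
import numpy as np
from scipy import ndimage

from .imaging import ImageVolume, RoiMask, world_to_voxel
from .recist import RecistAnnotation

__all__ = [
    "RoiSpec",
    "SeedConflictError",
    "build_sphere",
    "build_cylinder",
    "build_lung_slice",
    "segment_solid",
    "expand_ggo",
    "build_all",
    "ROI_KINDS",
]

log = logging.getLogger(__name__)

ROI_KINDS = ("lung_slice", "solid_ggo", "cylinder", "sphere20", "sphere40", "sphere_recist")


class SeedConflictError(ValueError):
    """Foreground (RECIST line) and background (ring) seeds overlap."""


@dataclass
class RoiSpec:
    """Geometry defaults for the six ROI constructions."""

    cylinder_radius: float = 10.0  # mm
    ggo_expansion: float = 16.0  # mm
    ring_factor: float = 1.5  # background ring radius = ring_factor * L/2

    def __post_init__(self):
        if self.cylinder_radius <= 0 or self.ggo_expansion <= 0 or self.ring_factor <= 0:
            raise ValueError("RoiSpec radii/expansions must be > 0")


def _grid_coords(vol: ImageVolume):
    sp = np.asarray(vol.spacing)
    org = np.asarray(vol.origin)
    return [np.arange(vol.shape[d]) * sp[d] + org[d] for d in range(3)]


def _restrict(mask: np.ndarray, lung: RoiMask, kind: str) -> np.ndarray:
    out = mask & lung.mask
    if not out.any():
        raise ValueError(f"{kind} ROI is empty after intersection with the lung mask")
    return out


def build_sphere(
    a: RecistAnnotation, diameter: float, vol: ImageVolume, lung: RoiMask, kind: str | None = None
) -> RoiMask:
    """Sphere of the given diameter (mm) centered on the RECIST line midpoint."""
    if diameter <= 0:
        raise ValueError(f"sphere diameter must be > 0, got {diameter}")
    if kind is None:
        kind = f"sphere{diameter:g}"
    c = a.midpoint
    xs = _grid_coords(vol)
    d2 = (
        (xs[0][:, None, None] - c[0]) ** 2
        + (xs[1][None, :, None] - c[1]) ** 2
        + (xs[2][None, None, :] - c[2]) ** 2
    )
    inside = d2 <= (diameter / 2.0) ** 2
    if not inside.any():
        # diameter below voxel size: take the voxel containing the midpoint
        idx = np.round(world_to_voxel(vol, c)).astype(int)
        if np.all(idx >= 0) and np.all(idx < np.asarray(vol.shape)):
            inside[tuple(idx)] = True
    return RoiMask(_restrict(inside, lung, kind), vol.spacing, vol.origin, kind=kind)


def build_cylinder(
    a: RecistAnnotation, radius: float, vol: ImageVolume, lung: RoiMask
) -> RoiMask:
    """Cylinder with the RECIST line as its axis: perpendicular distance <= radius
    and axial projection within the segment (flat ends)."""
    p1, p2 = np.asarray(a.p1), np.asarray(a.p2)
    L = np.linalg.norm(p2 - p1)
    if L <= 0:
        raise ValueError("cylinder requires a RECIST line of positive length")
    axis = (p2 - p1) / L
    xs = _grid_coords(vol)
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    dx, dy, dz = X - p1[0], Y - p1[1], Z - p1[2]
    t = dx * axis[0] + dy * axis[1] + dz * axis[2]
    perp2 = dx**2 + dy**2 + dz**2 - t**2
    inside = (t >= 0) & (t <= L) & (perp2 <= radius**2 + 1e-12)
    return RoiMask(_restrict(inside, lung, "cylinder"), vol.spacing, vol.origin, kind="cylinder")


def _slice_index(a: RecistAnnotation, vol: ImageVolume) -> int:
    z = int(round(world_to_voxel(vol, a.p1)[2]))
    if not 0 <= z < vol.shape[2]:
        raise ValueError(f"RECIST slice z={z} outside grid of {vol.shape[2]} slices")
    return z


def build_lung_slice(a: RecistAnnotation, vol: ImageVolume, lung: RoiMask) -> RoiMask:
    """The segmented lung in the axial slice where the RECIST line was drawn (2D)."""
    z = _slice_index(a, vol)
    inside = np.zeros(vol.shape, dtype=bool)
    inside[:, :, z] = lung.mask[:, :, z]
    if not inside.any():
        raise ValueError(f"lung mask is empty in RECIST slice {z}")
    return RoiMask(inside, vol.spacing, vol.origin, kind="lung_slice", is_2d=True)


def _bresenham_3d(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Integer voxel chain from a to b (inclusive) by uniform line sampling."""
    n = int(np.max(np.abs(b - a))) + 1
    steps = np.linspace(0.0, 1.0, max(n * 2, 2))
    pts = np.round(a[None, :] + steps[:, None] * (b - a)[None, :]).astype(int)
    _, keep = np.unique(pts, axis=0, return_index=True)
    return pts[np.sort(keep)]


def _line_voxels(a: RecistAnnotation, vol: ImageVolume) -> np.ndarray:
    i1 = np.round(world_to_voxel(vol, a.p1)).astype(int)
    i2 = np.round(world_to_voxel(vol, a.p2)).astype(int)
    pts = _bresenham_3d(i1, i2)
    shape = np.asarray(vol.shape)
    if np.any(pts < 0) or np.any(pts >= shape):
        raise ValueError("RECIST line leaves the image grid")
    return pts


def _ring_voxels(a: RecistAnnotation, vol: ImageVolume, radius_mm: float) -> np.ndarray:
    c = a.midpoint
    z = _slice_index(a, vol)
    sp = np.asarray(vol.spacing)
    n = max(16, int(math.ceil(2 * math.pi * radius_mm / min(sp[:2]) * 2)))
    ang = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    pts_mm = np.stack(
        [c[0] + radius_mm * np.cos(ang), c[1] + radius_mm * np.sin(ang)], axis=1
    )
    ij = np.round((pts_mm - np.asarray(vol.origin)[:2]) / sp[:2]).astype(int)
    shape = np.asarray(vol.shape)
    if np.any(ij < 0) or np.any(ij >= shape[:2]):
        raise ValueError(
            f"background ring (radius {radius_mm:.1f} mm) leaves the image grid"
        )
    ij = np.unique(ij, axis=0)
    return np.column_stack([ij, np.full(len(ij), z)])


def segment_solid(
    a: RecistAnnotation,
    vol: ImageVolume,
    lung: RoiMask,
    spec: RoiSpec | None = None,
) -> RoiMask:
    """Solid lesion component by seeded s-t min-cut on a 6-connected voxel graph.

    Hard foreground seeds are the voxels under the rasterized RECIST line; hard
    background seeds are a circle of radius ``ring_factor * L/2`` in the RECIST
    slice. Pairwise weights are ``exp(-dI^2 / (2 sigma_d^2))`` with a per-axis
    ``sigma_d`` estimated from intensity gradients in the seed neighborhoods
    (median squared 6-neighbor difference along that axis). The returned
    mask is the foreground connected component containing the line, intersected
    with the lung. A uniform image yields a degenerate result (the line seeds
    only), flagged via ``RoiMask.degenerate``.
    """
    spec = spec or RoiSpec()
    L = a.length_mm
    if L <= 0:
        raise ValueError("solid segmentation requires a RECIST line of positive length")
    fg = _line_voxels(a, vol)
    ring_radius = spec.ring_factor * L / 2.0
    bg = _ring_voxels(a, vol, ring_radius)

    fg_set = set(map(tuple, fg))
    if any(tuple(p) in fg_set for p in bg):
        raise SeedConflictError(
            f"background ring (radius {ring_radius:.1f} mm) intersects the RECIST line seeds; "
            "increase ring_factor so the ring circumscribes the lesion"
        )

    # working box: ring bounding box plus margin in-plane, +- L/2 in z
    sp = np.asarray(vol.spacing)
    shape = np.asarray(vol.shape)
    z0 = max(0, int(math.floor(a.slice_index - (L / 2.0) / sp[2])))
    z1 = min(shape[2] - 1, int(math.ceil(a.slice_index + (L / 2.0) / sp[2])))
    lo = np.array([max(0, bg[:, d].min() - 2) for d in range(2)] + [z0])
    hi = np.array([min(shape[d] - 1, bg[:, d].max() + 2) for d in range(2)] + [z1])
    box_shape = tuple(hi - lo + 1)
    img = vol.intensities[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1].astype(
        np.float64
    )

    def flat(pts):
        q = pts - lo
        return np.ravel_multi_index((q[:, 0], q[:, 1], q[:, 2]), box_shape)

    fg_ids, bg_ids = flat(fg), flat(bg)

    # sigma estimated per axis from seed-neighborhood gradients: the median
    # squared 6-neighbor difference. Per-axis because slice spacing is several
    # times the in-plane spacing (intensities decorrelate across slices);
    # median because seeds that touch strong edges (line endpoints on the
    # lesion boundary, ring segments crossing the lung border) would otherwise
    # dominate the scale.
    sigma2 = np.zeros(3)
    for d in range(3):
        grads = []
        for pts in (fg, bg):
            for sgn in (1, -1):
                nb = pts.copy()
                nb[:, d] += sgn
                ok = (nb[:, d] >= 0) & (nb[:, d] < shape[d])
                if ok.any():
                    grads.append(
                        vol.intensities[tuple(pts[ok].T)].astype(np.float64)
                        - vol.intensities[tuple(nb[ok].T)].astype(np.float64)
                    )
        sigma2[d] = float(np.median(np.concatenate(grads) ** 2))

    n_vox = int(np.prod(box_shape))
    src, snk = n_vox, n_vox + 1
    if np.all(sigma2 < 1e-12):
        log.warning("segment_solid: uniform image around seeds; returning degenerate line mask")
        out = np.zeros(vol.shape, dtype=bool)
        out[tuple(fg.T)] = True
        return RoiMask(
            out & lung.mask, vol.spacing, vol.origin, kind="solid", degenerate=True
        )

    edges, caps = [], []
    ids = np.arange(n_vox).reshape(box_shape)
    for d in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[d] = slice(0, -1)
        sl_b[d] = slice(1, None)
        ia = ids[tuple(sl_a)].ravel()
        ib = ids[tuple(sl_b)].ravel()
        dI = (img[tuple(sl_a)] - img[tuple(sl_b)]).ravel()
        w = np.exp(-(dI**2) / (2.0 * max(sigma2[d], 1.0))) + 1e-4
        edges.append(np.column_stack([ia, ib]))
        caps.append(w)
    edges = np.concatenate(edges)
    caps = np.concatenate(caps)
    inf_cap = float(caps.sum()) + 1.0

    t_edges = np.concatenate(
        [
            np.column_stack([np.full(len(fg_ids), src), fg_ids]),
            np.column_stack([bg_ids, np.full(len(bg_ids), snk)]),
        ]
    )
    all_edges = np.concatenate([edges, t_edges])
    all_caps = np.concatenate([caps, np.full(len(t_edges), inf_cap)])

    g = ig.Graph(n_vox + 2, list(map(tuple, all_edges)), directed=False)
    cut = g.st_mincut(src, snk, capacity=list(all_caps))
    side = cut.partition[0] if src in cut.partition[0] else cut.partition[1]
    fg_flat = np.zeros(n_vox, dtype=bool)
    side = [v for v in side if v < n_vox]
    fg_flat[side] = True
    box_mask = fg_flat.reshape(box_shape)

    # keep the 6-connected component containing the line seeds
    lbl, _ = ndimage.label(box_mask)
    keep = np.unique(lbl[tuple((fg - lo).T)])
    keep = keep[keep > 0]
    box_mask = np.isin(lbl, keep)

    out = np.zeros(vol.shape, dtype=bool)
    out[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = box_mask
    return RoiMask(_restrict(out, lung, "solid"), vol.spacing, vol.origin, kind="solid")


def expand_ggo(solid: RoiMask, width: float, lung: RoiMask) -> RoiMask:
    """Concentric expansion of the solid by ``width`` mm, excluding the solid.

    Distances are Euclidean in mm with the grid's anisotropic spacing.
    """
    if not solid.mask.any():
        raise ValueError("cannot expand an empty solid mask")
    if width <= 0:
        raise ValueError(f"expansion width must be > 0, got {width}")
    dist = ndimage.distance_transform_edt(~solid.mask, sampling=solid.spacing)
    shell = (dist <= width) & ~solid.mask
    out = _restrict(shell, lung, "ggo")
    return RoiMask(out, solid.spacing, solid.origin, kind="ggo", sub_label="ggo")


def build_all(
    a: RecistAnnotation, vol: ImageVolume, lung: RoiMask, spec: RoiSpec | None = None
) -> dict:
    """All six ROIs; the ``solid_ggo`` entry is a (solid, ggo) pair."""
    spec = spec or RoiSpec()
    out = {}
    builders = {
        "lung_slice": lambda: build_lung_slice(a, vol, lung),
        "cylinder": lambda: build_cylinder(a, spec.cylinder_radius, vol, lung),
        "sphere20": lambda: build_sphere(a, 20.0, vol, lung, kind="sphere20"),
        "sphere40": lambda: build_sphere(a, 40.0, vol, lung, kind="sphere40"),
        "sphere_recist": lambda: build_sphere(a, a.length_mm, vol, lung, kind="sphere_recist"),
    }
    for kind, fn in builders.items():
        try:
            out[kind] = fn()
        except Exception as exc:
            raise RuntimeError(f"ROI builder {kind!r} failed: {exc}") from exc
    try:
        solid = segment_solid(a, vol, lung, spec)
        ggo = expand_ggo(solid, spec.ggo_expansion, lung)
    except Exception as exc:
        raise RuntimeError(f"ROI builder 'solid_ggo' failed: {exc}") from exc
    out["solid_ggo"] = (solid, ggo)
    return out
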