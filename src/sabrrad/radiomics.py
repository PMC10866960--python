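"""Radiomic feature extraction: first-order, GLCM, GLRLM and shape features.

Texture matrices are computed in the four unique axial-plane neighbor
directions only (out-of-plane neighbors are excluded because slice spacing is
several times the in-plane spacing), and each texture feature is reported per
direction plus as the arithmetic mean over the four directions ("avg"), giving
five direction options. Intensities are discretized into equal-width bins over
the ROI min-max range before any matrix is built; first-order features are
computed on the raw HU values (entropy/uniformity on the discretized levels).

Feature membership is frozen in :mod:`sabrrad.manifest`: 20 first-order,
21 GLCM, 11 GLRLM, 24 shape; 180 features per single ROI and 384 for the
solid+GGO pair (which adds shape features on the solid sub-ROI).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .imaging import ImageVolume, RoiMask
from .manifest import (
    DIRECTION_OFFSETS,
    DIRECTIONS,
    FIRST_ORDER_NAMES,
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    SHAPE_NAMES,
)

__all__ = [
    "DiscretizationParams",
    "ExtractionError",
    "discretize",
    "first_order",
    "glcm",
    "glcm_features",
    "glrlm",
    "glrlm_features",
    "shape_features",
    "extract",
]


class ExtractionError(RuntimeError):
    """A feature could not be computed; the message names the feature."""


@dataclass(frozen=True)
class DiscretizationParams:
    """Gray-level discretization: ``n_levels`` equal-width bins.

    ``range_mode='roi_minmax'`` bins over the ROI's own min-max (default);
    ``'fixed_hu_window'`` uses ``hu_window`` (lo, hi) clipped.
    """

    n_levels: int = 32
    range_mode: str = "roi_minmax"
    hu_window: tuple[float, float] = (-1000.0, 400.0)

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError(f"n_levels must be >= 2, got {self.n_levels}")
        if self.range_mode not in ("roi_minmax", "fixed_hu_window"):
            raise ValueError(f"unknown range_mode {self.range_mode!r}")


def discretize(values: np.ndarray, disc: DiscretizationParams) -> np.ndarray:
    """Map intensities to integer levels 0 .. n_levels-1."""
    values = np.asarray(values, dtype=float)
    if disc.range_mode == "roi_minmax":
        lo, hi = float(values.min()), float(values.max())
    else:
        lo, hi = disc.hu_window
        values = np.clip(values, lo, hi)
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int32)
    lev = np.floor((values - lo) / (hi - lo) * disc.n_levels).astype(np.int32)
    return np.clip(lev, 0, disc.n_levels - 1)


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def first_order(vol: ImageVolume, roi: RoiMask, disc: DiscretizationParams | None = None) -> dict:
    """The 20 first-order features on the raw HU multiset within the ROI.

    Zero-variance convention: skewness and kurtosis are 0 for constant or
    single-voxel ROIs; the coefficient of variation is 0 when the mean is 0.
    """
    disc = disc or DiscretizationParams()
    if not roi.mask.any():
        raise ExtractionError("first_order: empty ROI")
    v = vol.intensities[roi.mask].astype(np.float64)
    n = v.size
    mean = float(v.mean())
    var = float(v.var())  # population variance
    sd = math.sqrt(var)
    if sd > 0:
        z = (v - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
    else:
        skew = kurt = 0.0
    p10, p25, p75, p90 = np.percentile(v, [10, 25, 75, 90])
    mid = v[(v >= p10) & (v <= p90)]
    rmad = float(np.abs(mid - mid.mean()).mean()) if mid.size else 0.0
    levels = discretize(v, disc)
    p = np.bincount(levels, minlength=disc.n_levels).astype(float) / n
    pz = p[p > 0]
    out = {
        "mean": mean,
        "median": float(np.median(v)),
        "minimum": float(v.min()),
        "maximum": float(v.max()),
        "range": float(v.max() - v.min()),
        "variance": var,
        "standard_deviation": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float(np.sum(v**2)),
        "entropy": float(-np.sum(pz * np.log2(pz))),
        "uniformity": float(np.sum(p**2)),
        "percentile10": float(p10),
        "percentile90": float(p90),
        "interquartile_range": float(p75 - p25),
        "mean_absolute_deviation": float(np.abs(v - mean).mean()),
        "robust_mean_absolute_deviation": rmad,
        "root_mean_square": float(np.sqrt(np.mean(v**2))),
        "coefficient_of_variation": float(sd / abs(mean)) if mean != 0 else 0.0,
        "total_intensity": float(v.sum()),
    }
    assert tuple(out) == FIRST_ORDER_NAMES
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _crop(vol: ImageVolume, roi: RoiMask):
    idx = np.argwhere(roi.mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return vol.intensities[sl], roi.mask[sl]


def glcm(
    vol: ImageVolume,
    roi: RoiMask,
    offset: tuple[int, int, int],
    disc: DiscretizationParams | None = None,
) -> np.ndarray:
    """Normalized symmetric gray-level co-occurrence matrix for one offset.

    Counts pairs (v, v+offset) with both voxels inside the ROI, accumulated in
    both orderings, normalized to sum 1. Matrix is n_levels x n_levels.
    """
    disc = disc or DiscretizationParams()
    offset = tuple(int(o) for o in offset)
    if offset not in set(DIRECTION_OFFSETS.values()):
        raise ValueError(f"offset must be an axial-plane neighbor offset, got {offset}")
    img, mask = _crop(vol, roi)
    levels = np.full(mask.shape, -1, dtype=np.int32)
    levels[mask] = discretize(img[mask], disc)
    a, b = _shifted_pairs(levels, offset)
    if a.size == 0:
        raise ExtractionError(f"glcm: no valid voxel pairs for offset {offset}")
    L = disc.n_levels
    counts = np.bincount(a * L + b, minlength=L * L).astype(np.float64).reshape(L, L)
    counts = counts + counts.T  # symmetric accumulation (both orderings)
    return counts / counts.sum()


def _shifted_pairs(levels: np.ndarray, offset):
    """Pairs of levels at (v, v+offset) where both voxels are inside the ROI."""
    sl_a, sl_b = [], []
    for d, o in enumerate(offset):
        n = levels.shape[d]
        if abs(o) >= n:
            return np.empty(0, np.int32), np.empty(0, np.int32)
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    a = levels[tuple(sl_a)].ravel()
    b = levels[tuple(sl_b)].ravel()
    ok = (a >= 0) & (b >= 0)
    return a[ok], b[ok]


def glcm_features(P: np.ndarray) -> dict:
    """The 21 GLCM features from a normalized co-occurrence matrix."""
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("GLCM must be square")
    if not math.isclose(P.sum(), 1.0, abs_tol=1e-6):
        raise ValueError(f"GLCM must be normalized to sum 1, sums to {P.sum()}")
    L = P.shape[0]
    i = np.arange(1, L + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    var_x = float(np.sum((i - mu_x) ** 2 * px))
    var_y = float(np.sum((i - mu_y) ** 2 * py))

    k_diff = np.arange(0, L, dtype=np.float64)
    p_diff = np.array([P[np.abs(I - J) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * L + 1, dtype=np.float64)
    p_sum = np.array([P[(I + J) == k].sum() for k in k_sum])

    def ent(q):
        q = q[q > 0]
        return float(-np.sum(q * np.log2(q))) if q.size else 0.0

    hxy = ent(P.ravel())
    hx, hy = ent(px), ent(py)
    pxy = np.outer(px, py)
    nz = pxy > 0
    hxy1 = float(-np.sum(P[nz] * np.log2(pxy[nz])))
    hxy2 = float(-np.sum(pxy[nz] * np.log2(pxy[nz])))

    da = float(np.sum(k_diff * p_diff))
    if var_x > 0 and var_y > 0:
        corr = float((np.sum(I * J * P) - mu_x * mu_y) / math.sqrt(var_x * var_y))
    else:
        corr = 1.0
    denom = max(hx, hy)
    imc1 = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))))
    off_diag = np.abs(I - J) > 0

    out = {
        "autocorrelation": float(np.sum(I * J * P)),
        "joint_average": mu_x,
        "cluster_prominence": float(np.sum((I + J - mu_x - mu_y) ** 4 * P)),
        "cluster_shade": float(np.sum((I + J - mu_x - mu_y) ** 3 * P)),
        "cluster_tendency": float(np.sum((I + J - mu_x - mu_y) ** 2 * P)),
        "contrast": float(np.sum((I - J) ** 2 * P)),
        "correlation": corr,
        "difference_average": da,
        "difference_entropy": ent(p_diff),
        "difference_variance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "joint_energy": float(np.sum(P**2)),
        "joint_entropy": hxy,
        "imc1": imc1,
        "imc2": imc2,
        "inverse_difference": float(np.sum(P / (1.0 + np.abs(I - J)))),
        "inverse_difference_normalized": float(np.sum(P / (1.0 + np.abs(I - J) / L))),
        "inverse_difference_moment": float(np.sum(P / (1.0 + (I - J) ** 2))),
        "inverse_difference_moment_normalized": float(np.sum(P / (1.0 + ((I - J) / L) ** 2))),
        "inverse_variance": float(np.sum(P[off_diag] / (I[off_diag] - J[off_diag]) ** 2)),
        "maximum_probability": float(P.max()),
        "sum_entropy": ent(p_sum),
    }
    assert tuple(out) == GLCM_FEATURE_NAMES
    return out


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _lines_2d(arr2d: np.ndarray, offset2d: tuple[int, int]):
    """1D lines of a 2D array along an in-plane direction."""
    if offset2d == (1, 0):
        for j in range(arr2d.shape[1]):
            yield arr2d[:, j]
    elif offset2d == (0, 1):
        for k in range(arr2d.shape[0]):
            yield arr2d[k, :]
    elif offset2d == (1, 1):
        for o in range(-arr2d.shape[0] + 1, arr2d.shape[1]):
            yield np.diagonal(arr2d, offset=o)
    elif offset2d == (-1, 1):
        flipped = arr2d[::-1, :]
        for o in range(-arr2d.shape[0] + 1, arr2d.shape[1]):
            yield np.diagonal(flipped, offset=o)
    else:
        raise ValueError(f"unsupported in-plane offset {offset2d}")


def _run_lengths(line: np.ndarray):
    """(value, run length) pairs for a 1D level line; -1 breaks and is dropped."""
    if line.size == 0:
        return
    change = np.flatnonzero(np.diff(line)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [line.size]])
    for s, e in zip(starts, ends):
        if line[s] >= 0:
            yield int(line[s]), int(e - s)


def glrlm(
    vol: ImageVolume,
    roi: RoiMask,
    direction: str,
    disc: DiscretizationParams | None = None,
) -> np.ndarray:
    """Gray-level run-length matrix R[level, run_length-1] for one axial direction.

    Runs of equal discretized level are counted along in-plane lines and are
    truncated at the ROI boundary (a non-ROI voxel ends the run).
    """
    disc = disc or DiscretizationParams()
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    off = DIRECTION_OFFSETS[direction]
    img, mask = _crop(vol, roi)
    levels = np.full(mask.shape, -1, dtype=np.int32)
    levels[mask] = discretize(img[mask], disc)
    max_run = max(mask.shape[0], mask.shape[1])
    R = np.zeros((disc.n_levels, max_run), dtype=np.float64)
    for z in range(levels.shape[2]):
        for line in _lines_2d(levels[:, :, z], (off[0], off[1])):
            for g, rl in _run_lengths(np.ascontiguousarray(line)):
                R[g, rl - 1] += 1
    if R.sum() == 0:
        raise ExtractionError(f"glrlm: no runs in direction {direction}")
    return R


def glrlm_features(R: np.ndarray, n_voxels: int) -> dict:
    """The 11 classical run-length features; RP uses the ROI voxel count."""
    R = np.asarray(R, dtype=np.float64)
    Nr = R.sum()
    if Nr == 0:
        raise ExtractionError("glrlm_features: empty run-length matrix")
    g = np.arange(1, R.shape[0] + 1, dtype=np.float64)[:, None]
    l = np.arange(1, R.shape[1] + 1, dtype=np.float64)[None, :]
    out = {
        "short_run_emphasis": float(np.sum(R / l**2) / Nr),
        "long_run_emphasis": float(np.sum(R * l**2) / Nr),
        "gray_level_nonuniformity": float(np.sum(R.sum(axis=1) ** 2) / Nr),
        "run_length_nonuniformity": float(np.sum(R.sum(axis=0) ** 2) / Nr),
        "run_percentage": float(Nr / n_voxels),
        "low_gray_level_run_emphasis": float(np.sum(R / g**2) / Nr),
        "high_gray_level_run_emphasis": float(np.sum(R * g**2) / Nr),
        "short_run_low_gray_level_emphasis": float(np.sum(R / (g**2 * l**2)) / Nr),
        "short_run_high_gray_level_emphasis": float(np.sum(R * g**2 / l**2) / Nr),
        "long_run_low_gray_level_emphasis": float(np.sum(R * l**2 / g**2) / Nr),
        "long_run_high_gray_level_emphasis": float(np.sum(R * g**2 * l**2) / Nr),
    }
    assert tuple(out) == GLRLM_FEATURE_NAMES
    return out


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise distance; uses the convex hull when possible."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(points) > 16 and points.shape[1] >= 2:
        try:
            pts = points[ConvexHull(points).vertices]
        except QhullError:
            pts = points
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


def _max_planar_diameter(coords: np.ndarray, plane_axes: tuple[int, int], normal_axis: int) -> float:
    """Max in-plane chord over planes perpendicular to ``normal_axis``."""
    best = 0.0
    vals = np.unique(coords[:, normal_axis])
    for v in vals:
        pts = coords[coords[:, normal_axis] == v][:, plane_axes]
        best = max(best, _max_pairwise(pts))
    return best


def shape_features(solid_mask: RoiMask) -> dict:
    """The 24 mesh/voxel shape descriptors in mm, for a 3D mask.

    Surface quantities come from a marching-cubes mesh of the mask; principal
    axis lengths are 4*sqrt(eigenvalue) of the voxel-center covariance; the
    convex hull is taken over boundary voxel corners so a digital cube has
    solidity 1.
    """
    if solid_mask.is_2d:
        raise ExtractionError("shape features are only defined for 3D (solid) ROIs")
    if not solid_mask.mask.any():
        raise ExtractionError("shape_features: empty mask")
    spacing = np.asarray(solid_mask.spacing)
    mask = solid_mask.mask
    n = int(mask.sum())
    voxel_volume = n * float(np.prod(spacing))

    # anti-alias the binary indicator (0.5 voxel Gaussian) so the iso-surface
    # does not carry the stair-step area bias of a raw binary marching cubes
    padded = ndimage.gaussian_filter(np.pad(mask, 2).astype(np.float64), sigma=0.5)
    if padded.max() <= 0.5:  # masks of a few voxels smooth below the iso-level
        padded = np.pad(mask, 2).astype(np.float64)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    surface_area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    mesh_volume = float(abs(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))) / 6.0)
    V = mesh_volume if mesh_volume > 0 else voxel_volume
    A = surface_area
    sphericity = (math.pi ** (1.0 / 3.0)) * ((6.0 * V) ** (2.0 / 3.0)) / A

    coords = np.argwhere(mask) * spacing
    if n > 1:
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        eigvals = np.clip(eigvals, 0.0, None)
    else:
        eigvals = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eigvals)).tolist()
    elongation = math.sqrt(eigvals[1] / eigvals[0]) if eigvals[0] > 0 else 1.0
    flatness = math.sqrt(eigvals[2] / eigvals[0]) if eigvals[0] > 0 else 1.0

    idx = np.argwhere(mask)
    bbox_volume = float(np.prod((idx.max(axis=0) - idx.min(axis=0) + 1) * spacing))

    eroded = ndimage.binary_erosion(mask)
    boundary = np.argwhere(mask & ~eroded)
    # convex hull over the 8 corners of each boundary voxel
    half = spacing / 2.0
    offs = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]) * half
    corners = (boundary * spacing)[:, None, :] + offs[None, :, :]
    corners = corners.reshape(-1, 3)
    try:
        hull = ConvexHull(corners)
        hull_volume = float(hull.volume)
        hull_area = float(hull.area)
    except QhullError:
        hull_volume, hull_area = voxel_volume, surface_area

    bcenters = boundary * spacing
    out = {
        "voxel_volume": voxel_volume,
        "mesh_volume": mesh_volume,
        "surface_area": surface_area,
        "surface_to_volume_ratio": A / V,
        "sphericity": sphericity,
        "compactness1": V / (math.sqrt(math.pi) * A**1.5),
        "compactness2": 36.0 * math.pi * V**2 / A**3,
        "spherical_disproportion": 1.0 / sphericity,
        "equivalent_diameter": 2.0 * (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0),
        "maximum_3d_diameter": _max_pairwise(bcenters),
        "maximum_2d_diameter_axial": _max_planar_diameter(bcenters, (0, 1), 2),
        "maximum_2d_diameter_coronal": _max_planar_diameter(bcenters, (0, 2), 1),
        "maximum_2d_diameter_sagittal": _max_planar_diameter(bcenters, (1, 2), 0),
        "major_axis_length": major,
        "minor_axis_length": minor,
        "least_axis_length": least,
        "elongation": elongation,
        "flatness": flatness,
        "bounding_box_volume": bbox_volume,
        "extent": voxel_volume / bbox_volume,
        "convex_hull_volume": hull_volume,
        "solidity": voxel_volume / hull_volume,
        "convex_hull_surface_area": hull_area,
        "surface_roughness": surface_area / hull_area,
    }
    assert tuple(out) == SHAPE_NAMES
    return out


# ---------------------------------------------------------------------------
# extraction driver
# ---------------------------------------------------------------------------

def _texture_block(vol, roi, label, disc) -> dict:
    out = {}
    for name, value in first_order(vol, roi, disc).items():
        out[f"{label}|firstorder|{name}"] = value
    per_dir_glcm = {}
    per_dir_glrlm = {}
    n_vox = roi.count()
    for direction in DIRECTIONS:
        try:
            P = glcm(vol, roi, DIRECTION_OFFSETS[direction], disc)
            per_dir_glcm[direction] = glcm_features(P)
            R = glrlm(vol, roi, direction, disc)
            per_dir_glrlm[direction] = glrlm_features(R, n_vox)
        except Exception as exc:
            raise ExtractionError(f"{label}|texture|{direction}: {exc}") from exc
    for family, per_dir, names in (
        ("glcm", per_dir_glcm, GLCM_FEATURE_NAMES),
        ("glrlm", per_dir_glrlm, GLRLM_FEATURE_NAMES),
    ):
        for fname in names:
            vals = [per_dir[d][fname] for d in DIRECTIONS]
            for d, v in zip(DIRECTIONS, vals):
                out[f"{label}|{family}|{fname}|{d}"] = v
            out[f"{label}|{family}|{fname}|avg"] = float(np.mean(vals))
    return out


def extract(
    vol: ImageVolume,
    rois,
    roi_kind: str,
    disc: DiscretizationParams | None = None,
) -> dict:
    """Extract the full feature vector for one ROI kind on one case.

    ``rois`` is a single :class:`RoiMask`, or a (solid, ggo) pair for the
    ``solid_ggo`` kind. Single kinds yield exactly 180 features; solid+GGO
    yields 180 + 180 + 24 = 384 (shape on the solid sub-ROI only). All values
    are finite.
    """
    disc = disc or DiscretizationParams()
    out = {}
    if roi_kind == "solid_ggo":
        solid, ggo = rois
        out.update(_texture_block(vol, solid, "solid", disc))
        out.update(_texture_block(vol, ggo, "ggo", disc))
        try:
            for name, value in shape_features(solid).items():
                out[f"solid|shape|{name}"] = value
        except Exception as exc:
            raise ExtractionError(f"solid|shape: {exc}") from exc
    else:
        out.update(_texture_block(vol, rois, roi_kind, disc))
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise ExtractionError(f"non-finite feature values: {bad[:5]}")
    return out
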