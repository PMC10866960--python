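"""Synthetic post-SABR lung CT phantoms.

Generates cohorts of 3D CT-like volumes with a lung mask, a lesion whose
longest axial diameter triggers RECIST progressive disease on a serial
measurement schedule, and two outcome classes (cancer recurrence vs
radiation-induced lung injury, RILI) that differ in within-lesion mean
density, texture homogeneity, and intensity skewness:

* recurrence lesions are denser (higher mean HU), smoother (longer spatial
  correlation length, lower noise amplitude -> higher GLCM maximum/joint
  energy) and symmetric in their intensity histogram;
* RILI lesions are less dense, noisier, and positively skewed.

Lesions are unions of 2-4 overlapping ellipsoids whose in-plane footprint is
bounded by a disc of the requested diameter, so the longest axial chord of the
continuous shape equals the requested diameter exactly and the voxelized chord
is within one in-plane voxel of it. The PD-scan lesion size is drawn from the
same distribution in both classes, so lesion size carries no outcome signal.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .imaging import ImageVolume, RoiMask, write_mask, write_volume
from .recist import RecistAnnotation, find_pd_scan

__all__ = [
    "PhantomParams",
    "PhantomCase",
    "generate_cohort",
    "synthesize_lesion",
    "derive_recist_line",
    "write_cohort",
]

CLASS_NAMES = ("recurrence", "rili")

# HU of tissue outside the lung (chest wall stand-in) and of the GGO halo core.
_BODY_HU = 20.0
_GGO_CORE_HU = -600.0


def _check_class_map(name, value):
    if set(value) != set(CLASS_NAMES):
        raise ValueError(f"{name} keys must be exactly {set(CLASS_NAMES)}, got {set(value)}")
    return dict(value)


@dataclass
class PhantomParams:
    """Cohort-level generation parameters; defaults are the study conditions.

    Spacing defaults to the common resampled grid (0.74 x 0.74 x 5.00 mm);
    ``randomize_spacing`` instead draws per-case spacing from the scanner
    ranges (0.57-0.84 mm in-plane, 1.5-5.0 mm slices) so the resampling stage
    is exercised. Lesion PD-scan diameter is truncated-normal with mean 55 mm.
    """

    n_cases: int = 68
    prevalence: float = 0.41  # fraction labeled recurrence
    voxel_spacing: tuple[float, float, float] = (0.74, 0.74, 5.0)
    grid_shape: tuple[int, int, int] = (128, 128, 42)
    lung_hu_mean: float = -850.0
    lung_hu_sd: float = 40.0
    lesion_hu_mean_by_class: dict = field(
        default_factory=lambda: {"recurrence": -50.0, "rili": -150.0}
    )
    lesion_noise_sd_by_class: dict = field(
        default_factory=lambda: {"recurrence": 40.0, "rili": 80.0}
    )
    lesion_texture_corr_len_by_class: dict = field(
        default_factory=lambda: {"recurrence": 3.0, "rili": 1.0}
    )
    lesion_skew_by_class: dict = field(
        default_factory=lambda: {"recurrence": 0.0, "rili": 4.0}
    )
    lesion_diameter_mean: float = 55.0
    lesion_diameter_sd: float = 8.0
    lesion_diameter_range: tuple[float, float] = (30.0, 60.0)
    ggo_halo_width: float = 10.0
    n_followups: int = 2
    growth_schedule_by_class: dict = field(
        default_factory=lambda: {"recurrence": (1.0, 1.1, 1.35), "rili": (1.0, 0.7, 1.0)}
    )
    randomize_spacing: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if self.n_cases < 1:
            raise ValueError(f"n_cases must be >= 1, got {self.n_cases}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be positive, got {self.voxel_spacing}")
        if self.lesion_diameter_sd < 0:
            raise ValueError(f"lesion_diameter_sd must be >= 0, got {self.lesion_diameter_sd}")
        for name in (
            "lesion_hu_mean_by_class",
            "lesion_noise_sd_by_class",
            "lesion_texture_corr_len_by_class",
            "lesion_skew_by_class",
            "growth_schedule_by_class",
        ):
            setattr(self, name, _check_class_map(name, getattr(self, name)))
        for cls, sched in self.growth_schedule_by_class.items():
            sched = tuple(float(v) for v in sched)
            if len(sched) != self.n_followups + 1:
                raise ValueError(
                    f"growth_schedule_by_class[{cls!r}] must have n_followups+1 "
                    f"= {self.n_followups + 1} entries, got {len(sched)}"
                )
            self.growth_schedule_by_class[cls] = sched

    @classmethod
    def null(cls, **overrides) -> "PhantomParams":
        """Parameters with all class-conditional contrasts removed.

        Both classes share the averaged lesion appearance, so every feature is
        outcome-independent and downstream AUCs should be ~0.5.
        """
        base = cls(**overrides)
        for name in (
            "lesion_hu_mean_by_class",
            "lesion_noise_sd_by_class",
            "lesion_texture_corr_len_by_class",
            "lesion_skew_by_class",
        ):
            m = getattr(base, name)
            avg = (m["recurrence"] + m["rili"]) / 2.0
            setattr(base, name, {"recurrence": avg, "rili": avg})
        return base


@dataclass
class PhantomCase:
    """One synthetic patient at the PD decision point."""

    case_id: str
    volume: ImageVolume
    lung_mask: RoiMask
    lesion_mask_truth: RoiMask
    recist_series: list  # list[RecistAnnotation], one per scan
    label: str
    pd_scan_index: int | None

    @property
    def pd_annotation(self) -> RecistAnnotation:
        if self.pd_scan_index is None:
            raise ValueError(f"case {self.case_id} never triggered PD")
        return self.recist_series[self.pd_scan_index]

    @property
    def lengths_mm(self) -> tuple[float, ...]:
        return tuple(a.length_mm for a in self.recist_series)


def _ellipsoid_union_mask(shape, spacing, ellipsoids) -> np.ndarray:
    """Voxelize a union of ellipsoids given as (center_mm, semi_axes_mm, theta)."""
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for c, ax, _ in ellipsoids:
        lo = np.minimum(lo, np.asarray(c) - np.max(ax))
        hi = np.maximum(hi, np.asarray(c) + np.max(ax))
    i0 = np.maximum(0, np.floor(lo / spacing).astype(int))
    i1 = np.minimum(np.asarray(shape) - 1, np.ceil(hi / spacing).astype(int))
    if np.any(i1 < i0):
        return np.zeros(shape, dtype=bool)
    xs = [np.arange(i0[d], i1[d] + 1) * spacing[d] for d in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    sub = np.zeros(X.shape, dtype=bool)
    for c, ax, theta in ellipsoids:
        dx, dy, dz = X - c[0], Y - c[1], Z - c[2]
        ct, st = math.cos(theta), math.sin(theta)
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        sub |= (u / ax[0]) ** 2 + (v / ax[1]) ** 2 + (dz / ax[2]) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[i0[0] : i1[0] + 1, i0[1] : i1[1] + 1, i0[2] : i1[2] + 1] = sub
    return mask


def synthesize_lesion(
    center,
    diameter: float,
    texture_corr_len: float,
    hu_mean: float,
    rng: np.random.Generator,
    *,
    spacing=(0.74, 0.74, 5.0),
    grid_shape=(128, 128, 42),
    noise_sd: float = 60.0,
    skew: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize one lesion: a connected ellipsoid-union blob with textured HU.

    Returns ``(mask, patch)``: a full-grid boolean mask and a full-grid float
    array whose values are valid inside the mask. Intensities are spatially
    correlated noise (white noise smoothed with a Gaussian of length
    ``texture_corr_len`` mm, rescaled to ``noise_sd``) around ``hu_mean``;
    ``skew`` sets the marginal skew-normal shape parameter of the raw noise.
    The blob's longest axial chord of the continuous shape equals ``diameter``.
    """
    if diameter <= 0:
        raise ValueError(f"diameter must be > 0, got {diameter}")
    center = np.asarray(center, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    grid_shape = tuple(int(n) for n in grid_shape)
    r = diameter / 2.0

    # Main ellipsoid: in-plane semi-axes (r, f*r) rotated in-plane; z semi-axis h*r.
    f = rng.uniform(0.65, 0.9)
    h = rng.uniform(0.5, 0.8)
    theta = rng.uniform(0.0, math.pi)
    ellipsoids = [(center, (r, f * r, h * r), theta)]
    # 1-3 bumps constrained so no point leaves the in-plane disc of radius r
    # nor the z slab of half-height h*r: |offset| + semi-axis <= bound.
    for _ in range(int(rng.integers(1, 4))):
        phi = rng.uniform(0.0, 2 * math.pi)
        rho = rng.uniform(0.15, 0.35) * diameter
        off_z = rng.uniform(-0.2, 0.2) * h * r
        want = rng.uniform(0.2, 0.4) * diameter
        b_xy = min(want, r - rho - 1e-6)
        b_z = min(want * h, h * r - abs(off_z) - 1e-6)
        if b_xy <= 0 or b_z <= 0:
            continue
        c = center + np.array([rho * math.cos(phi), rho * math.sin(phi), off_z])
        ellipsoids.append((c, (b_xy, b_xy, b_z), 0.0))

    # reject lesions that leave the grid
    extent = np.asarray(grid_shape) * spacing
    if np.any(center - r < -1e-9) or np.any(center + r > extent + 1e-9):
        raise ValueError(
            f"lesion (center {center.tolist()}, diameter {diameter}) extends beyond the grid"
        )

    mask = _ellipsoid_union_mask(grid_shape, spacing, ellipsoids)
    if not mask.any():
        # diameter far below one voxel: take the voxel containing the center
        idx = tuple(np.clip(np.round(center / spacing).astype(int), 0, np.asarray(grid_shape) - 1))
        mask = np.zeros(grid_shape, dtype=bool)
        mask[idx] = True

    patch = textured_field(
        grid_shape, spacing, texture_corr_len, rng, skew=skew, mean=hu_mean, sd=noise_sd
    )
    return mask, patch


def textured_field(grid_shape, spacing, corr_len_mm, rng, *, skew=0.0, mean=0.0, sd=1.0) -> np.ndarray:
    """Smoothed (skew-)normal white noise rescaled to the requested mean/sd."""
    if skew == 0.0:
        noise = rng.standard_normal(grid_shape)
    else:
        noise = stats.skewnorm.rvs(skew, size=grid_shape, random_state=rng)
    sigma_vox = float(corr_len_mm) / np.asarray(spacing, dtype=float)
    if np.any(sigma_vox > 1e-6):
        noise = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    s = noise.std()
    if s > 0:
        noise = (noise - noise.mean()) / s
    return mean + sd * noise


def derive_recist_line(
    lesion_mask: RoiMask, slice_axis: int = 2, scan_index: int = 0
) -> RecistAnnotation:
    """Longest chord between boundary voxel centers within a single axial slice.

    The chord is maximized per slice and across slices; ties are broken toward
    the lexicographically smallest (p1, p2) endpoint pair.
    """
    if slice_axis != 2:
        raise ValueError("slice axis must be the z axis (2)")
    mask = lesion_mask.mask
    if not mask.any():
        raise ValueError("cannot derive a RECIST line from an empty mask")
    spacing = np.asarray(lesion_mask.spacing)
    origin = np.asarray(lesion_mask.origin)
    best = (-1.0, None, None, None)  # length, p1, p2, slice
    for z in np.flatnonzero(mask.any(axis=(0, 1))):
        sl = mask[:, :, z]
        boundary = sl & ~ndimage.binary_erosion(sl)
        pts = np.argwhere(boundary)
        # lexicographic order so the first argmax is the smallest endpoint pair
        pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
        xy = pts * spacing[:2]
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        k = int(np.argmax(d2))
        i, j = divmod(k, len(pts))
        length = math.sqrt(d2[i, j])
        if length > best[0] + 1e-9:
            zw = z * spacing[2] + origin[2]
            p1 = (*(xy[i] + origin[:2]), zw)
            p2 = (*(xy[j] + origin[:2]), zw)
            if p2 < p1:
                p1, p2 = p2, p1
            best = (length, p1, p2, int(z))
    return RecistAnnotation(best[1], best[2], slice_index=best[3], scan_index=scan_index)


def _truncnorm(rng, mean, sd, lo, hi):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_cohort(params: PhantomParams) -> list[PhantomCase]:
    """Generate ``params.n_cases`` phantom cases; identical seed => identical output.

    Labels are assigned by exact stratification: round(prevalence * n_cases)
    cases are recurrence, shuffled deterministically.
    """
    n = params.n_cases
    n_pos = int(round(params.prevalence * n))
    labels = ["recurrence"] * n_pos + ["rili"] * (n - n_pos)
    root = np.random.default_rng(params.seed)
    root.shuffle(labels)
    seeds = np.random.SeedSequence(params.seed).spawn(n)
    cases = []
    for i in range(n):
        rng = np.random.default_rng(seeds[i])
        cases.append(_generate_case(f"case{i:03d}", labels[i], params, rng))
    return cases


def _generate_case(case_id, label, params: PhantomParams, rng) -> PhantomCase:
    if params.randomize_spacing:
        sp_xy = rng.uniform(0.57, 0.84)
        spacing = (sp_xy, sp_xy, rng.uniform(1.5, 5.0))
        # keep the physical extent fixed by scaling the grid
        base_extent = np.asarray(params.grid_shape) * np.asarray(params.voxel_spacing)
        shape = tuple(int(round(e / s)) for e, s in zip(base_extent, spacing))
    else:
        spacing = params.voxel_spacing
        shape = params.grid_shape
    spacing_arr = np.asarray(spacing)
    extent = np.asarray(shape) * spacing_arr

    schedule = params.growth_schedule_by_class[label]
    d_pd_target = _truncnorm(
        rng, params.lesion_diameter_mean, params.lesion_diameter_sd, *params.lesion_diameter_range
    )
    # anchor the PD-scan diameter at d_pd_target: pick the scan t where, with
    # baseline = d/schedule[t], the mm-series first triggers PD exactly at t
    pd_idx = None
    for t in range(1, len(schedule)):
        candidate = [d_pd_target / schedule[t] * fac for fac in schedule]
        if find_pd_scan(candidate) == t:
            pd_idx = t
            lengths = candidate
            break
    if pd_idx is None:
        raise ValueError(
            f"growth_schedule_by_class[{label!r}]={schedule} never triggers PD "
            f"at diameter {d_pd_target:.1f} mm"
        )

    center = extent / 2.0 + np.array(
        [rng.uniform(-3.0, 3.0), rng.uniform(-3.0, 3.0), rng.uniform(-spacing[2], spacing[2])]
    )
    lesion_mask, patch = synthesize_lesion(
        center,
        d_pd_target,
        params.lesion_texture_corr_len_by_class[label],
        params.lesion_hu_mean_by_class[label],
        rng,
        spacing=spacing,
        grid_shape=shape,
        noise_sd=params.lesion_noise_sd_by_class[label],
        skew=params.lesion_skew_by_class[label],
    )

    # lung: an axis-aligned ellipsoid filling ~96% of the grid
    xs = [np.arange(shape[d]) * spacing[d] for d in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    semi = 0.48 * extent
    c = extent / 2.0
    lung = ((X - c[0]) / semi[0]) ** 2 + ((Y - c[1]) / semi[1]) ** 2 + (
        (Z - c[2]) / semi[2]
    ) ** 2 <= 1.0
    lung |= lesion_mask  # lesion is always inside the lung volume

    intensities = np.full(shape, _BODY_HU, dtype=np.float32)
    parenchyma = textured_field(
        shape, spacing, 2.0, rng, mean=params.lung_hu_mean, sd=params.lung_hu_sd
    )
    intensities[lung] = parenchyma[lung].astype(np.float32)

    # GGO halo: fade from a -600 HU core at the solid edge back to parenchyma
    dist = ndimage.distance_transform_edt(~lesion_mask, sampling=spacing)
    halo = (dist <= params.ggo_halo_width) & ~lesion_mask & lung
    w = 1.0 - dist[halo] / params.ggo_halo_width
    intensities[halo] = (
        parenchyma[halo] + (_GGO_CORE_HU - params.lung_hu_mean) * w
    ).astype(np.float32)
    intensities[lesion_mask] = patch[lesion_mask].astype(np.float32)

    volume = ImageVolume(intensities, tuple(spacing), (0.0, 0.0, 0.0))
    lung_roi = RoiMask(lung, tuple(spacing), (0.0, 0.0, 0.0), kind="lung")
    truth = RoiMask(lesion_mask, tuple(spacing), (0.0, 0.0, 0.0), kind="lesion_truth")

    # re-anchor the whole series on the voxelized PD-scan length so the
    # schedule's ratios (and hence the PD trigger) hold exactly as configured
    pd_ann = derive_recist_line(truth, scan_index=pd_idx)
    rescale = pd_ann.length_mm / lengths[pd_idx]
    lengths = [L * rescale for L in lengths]
    series = []
    for t, L in enumerate(lengths):
        if t == pd_idx:
            series.append(pd_ann)
            continue
        # non-PD scans carry only a length; synthesize endpoints about the center
        half = np.array([L / 2.0, 0.0, 0.0])
        z_idx = int(round(center[2] / spacing[2]))
        p1 = (center - half).tolist()
        p2 = (center + half).tolist()
        p1[2] = p2[2] = z_idx * spacing[2]
        series.append(RecistAnnotation(tuple(p1), tuple(p2), slice_index=z_idx, scan_index=t))

    observed_pd = find_pd_scan([a.length_mm for a in series])
    return PhantomCase(case_id, volume, lung_roi, truth, series, label, observed_pd)


def write_cohort(cases, out_dir, fmt: str = ".nii.gz") -> Path:
    """Write volumes/masks plus the annotation table; returns the table path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        write_volume(case.volume, out_dir / f"{case.case_id}_ct{fmt}")
        write_mask(case.lung_mask, out_dir / f"{case.case_id}_lung{fmt}")
        write_mask(case.lesion_mask_truth, out_dir / f"{case.case_id}_lesion{fmt}")
        for a in case.recist_series:
            rows.append(
                {
                    "case_id": case.case_id,
                    "scan_index": a.scan_index,
                    "x1": a.p1[0],
                    "y1": a.p1[1],
                    "z": a.p1[2],
                    "x2": a.p2[0],
                    "y2": a.p2[1],
                    "length_mm": a.length_mm,
                    "label": case.label,
                }
            )
    table = out_dir / "annotations.csv"
    with open(table, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return table
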