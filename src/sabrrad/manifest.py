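"""Frozen feature manifest: the exact membership of each feature family.

The counts (20 first-order, 21 GLCM, 11 GLRLM, 24 shape) are contracts the
extraction pipeline and its tests pin against this module. Texture features
come in five direction options (0/45/90/135 degrees in the axial plane plus
their average), giving 20 + (21 + 11) * 5 = 180 features per ROI, and
180 + 180 + 24 = 384 for the solid+GGO pair.
"""
from __future__ import annotations

MANIFEST_VERSION = "1.0"

FIRST_ORDER_NAMES = (
    "mean",
    "median",
    "minimum",
    "maximum",
    "range",
    "variance",
    "standard_deviation",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
    "uniformity",
    "percentile10",
    "percentile90",
    "interquartile_range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "root_mean_square",
    "coefficient_of_variation",
    "total_intensity",
)

GLCM_FEATURE_NAMES = (
    "autocorrelation",
    "joint_average",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "joint_energy",
    "joint_entropy",
    "imc1",
    "imc2",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment",
    "inverse_difference_moment_normalized",
    "inverse_variance",
    "maximum_probability",
    "sum_entropy",
)

GLRLM_FEATURE_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
)

SHAPE_NAMES = (
    "voxel_volume",
    "mesh_volume",
    "surface_area",
    "surface_to_volume_ratio",
    "sphericity",
    "compactness1",
    "compactness2",
    "spherical_disproportion",
    "equivalent_diameter",
    "maximum_3d_diameter",
    "maximum_2d_diameter_axial",
    "maximum_2d_diameter_coronal",
    "maximum_2d_diameter_sagittal",
    "major_axis_length",
    "minor_axis_length",
    "least_axis_length",
    "elongation",
    "flatness",
    "bounding_box_volume",
    "extent",
    "convex_hull_volume",
    "solidity",
    "convex_hull_surface_area",
    "surface_roughness",
)

DIRECTIONS = ("0", "45", "90", "135")
DIRECTION_OPTIONS = DIRECTIONS + ("avg",)

# axial-plane voxel offsets (x, y, z) per direction label
DIRECTION_OFFSETS = {
    "0": (1, 0, 0),
    "45": (1, 1, 0),
    "90": (0, 1, 0),
    "135": (-1, 1, 0),
}

N_FIRST_ORDER = len(FIRST_ORDER_NAMES)  # 20
N_GLCM = len(GLCM_FEATURE_NAMES)  # 21
N_GLRLM = len(GLRLM_FEATURE_NAMES)  # 11
N_SHAPE = len(SHAPE_NAMES)  # 24
N_TEXTURE_PER_ROI = N_FIRST_ORDER + (N_GLCM + N_GLRLM) * len(DIRECTION_OPTIONS)  # 180
N_SOLID_GGO = 2 * N_TEXTURE_PER_ROI + N_SHAPE  # 384


def feature_manifest() -> dict:
    """The full manifest as a serializable mapping."""
    return {
        "version": MANIFEST_VERSION,
        "first_order": list(FIRST_ORDER_NAMES),
        "glcm": list(GLCM_FEATURE_NAMES),
        "glrlm": list(GLRLM_FEATURE_NAMES),
        "shape": list(SHAPE_NAMES),
        "directions": list(DIRECTION_OPTIONS),
        "counts": {
            "first_order": N_FIRST_ORDER,
            "glcm": N_GLCM,
            "glrlm": N_GLRLM,
            "shape": N_SHAPE,
            "per_roi": N_TEXTURE_PER_ROI,
            "solid_ggo": N_SOLID_GGO,
        },
    }
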