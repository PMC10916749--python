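"""The versioned 215-feature manifest.

The feature vector has a fixed, documented order: 79 first-order features
followed by 136 3D texture features.  The directional families (GLCM,
GLRLM) appear twice, once per aggregation scheme: ``merged`` pools counts
over the 13 directions into one matrix before computing features,
``averaged`` computes features per direction and averages them.  The
direction-free families (GLSZM, GLDZM, NGLDM, NGTDM) appear once.

Family sizes: GLCM 25 x 2 + GLRLM 16 x 2 + GLSZM 16 + GLDZM 16 + NGLDM 17
+ NGTDM 5 = 136 texture features.
"""

from __future__ import annotations

from functools import lru_cache

MANIFEST_VERSION = "1.0"

_MORPH = [
    "voxel_count", "volume_mm3", "surface_area_mm2", "surface_to_volume_ratio",
    "compactness_1", "compactness_2", "spherical_disproportion", "sphericity",
    "asphericity", "centre_of_mass_shift_mm", "max_diameter_mm",
    "major_axis_length_mm", "minor_axis_length_mm", "least_axis_length_mm",
    "elongation", "flatness", "volume_density_aabb", "integrated_intensity",
]

_LOCAL = ["local_intensity_peak", "global_intensity_peak"]

_STAT = [
    "mean", "variance", "standard_deviation", "skewness", "excess_kurtosis",
    "median", "minimum", "maximum", "range", "percentile_10", "percentile_25",
    "percentile_75", "percentile_90", "interquartile_range",
    "mean_absolute_deviation", "robust_mean_absolute_deviation",
    "median_absolute_deviation", "coefficient_of_variation",
    "quartile_coefficient_of_dispersion", "energy", "root_mean_square", "sum",
]

_IH = [
    "mean", "variance", "standard_deviation", "skewness", "excess_kurtosis",
    "median", "minimum", "maximum", "range", "percentile_10", "percentile_25",
    "percentile_75", "percentile_90", "interquartile_range",
    "mean_absolute_deviation", "robust_mean_absolute_deviation",
    "median_absolute_deviation", "coefficient_of_variation",
    "quartile_coefficient_of_dispersion", "mode", "entropy", "uniformity",
    "max_histogram_gradient", "max_histogram_gradient_level",
    "min_histogram_gradient", "min_histogram_gradient_level",
]

_IVH = (
    [f"volume_at_intensity_{q}" for q in (10, 25, 50, 75, 90)]
    + [f"intensity_at_volume_{q}" for q in (10, 25, 50, 75, 90)]
    + ["auc"]
)

_GLCM = [
    "joint_maximum", "joint_average", "joint_variance", "joint_entropy",
    "difference_average", "difference_variance", "difference_entropy",
    "sum_average", "sum_variance", "sum_entropy", "angular_second_moment",
    "contrast", "dissimilarity", "inverse_difference",
    "inverse_difference_normalised", "inverse_difference_moment",
    "inverse_difference_moment_normalised", "inverse_variance", "correlation",
    "autocorrelation", "cluster_tendency", "cluster_shade",
    "cluster_prominence", "information_correlation_1",
    "information_correlation_2",
]

_GLRLM = [
    "short_run_emphasis", "long_run_emphasis", "low_grey_level_run_emphasis",
    "high_grey_level_run_emphasis", "short_run_low_grey_level_emphasis",
    "short_run_high_grey_level_emphasis", "long_run_low_grey_level_emphasis",
    "long_run_high_grey_level_emphasis", "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised", "run_length_non_uniformity",
    "run_length_non_uniformity_normalised", "run_percentage",
    "grey_level_variance", "run_length_variance", "run_entropy",
]

_GLSZM = [
    "small_zone_emphasis", "large_zone_emphasis", "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis", "small_zone_low_grey_level_emphasis",
    "small_zone_high_grey_level_emphasis", "large_zone_low_grey_level_emphasis",
    "large_zone_high_grey_level_emphasis", "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised", "zone_size_non_uniformity",
    "zone_size_non_uniformity_normalised", "zone_percentage",
    "grey_level_variance", "zone_size_variance", "zone_size_entropy",
]

_GLDZM = [
    "small_distance_emphasis", "large_distance_emphasis",
    "low_grey_level_zone_emphasis", "high_grey_level_zone_emphasis",
    "small_distance_low_grey_level_emphasis",
    "small_distance_high_grey_level_emphasis",
    "large_distance_low_grey_level_emphasis",
    "large_distance_high_grey_level_emphasis", "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised", "zone_distance_non_uniformity",
    "zone_distance_non_uniformity_normalised", "zone_percentage",
    "grey_level_variance", "zone_distance_variance", "zone_distance_entropy",
]

_NGLDM = [
    "low_dependence_emphasis", "high_dependence_emphasis",
    "low_grey_level_count_emphasis", "high_grey_level_count_emphasis",
    "low_dependence_low_grey_level_emphasis",
    "low_dependence_high_grey_level_emphasis",
    "high_dependence_low_grey_level_emphasis",
    "high_dependence_high_grey_level_emphasis", "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised", "dependence_count_non_uniformity",
    "dependence_count_non_uniformity_normalised", "dependence_count_percentage",
    "grey_level_variance", "dependence_count_variance",
    "dependence_count_entropy", "dependence_count_energy",
]

_NGTDM = ["coarseness", "contrast", "busyness", "complexity", "strength"]


@lru_cache(maxsize=1)
def first_order_names() -> tuple[str, ...]:
    names = (
        ["morph_" + n for n in _MORPH]
        + _LOCAL
        + ["stat_" + n for n in _STAT]
        + ["ih_" + n for n in _IH]
        + ["ivh_" + n for n in _IVH]
    )
    return tuple("firstorder." + n for n in names)


@lru_cache(maxsize=1)
def texture_names() -> tuple[str, ...]:
    names: list[str] = []
    for agg in ("merged", "averaged"):
        names += [f"glcm.{agg}.{n}" for n in _GLCM]
    for agg in ("merged", "averaged"):
        names += [f"glrlm.{agg}.{n}" for n in _GLRLM]
    names += ["glszm." + n for n in _GLSZM]
    names += ["gldzm." + n for n in _GLDZM]
    names += ["ngldm." + n for n in _NGLDM]
    names += ["ngtdm." + n for n in _NGTDM]
    return tuple(names)


@lru_cache(maxsize=1)
def feature_manifest() -> tuple[str, ...]:
    """The full ordered 215-name manifest (79 first-order + 136 texture)."""
    manifest = first_order_names() + texture_names()
    assert len(manifest) == 215, f"manifest has {len(manifest)} names"
    return manifest
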