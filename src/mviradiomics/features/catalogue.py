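"""Canonical catalogue of the 94 radiomic features.

Six families: 19 first-order intensity statistics and five gray-level
texture-matrix families (GLCM 24, GLSZM 16, GLRLM 16, NGTDM 5, GLDM 14).
Feature names follow the ``<family>_<feature>`` convention; the phase prefix
is added when per-phase vectors are concatenated into a cohort matrix.
"""

from __future__ import annotations

FIRSTORDER_FEATURES: tuple[str, ...] = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
    "StandardDeviation",
)

GLCM_FEATURES: tuple[str, ...] = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
    "MCC",
)

GLSZM_FEATURES: tuple[str, ...] = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLRLM_FEATURES: tuple[str, ...] = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

NGTDM_FEATURES: tuple[str, ...] = (
    "Coarseness",
    "Contrast",
    "Busyness",
    "Complexity",
    "Strength",
)

GLDM_FEATURES: tuple[str, ...] = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

FAMILIES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
    "gldm": GLDM_FEATURES,
}

#: Expected family cardinalities; asserted at import so a catalogue edit
#: that breaks the 94-feature contract fails loudly.
FAMILY_SIZES: dict[str, int] = {
    "firstorder": 19,
    "glcm": 24,
    "glszm": 16,
    "glrlm": 16,
    "ngtdm": 5,
    "gldm": 14,
}

ALL_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{family}_{feat}" for family, feats in FAMILIES.items() for feat in feats
)

N_FEATURES = 94

for _fam, _feats in FAMILIES.items():
    if len(_feats) != FAMILY_SIZES[_fam]:
        raise AssertionError(
            f"feature catalogue corrupted: {_fam} has {len(_feats)} features, "
            f"expected {FAMILY_SIZES[_fam]}"
        )
if len(ALL_FEATURE_NAMES) != N_FEATURES:
    raise AssertionError("feature catalogue corrupted: total != 94")
if len(set(ALL_FEATURE_NAMES)) != N_FEATURES:
    raise AssertionError("feature catalogue corrupted: duplicate names")
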