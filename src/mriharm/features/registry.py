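"""The canonical 92-feature registry.

Feature names mirror the naming of the standard open-source extractor's
default-enabled lists (first-order standard deviation excluded as
redundant with variance).  Column names in feature tables are
``family_FeatureName``.
"""

FIRSTORDER = [
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
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
]

GLCM = [
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
]

GLRLM = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]

GLSZM = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
]

NGTDM = [
    "Busyness",
    "Coarseness",
    "Complexity",
    "Contrast",
    "Strength",
]

GLDM = [
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]

_FAMILIES = {
    "firstorder": FIRSTORDER,
    "glcm": GLCM,
    "glrlm": GLRLM,
    "glszm": GLSZM,
    "ngtdm": NGTDM,
    "gldm": GLDM,
}

FAMILY_COUNTS = {fam: len(names) for fam, names in _FAMILIES.items()}

FEATURE_NAMES = [f"{fam}_{name}" for fam, names in _FAMILIES.items() for name in names]

assert len(FEATURE_NAMES) == 92, "feature registry must contain exactly 92 features"


def feature_names_by_family(family: str) -> list[str]:
    return list(_FAMILIES[family])
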