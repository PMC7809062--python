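"""The engineered-feature bank catalog: 1428 features by filter and class.

The bank is organised as an 8-filter x 7-class grid with a fixed number
of features per cell (grand total 1428).  The catalog is the
authoritative contract for the bank: extraction output is validated
against it, and the per-cell counts are taken as fixed even where they
are not a plain multiple of the canonical per-class feature list (the
printed bank was assembled with filter-specific settings).
"""

from __future__ import annotations

from dataclasses import dataclass

FILTERS = ("exponential", "gradient", "lbp", "logarithm",
           "original", "square", "squareroot", "wavelet")
CLASSES = ("firstorder", "glcm", "gldm", "glrlm", "glszm", "ngtdm", "shape")

# features per (filter, class) cell, in CLASSES order
_CELL_COUNTS: dict[str, tuple[int, ...]] = {
    "exponential": (16, 0, 11, 12, 7, 0, 0),
    "gradient":    (18, 23, 14, 16, 16, 5, 0),
    "lbp":         (56, 0, 44, 48, 28, 0, 0),
    "logarithm":   (18, 23, 14, 16, 16, 5, 0),
    "original":    (18, 23, 14, 16, 16, 5, 12),
    "square":      (18, 23, 14, 16, 16, 4, 0),
    "squareroot":  (18, 23, 14, 16, 16, 5, 0),
    "wavelet":     (144, 184, 112, 128, 128, 39, 0),
}

# canonical per-class feature names; cells wider than the canonical list
# cycle through it with a variant suffix (_v1, _v2, ...), narrower cells
# truncate it
BASE_NAMES: dict[str, tuple[str, ...]] = {
    "firstorder": (
        "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
        "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
        "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
        "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity"),
    "glcm": (
        "Autocorrelation", "ClusterProminence", "ClusterShade",
        "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
        "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn",
        "Idn", "Imc1", "Imc2", "InverseVariance", "JointAverage",
        "JointEnergy", "JointEntropy", "MaximumProbability", "SumAverage",
        "SumEntropy", "SumSquares"),
    "gldm": (
        "DependenceEntropy", "DependenceNonUniformity",
        "DependenceNonUniformityNormalized", "DependenceVariance",
        "GrayLevelNonUniformity", "GrayLevelVariance",
        "HighGrayLevelEmphasis", "LargeDependenceEmphasis",
        "LargeDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
        "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
        "SmallDependenceLowGrayLevelEmphasis"),
    "glrlm": (
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
        "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
        "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
        "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
        "ShortRunLowGrayLevelEmphasis"),
    "glszm": (
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelZoneEmphasis",
        "LargeAreaEmphasis", "LargeAreaHighGrayLevelEmphasis",
        "LargeAreaLowGrayLevelEmphasis", "LowGrayLevelZoneEmphasis",
        "SizeZoneNonUniformity", "SizeZoneNonUniformityNormalized",
        "SmallAreaEmphasis", "SmallAreaHighGrayLevelEmphasis",
        "SmallAreaLowGrayLevelEmphasis", "ZoneEntropy", "ZonePercentage",
        "ZoneVariance"),
    "ngtdm": ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength"),
    "shape": (
        "Area", "Perimeter", "PerimeterAreaRatio", "MajorAxisLength",
        "MinorAxisLength", "Elongation", "Eccentricity", "Sphericity",
        "MaximumDiameter", "Extent", "Solidity", "EquivalentDiameter"),
}


@dataclass(frozen=True)
class CatalogEntry:
    filter_name: str
    feature_class: str
    expected_count: int


@dataclass(frozen=True)
class FeatureCatalog:
    entries: tuple[CatalogEntry, ...]

    def expected_count(self, filter_name: str, feature_class: str) -> int:
        for e in self.entries:
            if e.filter_name == filter_name and e.feature_class == feature_class:
                return e.expected_count
        raise KeyError((filter_name, feature_class))

    def filter_total(self, filter_name: str) -> int:
        return sum(e.expected_count for e in self.entries if e.filter_name == filter_name)

    def class_total(self, feature_class: str) -> int:
        return sum(e.expected_count for e in self.entries if e.feature_class == feature_class)

    @property
    def grand_total(self) -> int:
        return sum(e.expected_count for e in self.entries)

    def cell_feature_names(self, filter_name: str, feature_class: str) -> list[str]:
        """Unique names for one cell: ``<filter>_<class>_<Name>[_v<k>]``."""
        count = self.expected_count(filter_name, feature_class)
        base = BASE_NAMES[feature_class]
        names = []
        for i in range(count):
            stem = base[i % len(base)]
            variant = i // len(base)
            suffix = f"_v{variant}" if variant else ""
            names.append(f"{filter_name}_{feature_class}_{stem}{suffix}")
        return names

    def feature_names(self) -> list[str]:
        """All catalog names, filter-major then class order."""
        out: list[str] = []
        for f in FILTERS:
            for c in CLASSES:
                out.extend(self.cell_feature_names(f, c))
        return out


def build_feature_catalog() -> FeatureCatalog:
    """The full 1428-feature catalog with per-cell expected counts."""
    entries = tuple(
        CatalogEntry(f, c, _CELL_COUNTS[f][j])
        for f in FILTERS for j, c in enumerate(CLASSES)
    )
    return FeatureCatalog(entries=entries)
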