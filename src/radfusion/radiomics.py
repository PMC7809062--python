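"""The engineered radiomics feature bank: masking rule, extraction, validation.

The bank contract has three parts: an HU intensity-exclusion rule that
restricts the tumour ROI to soft-tissue attenuation (voxels below -10 HU
— fat — or above 500 HU — stents and large vessels — are dropped, the
boundary values retained); a catalog of 1428 named features across 8
image filters and 7 feature classes; and report-style validation of any
feature table against that catalog.

Feature values are computed by the in-package 2D engine
(:mod:`radfusion.texture`): each catalog cell is filled by running the
cell's feature class on the filter's image (wavelet and LBP cells wider
than one canonical feature list use successive sub-bands / radii as
variants).  Extraction is deterministic for a fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from skimage.feature import local_binary_pattern

from .catalog import BASE_NAMES, CLASSES, FILTERS, FeatureCatalog, build_feature_catalog
from . import texture

__all__ = [
    "IntensityMaskRule",
    "apply_intensity_mask",
    "extract_radiomics",
    "ValidationReport",
    "validate_feature_table",
]


@dataclass(frozen=True)
class IntensityMaskRule:
    """Exclude voxels with HU < hu_low or HU > hu_high (bounds retained)."""

    hu_low: float = -10.0
    hu_high: float = 500.0


class EmptyMaskError(ValueError):
    """No tumour voxels remain after masking."""


def apply_intensity_mask(image: np.ndarray, roi_mask: np.ndarray,
                         rule: IntensityMaskRule = IntensityMaskRule()) -> np.ndarray:
    """Refine an ROI mask by the HU exclusion rule.

    Returns a new boolean mask; the input mask is left unmodified.
    Raises :class:`EmptyMaskError` if nothing survives.
    """
    image = np.asarray(image)
    roi = np.asarray(roi_mask).astype(bool)
    if image.shape != roi.shape:
        raise ValueError("image and mask shapes differ")
    if not roi.any():
        raise EmptyMaskError("ROI mask is empty")
    refined = roi & (image >= rule.hu_low) & (image <= rule.hu_high)
    if not refined.any():
        raise EmptyMaskError("no tumour voxels remain after HU exclusion")
    return refined


def _norm01(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img, dtype=float)
    return (img - lo) / (hi - lo)


def _wavelet_bands(img: np.ndarray) -> list[np.ndarray]:
    """Eight same-size stationary-wavelet bands (levels 1-2, A/H/V/D)."""
    pad_r = (-img.shape[0]) % 4
    pad_c = (-img.shape[1]) % 4
    padded = np.pad(img, ((0, pad_r), (0, pad_c)), mode="reflect")
    coeffs = pywt.swt2(padded, "coif1", level=2, norm=True)
    # pywt returns deepest level first
    (a2, (h2, v2, d2)), (a1, (h1, v1, d1)) = coeffs
    bands = [a1, h1, v1, d1, a2, h2, v2, d2]
    return [b[:img.shape[0], :img.shape[1]] for b in bands]


def _filter_image(image: np.ndarray, filter_name: str, variant: int) -> np.ndarray:
    """Variant ``variant`` of a filtered image (variant 0 is canonical)."""
    img = np.asarray(image, dtype=float)
    if filter_name == "original":
        return img
    if filter_name == "exponential":
        return np.exp(4.0 * _norm01(img))
    if filter_name == "gradient":
        gy = ndimage.sobel(img, axis=0)
        gx = ndimage.sobel(img, axis=1)
        return np.hypot(gx, gy)
    if filter_name == "logarithm":
        return np.sign(img) * np.log1p(np.abs(img))
    if filter_name == "square":
        return _norm01(img) ** 2
    if filter_name == "squareroot":
        return np.sqrt(_norm01(img))
    if filter_name == "lbp":
        radius = variant + 1
        img8 = np.round(_norm01(img) * 255.0).astype(np.uint8)
        return local_binary_pattern(img8, P=8 * radius, R=radius, method="uniform")
    if filter_name == "wavelet":
        return _wavelet_bands(img)[variant]
    raise ValueError(f"unknown filter {filter_name!r}")


def extract_radiomics(image: np.ndarray, mask: np.ndarray,
                      catalog: FeatureCatalog | None = None) -> pd.Series:
    """Extract the full engineered bank for one (image, refined mask).

    Returns a Series of 1428 values named ``<filter>_<class>_<Name>``;
    names are validated against the catalog before returning.
    """
    if catalog is None:
        catalog = build_feature_catalog()
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyMaskError("mask is empty")

    values: dict[str, float] = {}
    cache: dict[tuple[str, int, str], dict[str, float]] = {}

    def cell_values(fname: str, cname: str, base_name: str, variant: int) -> float:
        key = (fname, variant, cname)
        if key not in cache:
            if cname == "shape":
                cache[key] = texture.shape_features(mask)
            else:
                vimg = _filter_image(image, fname, variant)
                if cname == "firstorder":
                    cache[key] = texture.firstorder_features(vimg, mask)
                else:
                    q = texture.quantize(vimg, mask)
                    cache[key] = texture.CLASS_FUNCS[cname](q)
        return cache[key][base_name]

    for fname in FILTERS:
        for cname in CLASSES:
            base = BASE_NAMES[cname]
            names = catalog.cell_feature_names(fname, cname)
            for i, full_name in enumerate(names):
                values[full_name] = cell_values(fname, cname, base[i % len(base)], i // len(base))

    row = pd.Series(values)
    expected = catalog.feature_names()
    if list(row.index) != expected:
        raise ValueError("extracted feature names do not match the catalog")
    return row


@dataclass
class ValidationReport:
    """Report-only comparison of a feature table against the catalog."""

    missing: list[str] = field(default_factory=list)
    extra: list[str] = field(default_factory=list)
    duplicates: list[str] = field(default_factory=list)
    non_finite: list[tuple[str, str]] = field(default_factory=list)  # (row, column)
    per_filter_counts: dict[str, tuple[int, int]] = field(default_factory=dict)  # observed, expected

    @property
    def valid(self) -> bool:
        return not (self.missing or self.extra or self.duplicates or self.non_finite)

    def summary(self) -> str:
        status = "valid" if self.valid else "INVALID"
        return (f"{status}: {len(self.missing)} missing, {len(self.extra)} extra, "
                f"{len(self.duplicates)} duplicate, {len(self.non_finite)} non-finite cells")


def validate_feature_table(table: pd.DataFrame,
                           catalog: FeatureCatalog | None = None) -> ValidationReport:
    """Check feature names, duplicates, finiteness and per-filter counts."""
    if catalog is None:
        catalog = build_feature_catalog()
    report = ValidationReport()
    cols = list(table.columns)
    expected = set(catalog.feature_names())
    seen = set()
    for c in cols:
        if c in seen:
            report.duplicates.append(c)
        seen.add(c)
    report.missing = sorted(expected - seen)
    report.extra = sorted(seen - expected)
    arr = table.to_numpy(dtype=float, na_value=np.nan)
    bad = np.argwhere(~np.isfinite(arr))
    for r, c in bad:
        report.non_finite.append((str(table.index[r]), str(cols[c])))
    for fname in FILTERS:
        observed = sum(1 for c in seen if c.startswith(fname + "_"))
        report.per_filter_counts[fname] = (observed, catalog.filter_total(fname))
    return report
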