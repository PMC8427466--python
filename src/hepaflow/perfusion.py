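"""FAIR perfusion mapping and parenchymal ROI measurement.

Perfusion is computed from paired T1 maps as

    P = (lambda / T1_blood) * (T1_global / T1_slice_selective - 1)

converted to ml/min/100 g (the conversion factor is computed from lambda
and T1_blood at call time, so overrides propagate; at the defaults
lambda = 0.95 ml/g, T1_blood = 1900 ms the factor is exactly 3000).
Negative perfusion is clamped to zero; non-physiological values above the
upper threshold are marked invalid and excluded from ROI means, as are
pixels whose T1 fit failed in either map.

Parenchymal measurements average three identically sized circular ROIs on
the right, middle and left hepatic parenchyma; the final value is the
unweighted mean of the three per-ROI means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .t1fit import T1MapSet
from .units import perfusion_unit_scale

ROI_LABELS = ("right", "middle", "left")


@dataclass(frozen=True)
class PerfusionParams:
    """Quantification constants: partition coefficient, blood T1, threshold."""

    lambda_ml_g: float = 0.95
    t1_blood_ms: float = 1900.0
    upper_threshold: float = 2000.0  # ml/min/100 g

    def validate(self) -> None:
        if min(self.lambda_ml_g, self.t1_blood_ms, self.upper_threshold) <= 0:
            raise ValueError("perfusion parameters must be strictly positive")


@dataclass
class PerfusionMap:
    """Pixel-wise perfusion in ml/min/100 g with a validity mask."""

    values: np.ndarray
    valid: np.ndarray
    params: PerfusionParams


def _values_and_valid(obj):
    if isinstance(obj, PerfusionMap):
        return obj.values, obj.valid
    if isinstance(obj, T1MapSet):
        return obj.t1, obj.valid
    arr = np.asarray(obj, float)
    return arr, np.isfinite(arr)


def perfusion_map(t1_global, t1_ss, params: PerfusionParams | None = None) -> PerfusionMap:
    """Compute the perfusion map from global and slice-selective T1 maps.

    Both inputs may be :class:`T1MapSet` objects or plain arrays (assumed
    co-registered and of identical shape).  Pixels invalid in either map,
    or exceeding the upper threshold, are invalid in the output; negative
    values are set to zero, so the clamp is idempotent.
    """
    if params is None:
        params = PerfusionParams()
    params.validate()
    g, valid_g = _values_and_valid(t1_global)
    s, valid_s = _values_and_valid(t1_ss)
    if g.shape != s.shape:
        raise ValueError("T1 maps must have identical shapes")
    scale = perfusion_unit_scale(params.lambda_ml_g, params.t1_blood_ms)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = scale * (g / s - 1.0)
    valid = valid_g & valid_s & np.isfinite(raw) & (s > 0)
    valid &= ~(raw > params.upper_threshold)
    values = np.where(valid, np.maximum(raw, 0.0), np.nan)
    return PerfusionMap(values=values, valid=valid, params=params)


@dataclass(frozen=True)
class CircleROI:
    """Circular ROI in pixel coordinates."""

    label: str
    centre: tuple[float, float]  # (row, col)
    radius: float

    def mask(self, shape) -> np.ndarray:
        r = np.arange(shape[0])[:, None] - self.centre[0]
        c = np.arange(shape[1])[None, :] - self.centre[1]
        return r * r + c * c <= self.radius ** 2


@dataclass(frozen=True)
class ROISet:
    """Exactly three circular ROIs on right, middle and left parenchyma."""

    rois: tuple[CircleROI, ...]

    def __post_init__(self):
        if len(self.rois) != 3:
            raise ValueError("exactly three ROIs are required")
        if {r.label for r in self.rois} != set(ROI_LABELS):
            raise ValueError(f"ROI labels must be {ROI_LABELS}")

    def validate(self, liver_mask: np.ndarray,
                 vessel_mask: np.ndarray | None = None) -> None:
        for roi in self.rois:
            m = roi.mask(liver_mask.shape)
            if not np.all(liver_mask[m]):
                raise ValueError(f"ROI {roi.label!r} extends outside the liver")
            if vessel_mask is not None and np.any(vessel_mask[m]):
                raise ValueError(f"ROI {roi.label!r} overlaps a vessel")

    @classmethod
    def for_phantom(cls, phantom, radius: float | None = None) -> "ROISet":
        """Place one ROI per lobe at the deepest interior point of the lobe.

        The default radius is 8 pixels at the 128 matrix (about 3.75 mm),
        scaled with the matrix size.  Centring each ROI at the maximum of
        the lobe's distance transform keeps it clear of the liver edge (and
        hence of smoothing-contaminated boundary pixels).
        """
        if radius is None:
            radius = max(2.0, round(8.0 * phantom.grid_shape[0] / 128.0))
        rois = []
        for label in ROI_LABELS:
            lobe = phantom.lobe_masks[label]
            dist = ndimage.distance_transform_edt(lobe)
            if dist.max() < radius + 1:
                raise ValueError(f"lobe {label!r} cannot contain an ROI of "
                                 f"radius {radius}")
            centre = np.unravel_index(int(np.argmax(dist)), dist.shape)
            rois.append(CircleROI(label, (float(centre[0]), float(centre[1])),
                                  float(radius)))
        rs = cls(tuple(rois))
        rs.validate(phantom.liver_mask)
        return rs


def roi_mean(map_or_t1, rois: ROISet) -> float:
    """Mean of the three per-ROI means (valid pixels only).

    This is the mean-of-means convention, not a pooled-pixel mean, so the
    result is insensitive to unequal valid-pixel counts per ROI.  An ROI
    containing no valid pixel raises an error naming the ROI.
    """
    values, valid = _values_and_valid(map_or_t1)
    means = []
    for roi in rois.rois:
        m = roi.mask(values.shape) & valid
        if not np.any(m):
            raise ValueError(f"ROI {roi.label!r} contains no valid pixels")
        means.append(float(values[m].mean()))
    return float(np.mean(means))
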