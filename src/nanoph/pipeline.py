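"""Pixel-level measurement pipeline for two-channel ratiometric micrographs.

Stages, in the order a measurement runs them: background subtraction on both
channels, reference-channel thresholding into a sensor mask, per-pixel
indicator/reference ratioing with reference-intensity weights, conversion to
pH through a calibration model, and aggregation into weighted histograms,
summary statistics, region tables, or rendered colour maps.

Weighting convention: each masked pixel contributes in proportion to its
background-subtracted reference intensity — i.e. to the local abundance of
nanosensor — so the pH distribution describes where the sensors are, not
merely where pixels are.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from skimage.measure import label as _sk_label

from .calibration import PH_SENTINEL, CalibrationModel, invert_response

logger = logging.getLogger("nanoph")

__all__ = [
    "ChannelPair",
    "BackgroundEstimate",
    "SensorMask",
    "RatioField",
    "PHField",
    "WeightedHistogram",
    "Region",
    "RegionSet",
    "PipelineConfig",
    "ThresholdScan",
    "ThresholdSelectionError",
    "EmptyMaskError",
    "estimate_background",
    "subtract_background",
    "build_mask",
    "select_threshold",
    "compute_ratio_field",
    "ratios_to_ph",
    "make_histogram",
    "summarize",
    "label_regions",
    "render_colormap",
]


class EmptyMaskError(ValueError):
    """No usable sensor pixels remain after masking/exclusions."""


@dataclass(frozen=True)
class ChannelPair:
    """Registered indicator and reference images on one pixel grid."""

    indicator: np.ndarray
    reference: np.ndarray
    time_index: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ind = np.asarray(self.indicator, dtype=float)
        ref = np.asarray(self.reference, dtype=float)
        if ind.shape != ref.shape:
            raise ValueError(
                f"channel shapes differ: indicator {ind.shape} vs reference {ref.shape}"
            )
        if ind.ndim != 2:
            raise ValueError(f"channels must be 2-D, got {ind.ndim}-D")
        for name, arr in (("indicator", ind), ("reference", ref)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative intensities")
        object.__setattr__(self, "indicator", ind)
        object.__setattr__(self, "reference", ref)

    @property
    def shape(self) -> tuple[int, int]:
        return self.indicator.shape


@dataclass(frozen=True)
class BackgroundEstimate:
    """Per-channel scalar background and how it was obtained.

    method is one of "roi" (mean over an outside-cell rectangle), "image"
    (mean of a sensor-free companion image) or "constant".
    """

    method: Literal["roi", "image", "constant"]
    indicator_value: float
    reference_value: float
    roi: tuple[int, int, int, int] | None = None  # (row0, row1, col0, col1), half-open

    def __post_init__(self):
        if self.indicator_value < 0 or self.reference_value < 0:
            raise ValueError("background values must be >= 0")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "indicator_value": self.indicator_value,
            "reference_value": self.reference_value,
            "roi": list(self.roi) if self.roi else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackgroundEstimate":
        roi = tuple(d["roi"]) if d.get("roi") else None
        return cls(d["method"], d["indicator_value"], d["reference_value"], roi)


@dataclass(frozen=True)
class SensorMask:
    mask: np.ndarray
    threshold: float

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self):
        return self.mask.shape


@dataclass(frozen=True)
class RatioField:
    """Per-masked-pixel ratios with normalized reference-intensity weights."""

    ratios: np.ndarray  # 1-D, finite, >= 0
    weights: np.ndarray  # 1-D, sums to 1
    coords: np.ndarray  # (N, 2) row, col
    shape: tuple[int, int]
    total_reference: float  # sum of reference intensity over included pixels
    n_excluded_zero_reference: int = 0


@dataclass(frozen=True)
class PHField:
    """Per-masked-pixel pH (NaN = out-of-range sentinel) with weights."""

    ph: np.ndarray
    weights: np.ndarray
    coords: np.ndarray
    shape: tuple[int, int]
    model: CalibrationModel
    time_index: int | None = None

    @property
    def sentinel_count(self) -> int:
        return int(np.isnan(self.ph).sum())

    @property
    def sentinel_fraction(self) -> float:
        return float(np.sum(self.weights[np.isnan(self.ph)]))

    def to_image(self) -> np.ndarray:
        """Dense float32 map: pH at masked pixels, NaN elsewhere."""
        img = np.full(self.shape, np.nan, dtype=np.float32)
        img[self.coords[:, 0], self.coords[:, 1]] = self.ph
        return img


@dataclass(frozen=True)
class WeightedHistogram:
    edges: np.ndarray  # strictly increasing bin edges, pH units
    masses: np.ndarray  # weight mass per bin
    out_of_range_mass: float  # the "pH > 10" bin
    bin_width: float

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum() + self.out_of_range_mass)

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


@dataclass(frozen=True)
class Region:
    label: int
    n_pixels: int
    mean_ph: float | None = None
    weighted_mean_ph: float | None = None


@dataclass(frozen=True)
class RegionSet:
    labels: np.ndarray  # labeled image, 0 = background
    regions: tuple[Region, ...]
    min_size: int
    max_size: int


@dataclass
class PipelineConfig:
    """Settings shared by calibration and measurement runs."""

    background: BackgroundEstimate | None = None
    threshold: float = 0.0
    bin_width: float = 0.2
    min_region_size: int = 1
    max_region_size: int = 10**9


# ----------------------------------------------------------------------
# operations


def estimate_background(
    pair: ChannelPair,
    method: Literal["roi", "image", "constant"],
    roi: tuple[int, int, int, int] | None = None,
    companion: ChannelPair | None = None,
    constant: tuple[float, float] | None = None,
) -> BackgroundEstimate:
    """Estimate a per-channel scalar background.

    "roi": mean over an outside-cell rectangle of this image pair.
    "image": mean over a sensor-free companion image pair.
    "constant": user-supplied (indicator, reference) values.
    """
    if method == "roi":
        if roi is None:
            raise ValueError("roi method requires a rectangle")
        r0, r1, c0, c1 = roi
        nrow, ncol = pair.shape
        if not (0 <= r0 < r1 <= nrow and 0 <= c0 < c1 <= ncol):
            raise ValueError(f"ROI {roi} empty or out of bounds for image {pair.shape}")
        return BackgroundEstimate(
            "roi",
            float(pair.indicator[r0:r1, c0:c1].mean()),
            float(pair.reference[r0:r1, c0:c1].mean()),
            roi=roi,
        )
    if method == "image":
        if companion is None:
            raise ValueError("image method requires a sensor-free companion pair")
        return BackgroundEstimate(
            "image", float(companion.indicator.mean()), float(companion.reference.mean())
        )
    if method == "constant":
        if constant is None:
            raise ValueError("constant method requires (indicator, reference) values")
        return BackgroundEstimate("constant", float(constant[0]), float(constant[1]))
    raise ValueError(f"unknown background method {method!r}")


def subtract_background(pair: ChannelPair, bg: BackgroundEstimate) -> ChannelPair:
    """Subtract the scalar background from each channel, clamping at zero.

    The fraction of clamped (would-be-negative) pixels is logged per channel;
    a large fraction signals systematic over-subtraction.
    """
    out = {}
    for name, arr, value in (
        ("indicator", pair.indicator, bg.indicator_value),
        ("reference", pair.reference, bg.reference_value),
    ):
        sub = arr - value
        clamped = np.count_nonzero(sub < 0)
        if clamped:
            frac = clamped / arr.size
            logger.info("background: clamped %.1f%% of %s pixels to 0", 100 * frac, name)
        if value >= arr.max() and arr.size:
            logger.warning(
                "background %s value %.3g >= channel maximum; channel is now empty",
                name,
                value,
            )
        out[name] = np.clip(sub, 0.0, None)
    return ChannelPair(
        indicator=out["indicator"],
        reference=out["reference"],
        time_index=pair.time_index,
        metadata={**pair.metadata, "background": bg.to_dict()},
    )


def build_mask(reference: np.ndarray, threshold: float) -> SensorMask:
    """Mask of nanosensor-containing pixels: reference strictly above threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ref = np.asarray(reference, dtype=float)
    return SensorMask(mask=ref > threshold, threshold=float(threshold))


@dataclass(frozen=True)
class ThresholdScan:
    threshold: float
    fraction_in_range: float
    thresholds: np.ndarray  # full candidate grid
    fractions: np.ndarray  # in-range fraction at each candidate (NaN if empty mask)
    n_masked: np.ndarray


class ThresholdSelectionError(RuntimeError):
    """No threshold reaches the required in-range fraction.

    Carries the best achievable fraction; usually means the calibration does
    not cover the image's ratio range and should be redone.
    """

    def __init__(self, message: str, best_fraction: float, scan: ThresholdScan | None = None):
        super().__init__(message)
        self.best_fraction = best_fraction
        self.scan = scan


def select_threshold(
    pair: ChannelPair,
    model: CalibrationModel,
    step: float = 1.0,
    min_fraction: float = 0.90,
) -> ThresholdScan:
    """Choose the reference threshold by the in-range-fraction rule.

    Scans candidate thresholds on a grid from 0 to the reference maximum in
    steps of ``step`` and returns the lowest threshold at which more than
    ``min_fraction`` of the masked pixels invert to a numeric pH inside the
    model's calibrated range.  Too high a threshold discards data; too low a
    threshold admits pixels outside the calibration range — this picks the
    lowest acceptable one.  Expects a background-subtracted pair.

    A pixel counts as in range when its ratio lies strictly between the
    asymptotes and its inverted pH falls inside [ph_lo, ph_hi].  Pixels are
    counted unweighted.
    """
    ref = pair.reference.ravel()
    ind = pair.indicator.ravel()

    # in-range status per pixel is threshold-independent: precompute once
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ref > 0, ind / np.where(ref > 0, ref, 1.0), np.nan)
    ph = invert_response(model, ratio)
    lo, hi = model.ph_range
    in_range = np.isfinite(ph) & (ph >= lo) & (ph <= hi)

    # sort by reference intensity descending; pixels with ref > t form a prefix
    order = np.argsort(-ref, kind="stable")
    ref_sorted = ref[order]
    cum_in_range = np.cumsum(in_range[order])

    thresholds = np.arange(0.0, float(ref.max()) + step, step)
    # number of pixels with ref > t == count of -ref strictly below -t
    n_masked = np.searchsorted(-ref_sorted, -thresholds, side="left")
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(
            n_masked > 0,
            cum_in_range[np.maximum(n_masked - 1, 0)] / np.maximum(n_masked, 1),
            np.nan,
        )

    ok = (n_masked > 0) & (fractions > min_fraction)
    scan_kwargs = dict(thresholds=thresholds, fractions=fractions, n_masked=n_masked)
    if not np.any(ok):
        best = float(np.nanmax(fractions)) if np.any(n_masked > 0) else 0.0
        raise ThresholdSelectionError(
            f"no threshold reaches an in-range fraction > {min_fraction:.2f} "
            f"(best achievable: {best:.3f}); recalibrate over a wider pH range",
            best_fraction=best,
            scan=ThresholdScan(float("nan"), best, **scan_kwargs),
        )
    idx = int(np.argmax(ok))  # lowest qualifying threshold
    return ThresholdScan(
        threshold=float(thresholds[idx]),
        fraction_in_range=float(fractions[idx]),
        **scan_kwargs,
    )


def compute_ratio_field(pair: ChannelPair, mask: SensorMask) -> RatioField:
    """Per-pixel indicator/reference ratios over the mask, reference-weighted.

    Masked pixels whose (background-subtracted) reference is zero cannot be
    ratioed; they are excluded and counted, never assigned infinity.  Weights
    are the reference intensities of the surviving pixels normalized to unit
    sum.
    """
    if mask.shape != pair.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {pair.shape}")
    rows, cols = np.nonzero(mask.mask)
    ref = pair.reference[rows, cols]
    ind = pair.indicator[rows, cols]
    keep = ref > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("ratio field: excluded %d masked pixels with zero reference", n_excluded)
    if not np.any(keep):
        raise EmptyMaskError("no masked pixels with positive reference intensity")
    ref, ind = ref[keep], ind[keep]
    coords = np.column_stack([rows[keep], cols[keep]])
    total_ref = float(ref.sum())
    return RatioField(
        ratios=ind / ref,
        weights=ref / total_ref,
        coords=coords,
        shape=pair.shape,
        total_reference=total_ref,
        n_excluded_zero_reference=n_excluded,
    )


def ratios_to_ph(field: RatioField, model: CalibrationModel) -> PHField:
    """Convert each pixel's ratio to pH through the inverse calibration.

    Numeric pH values falling outside the calibrated buffer interval are also
    demoted to the sentinel: the sigmoid extrapolates smoothly beyond the
    measured buffers but the calibration does not vouch for it there.
    """
    ph = invert_response(model, field.ratios)
    lo, hi = model.ph_range
    outside = np.isfinite(ph) & ((ph < lo) | (ph > hi))
    ph = np.where(outside, PH_SENTINEL, ph)
    n_sent = int(np.isnan(ph).sum())
    if n_sent:
        logger.info(
            "pH conversion: %d/%d pixels out of calibration range (sentinel)",
            n_sent,
            ph.size,
        )
    return PHField(
        ph=ph,
        weights=field.weights,
        coords=field.coords,
        shape=field.shape,
        model=model,
    )


def make_histogram(field: PHField, bin_width: float = 0.2) -> WeightedHistogram:
    """Weight-mass histogram over the calibrated range plus an overflow bin.

    Bins are half-open [lo, hi) with the final bin closed, spanning
    [ph_lo, ph_hi]; sentinel pixels accumulate in a separate out-of-range
    bin so the total mass is conserved at 1.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    lo, hi = field.model.ph_range
    n_bins = max(int(math.ceil((hi - lo) / bin_width - 1e-9)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    numeric = np.isfinite(field.ph)
    out_mass = float(field.weights[~numeric].sum())
    idx = np.floor((field.ph[numeric] - lo) / bin_width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # closes the final bin at ph_hi
    masses = np.bincount(idx, weights=field.weights[numeric], minlength=n_bins)
    return WeightedHistogram(
        edges=edges, masses=masses, out_of_range_mass=out_mass, bin_width=bin_width
    )


def summarize(obj) -> dict:
    """Summary statistics of a pH field, region set, or time series.

    For a :class:`PHField`: weighted mean (reference-intensity weights),
    unweighted mean, SD over pixels, and the numeric-pixel fraction.  For a
    :class:`RegionSet`: mean and SD over region means.  For a sequence of
    fields (a time series): one record per time point.
    """
    if isinstance(obj, PHField):
        numeric = np.isfinite(obj.ph)
        if not np.any(numeric):
            raise ValueError("all pixels are out-of-range sentinels; nothing to summarize")
        ph = obj.ph[numeric]
        w = obj.weights[numeric]
        return {
            "weighted_mean_ph": float(np.sum(ph * w) / w.sum()),
            "mean_ph": float(ph.mean()),
            "sd_ph": float(ph.std(ddof=1)) if ph.size > 1 else 0.0,
            "numeric_fraction": float(numeric.mean()),
            "n_pixels": int(obj.ph.size),
            "n_sentinel": int(obj.sentinel_count),
            "replication_unit": "pixels",
        }
    if isinstance(obj, RegionSet):
        means = [r.weighted_mean_ph for r in obj.regions if r.weighted_mean_ph is not None]
        if not means:
            raise ValueError("no regions with numeric pH to summarize")
        arr = np.asarray(means)
        return {
            "mean_ph": float(arr.mean()),
            "sd_ph": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "n_regions": int(arr.size),
            "replication_unit": "regions",
        }
    if isinstance(obj, Sequence):
        records = []
        for t, fld in enumerate(obj):
            rec = summarize(fld)
            rec["time_index"] = fld.time_index if fld.time_index is not None else t
            records.append(rec)
        return {"time_series": records, "replication_unit": "frames"}
    raise TypeError(f"cannot summarize {type(obj).__name__}")


def label_regions(
    mask: SensorMask,
    min_size: int = 1,
    max_size: int = 10**9,
    ph_field: PHField | None = None,
) -> RegionSet:
    """8-connected components of the mask filtered by a pixel-count criterion.

    When a pH field is attached, each surviving region carries its weighted
    and unweighted mean pH over numeric pixels.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if max_size < min_size:
        raise ValueError("max_size must be >= min_size")
    labeled = _sk_label(mask.mask, connectivity=2)  # connectivity=2 is 8-connected in 2-D

    dense_ph = dense_w = None
    if ph_field is not None:
        dense_ph = np.full(mask.shape, np.nan)
        dense_w = np.zeros(mask.shape)
        dense_ph[ph_field.coords[:, 0], ph_field.coords[:, 1]] = ph_field.ph
        dense_w[ph_field.coords[:, 0], ph_field.coords[:, 1]] = ph_field.weights

    regions = []
    out_labels = np.zeros_like(labeled)
    for lab in range(1, labeled.max() + 1):
        sel = labeled == lab
        n = int(sel.sum())
        if not (min_size <= n <= max_size):
            continue
        mean_ph = wmean_ph = None
        if dense_ph is not None:
            vals = dense_ph[sel]
            wts = dense_w[sel]
            ok = np.isfinite(vals)
            if np.any(ok) and wts[ok].sum() > 0:
                mean_ph = float(vals[ok].mean())
                wmean_ph = float(np.sum(vals[ok] * wts[ok]) / wts[ok].sum())
        new_lab = len(regions) + 1
        out_labels[sel] = new_lab
        regions.append(
            Region(label=new_lab, n_pixels=n, mean_ph=mean_ph, weighted_mean_ph=wmean_ph)
        )
    return RegionSet(
        labels=out_labels, regions=tuple(regions), min_size=min_size, max_size=max_size
    )


def render_colormap(
    field: PHField,
    cmap: str = "viridis",
    background_rgb: tuple[int, int, int] = (64, 64, 64),
) -> np.ndarray:
    """Render the pH field as an RGB image (uint8).

    Numeric pH maps linearly from [ph_lo, ph_hi] onto the colormap; sentinel
    pixels are black; pixels outside the mask take the background colour.
    Deterministic for identical inputs.
    """
    import matplotlib

    lo, hi = field.model.ph_range
    cm = matplotlib.colormaps[cmap]
    img = np.empty((*field.shape, 3), dtype=np.uint8)
    img[:, :] = background_rgb

    numeric = np.isfinite(field.ph)
    span = hi - lo if hi > lo else 1.0
    frac = np.clip((field.ph[numeric] - lo) / span, 0.0, 1.0)
    rgba = cm(frac)
    rc = field.coords[numeric]
    img[rc[:, 0], rc[:, 1]] = (rgba[:, :3] * 255).round().astype(np.uint8)
    rs = field.coords[~numeric]
    img[rs[:, 0], rs[:, 1]] = (0, 0, 0)  # out-of-range pixels render black
    return img
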