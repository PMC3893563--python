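"""High-level drivers tying the pipeline stages together for one run.

These are the functions the CLI wraps; scripted analyses can call them
directly with in-memory objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as nio
from . import pipeline as pl
from .calibration import CalibrationModel, calibrate_from_images
from .config import RunConfig

logger = logging.getLogger("nanoph")

__all__ = ["MeasurementResult", "measure_pair", "calibrate_from_manifest"]


@dataclass
class MeasurementResult:
    field: pl.PHField
    histogram: pl.WeightedHistogram
    summary: dict
    colormap: np.ndarray
    threshold: float
    regions: pl.RegionSet | None = None


def _background_estimate(pair: pl.ChannelPair, cfg: RunConfig, base_dir=".") -> pl.BackgroundEstimate | None:
    bc = cfg.background
    if bc.method == "none":
        return None
    if bc.method == "roi":
        return pl.estimate_background(pair, "roi", roi=bc.roi)
    if bc.method == "image":
        companion = nio.read_channel_pair(
            Path(base_dir) / bc.companion_path,
            indicator=cfg.channel_indicator,
            reference=cfg.channel_reference,
            slice_index=cfg.slice_index,
        )
        return pl.estimate_background(pair, "image", companion=companion)
    return pl.estimate_background(
        pair, "constant", constant=(bc.constant_indicator, bc.constant_reference)
    )


def measure_pair(
    pair: pl.ChannelPair,
    model: CalibrationModel,
    cfg: RunConfig | None = None,
    base_dir=".",
) -> MeasurementResult:
    """Run the full measurement pipeline on one image pair.

    Stages: background subtraction, threshold selection (automatic by the
    in-range-fraction rule, or fixed), masking, ratioing with reference
    weights, pH conversion, then histogram/summary/colour map.  In "region"
    mode connected components within the size criteria are summarized; in
    "image" mode the image-wide weighted mean ratio yields a single pH.
    """
    cfg = cfg or RunConfig()
    bg = _background_estimate(pair, cfg, base_dir)
    if bg is not None:
        pair = pl.subtract_background(pair, bg)

    if cfg.threshold == "auto":
        scan = pl.select_threshold(pair, model, step=cfg.threshold_step)
        threshold = scan.threshold
        logger.info(
            "auto threshold %.3g (in-range fraction %.3f)", threshold, scan.fraction_in_range
        )
    else:
        threshold = float(cfg.threshold)

    mask = pl.build_mask(pair.reference, threshold)
    field = pl.compute_ratio_field(pair, mask)

    if cfg.analysis_mode == "image":
        mean_ratio = float(np.sum(field.ratios * field.weights))
        from dataclasses import replace

        field = replace(
            field,
            ratios=np.array([mean_ratio]),
            weights=np.array([1.0]),
            coords=np.zeros((1, 2), dtype=int),
        )

    ph_field = pl.ratios_to_ph(field, model)
    regions = None
    if cfg.analysis_mode == "region":
        regions = pl.label_regions(
            mask, cfg.regions.min_size, cfg.regions.max_size, ph_field=ph_field
        )
        summary = pl.summarize(regions)
    else:
        summary = pl.summarize(ph_field)

    return MeasurementResult(
        field=ph_field,
        histogram=pl.make_histogram(ph_field, cfg.bin_width),
        summary=summary,
        colormap=pl.render_colormap(ph_field, cmap=cfg.colormap),
        threshold=threshold,
        regions=regions,
    )


def calibrate_from_manifest(manifest_path, cfg: RunConfig | None = None) -> CalibrationModel:
    """Build a calibration model from a CSV manifest of images and pH values."""
    cfg = cfg or RunConfig()
    rows = nio.read_manifest(manifest_path)
    base = Path(manifest_path).parent
    entries = []
    for row in rows:
        pair = nio.read_channel_pair(
            base / row["path"],
            indicator=row["channel_indicator"],
            reference=row["channel_reference"],
            slice_index=cfg.slice_index,
        )
        entries.append((pair, row["ph"]))
    bg = None
    if entries and cfg.background.method != "none":
        bg = _background_estimate(entries[0][0], cfg, base)
    pcfg = pl.PipelineConfig(
        background=bg,
        threshold=0.0 if cfg.threshold == "auto" else float(cfg.threshold),
        bin_width=cfg.bin_width,
    )
    return calibrate_from_images(entries, pcfg)
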