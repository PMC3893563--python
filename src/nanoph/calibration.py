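"""Sigmoidal ratio-vs-pH calibration: fitting, evaluation, inversion, serialization.

The ratiometric response of a pH nanosensor (indicator/reference intensity
ratio ``R`` as a function of pH) is modelled by a four-parameter logistic

    R(pH) = R_min + (R_max - R_min) / (1 + 10**((pKa - pH) * hillslope))

with lower/upper asymptotes ``R_min``/``R_max``, inflection point ``pKa``
(half-maximal response) and steepness ``hillslope``.  The inverse,

    pH(R) = pKa - log10((R_max - R_min) / (R - R_min) - 1) / hillslope,

is defined only for ratios strictly between the asymptotes; outside that
interval a pixel is out of the sensor's range and is assigned the
out-of-range sentinel (NaN internally, reported as "pH > 10").
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PH_SENTINEL",
    "SENTINEL_LABEL",
    "CalibrationPoint",
    "FitStats",
    "CalibrationModel",
    "FitConfig",
    "FitError",
    "forward_response",
    "invert_response",
    "fit_calibration",
    "calibrate_from_images",
    "points_to_csv",
    "points_from_csv",
]

#: Out-of-range sentinel carried through all numeric arrays.
PH_SENTINEL = float("nan")

#: Human-readable label for the sentinel in reports and legends.
SENTINEL_LABEL = "pH > 10"


class FitError(RuntimeError):
    """Calibration fit failed; carries diagnostics from every start tried."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration observation: mean ratio at a known buffer pH."""

    ph: float
    ratio: float
    weight: float = 1.0
    n_pixels: int = 0

    def __post_init__(self):
        if not math.isfinite(self.ratio) or self.ratio <= 0:
            raise ValueError(f"ratio must be finite and > 0, got {self.ratio}")
        if self.weight < 0:
            raise ValueError(f"weight must be >= 0, got {self.weight}")
        if not math.isfinite(self.ph):
            raise ValueError(f"ph must be finite, got {self.ph}")


@dataclass(frozen=True)
class FitStats:
    rss: float
    stderr: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    n_points: int = 0
    residuals: tuple[float, ...] = ()


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted sigmoid parameters plus the calibrated pH interval."""

    r_min: float
    r_max: float
    pka: float
    hillslope: float
    ph_range: tuple[float, float] = (0.0, 14.0)
    fit_stats: FitStats | None = None

    def __post_init__(self):
        if not self.r_max > self.r_min:
            raise ValueError(f"r_max ({self.r_max}) must exceed r_min ({self.r_min})")
        if self.hillslope == 0 or not math.isfinite(self.hillslope):
            raise ValueError("hillslope must be nonzero and finite")
        lo, hi = self.ph_range
        if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
            raise ValueError(f"invalid ph_range {self.ph_range}")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "r_min": self.r_min,
            "r_max": self.r_max,
            "pka": self.pka,
            "hillslope": self.hillslope,
            "ph_lo": self.ph_range[0],
            "ph_hi": self.ph_range[1],
        }
        if self.fit_stats is not None:
            d["fit_stats"] = {
                "rss": self.fit_stats.rss,
                "stderr": dict(self.fit_stats.stderr),
                "converged": self.fit_stats.converged,
                "n_points": self.fit_stats.n_points,
            }
        from . import __version__

        d["software_version"] = __version__
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        stats = None
        if "fit_stats" in d:
            fs = d["fit_stats"]
            stats = FitStats(
                rss=fs.get("rss", float("nan")),
                stderr=dict(fs.get("stderr", {})),
                converged=fs.get("converged", True),
                n_points=fs.get("n_points", 0),
            )
        return cls(
            r_min=d["r_min"],
            r_max=d["r_max"],
            pka=d["pka"],
            hillslope=d["hillslope"],
            ph_range=(d.get("ph_lo", 0.0), d.get("ph_hi", 14.0)),
            fit_stats=stats,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def forward_response(model: CalibrationModel, ph):
    """Evaluate the sigmoid R(pH); accepts scalars or arrays.

    Returns values strictly inside (r_min, r_max) for finite pH.
    """
    ph_arr = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph_arr)):
        raise ValueError("ph must be finite")
    span = model.r_max - model.r_min
    out = model.r_min + span / (1.0 + 10.0 ** ((model.pka - ph_arr) * model.hillslope))
    return float(out) if np.isscalar(ph) or ph_arr.ndim == 0 else out


def invert_response(model: CalibrationModel, ratio):
    """Map a ratio (scalar or array) to pH; out-of-range ratios become NaN.

    A ratio at or beyond either asymptote (or non-finite) has no pH under the
    model; those entries are assigned the out-of-range sentinel rather than
    raising, matching the convention of reporting such pixels as "pH > 10".
    """
    r = np.asarray(ratio, dtype=float)
    span = model.r_max - model.r_min
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = span / (r - model.r_min) - 1.0
        ph = model.pka - np.log10(arg) / model.hillslope
    in_range = np.isfinite(r) & (r > model.r_min) & (r < model.r_max)
    ph = np.where(in_range, ph, PH_SENTINEL)
    return float(ph) if np.isscalar(ratio) or r.ndim == 0 else ph


@dataclass(frozen=True)
class FitConfig:
    """Options for :func:`fit_calibration`.

    weighted
        Use per-point weights in the least-squares objective (on by
        default; weights typically carry total reference intensity).
    fallback_hillslopes
        Extra starting hillslopes tried when the data-driven start fails.
    """

    weighted: bool = True
    fallback_hillslopes: tuple[float, ...] = (-2.0, -1.0, 1.0, 2.0)
    max_nfev: int = 10000
    xtol: float = 1e-14
    ftol: float = 1e-14
    gtol: float = 1e-14


def _objective(params, phs, ratios, sqw):
    r_min, r_max, pka, hill = params
    pred = r_min + (r_max - r_min) / (1.0 + 10.0 ** ((pka - phs) * hill))
    return sqw * (ratios - pred)


def fit_calibration(
    points: Sequence[CalibrationPoint], config: FitConfig | None = None
) -> CalibrationModel:
    """Weighted least-squares fit of the four-parameter sigmoid.

    Minimizes sum_i w_i (ratio_i - R(pH_i))^2 over (r_min, r_max, pKa,
    hillslope).  Initialization is data-driven (asymptotes from the ratio
    extremes, pKa from the point nearest the mid-ratio, hillslope +1) with a
    multi-start fallback over hillslope in {-2, -1, 1, 2}.  Deterministic for
    identical inputs and config.
    """
    config = config or FitConfig()
    pts = list(points)
    if len(pts) < 5:
        raise FitError(f"need >= 5 calibration points, got {len(pts)}")
    phs = np.array([p.ph for p in pts])
    if len(np.unique(phs)) < 4:
        raise FitError("need >= 4 distinct pH values")
    ratios = np.array([p.ratio for p in pts])
    weights = np.array([p.weight for p in pts]) if config.weighted else np.ones(len(pts))
    if np.all(weights == 0):
        raise FitError("all point weights are zero")
    sqw = np.sqrt(weights / weights.max())

    r_lo, r_hi = ratios.min(), ratios.max()
    spread = max(r_hi - r_lo, 1e-6)
    mid = (r_lo + r_hi) / 2.0
    pka0 = phs[np.argmin(np.abs(ratios - mid))]
    starts = [(r_lo, r_hi, pka0, 1.0)]
    starts += [(r_lo, r_hi, pka0, h) for h in config.fallback_hillslopes if h != 1.0]

    diagnostics = []
    best = None
    for x0 in starts:
        # widen degenerate asymptote starts so the span is nonzero
        x0 = (x0[0] - 0.05 * spread, x0[1] + 0.05 * spread, x0[2], x0[3])
        try:
            res = least_squares(
                _objective,
                x0,
                args=(phs, ratios, sqw),
                max_nfev=config.max_nfev,
                xtol=config.xtol,
                ftol=config.ftol,
                gtol=config.gtol,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            diagnostics.append({"start": x0, "error": str(exc)})
            continue
        r_min_f, r_max_f, _, _ = res.x
        ok = res.success and r_max_f > r_min_f
        diagnostics.append({"start": x0, "cost": float(res.cost), "success": bool(ok)})
        if ok and (best is None or res.cost < best.cost - 1e-15):
            best = res
        if best is not None and x0 == starts[0] and best.success:
            break  # data-driven start converged; no fallback needed

    if best is None:
        raise FitError("calibration fit did not converge from any start", diagnostics)

    r_min_f, r_max_f, pka_f, hill_f = (float(v) for v in best.x)
    resid = _objective(best.x, phs, ratios, sqw)
    rss = float(np.sum(resid**2))
    stderr = {}
    try:
        jtj = best.jac.T @ best.jac
        dof = max(len(pts) - 4, 1)
        cov = np.linalg.inv(jtj) * (rss / dof)
        for name, var in zip(("r_min", "r_max", "pka", "hillslope"), np.diag(cov)):
            stderr[name] = float(np.sqrt(max(var, 0.0)))
    except np.linalg.LinAlgError:
        pass

    return CalibrationModel(
        r_min=r_min_f,
        r_max=r_max_f,
        pka=pka_f,
        hillslope=hill_f,
        ph_range=(float(phs.min()), float(phs.max())),
        fit_stats=FitStats(
            rss=rss,
            stderr=stderr,
            converged=True,
            n_points=len(pts),
            residuals=tuple(float(r) for r in resid),
        ),
    )


def calibrate_from_images(manifest, pipeline_config=None, fit_config=None) -> CalibrationModel:
    """Build a calibration model from (ChannelPair, pH) image observations.

    For each image: background removal (if configured), reference-threshold
    masking, per-pixel ratioing, and reference-intensity weighting; the
    weighted mean ratio of the image is one observation.  Images sharing a pH
    are averaged (weighted by total reference intensity) into a single
    calibration point whose fit weight is that total intensity.

    Parameters
    ----------
    manifest : sequence of (ChannelPair, float)
        Image pairs with their known buffer pH.
    pipeline_config : PipelineConfig, optional
        Background and threshold settings (see :mod:`nanoph.pipeline`).
    """
    from . import pipeline  # deferred: pipeline imports this module

    cfg = pipeline_config or pipeline.PipelineConfig()
    entries = list(manifest)
    by_ph: dict[float, list] = {}
    for pair, ph in entries:
        by_ph.setdefault(float(ph), []).append(pair)
    if len(by_ph) < 5:
        raise FitError(f"need >= 5 pH levels, got {len(by_ph)}")

    shapes = {p.shape for p, _ in entries}
    if len(shapes) != 1:
        raise ValueError(f"all images must share a shape, got {shapes}")

    points = []
    for ph in sorted(by_ph):
        means, tot_weights, n_pix = [], [], 0
        for pair in by_ph[ph]:
            sub = pair
            if cfg.background is not None:
                sub = pipeline.subtract_background(pair, cfg.background)
            mask = pipeline.build_mask(sub.reference, cfg.threshold)
            if mask.n_pixels == 0:
                pipeline.logger.warning("empty mask at pH %.2f; image excluded", ph)
                continue
            field = pipeline.compute_ratio_field(sub, mask)
            means.append(float(np.sum(field.ratios * field.weights)))
            tot_weights.append(field.total_reference)
            n_pix += field.ratios.size
        if not means:
            raise FitError(f"every image at pH {ph} produced an empty mask")
        w = np.asarray(tot_weights)
        mean_ratio = float(np.sum(np.asarray(means) * w) / w.sum())
        points.append(
            CalibrationPoint(ph=ph, ratio=mean_ratio, weight=float(w.sum()), n_pixels=n_pix)
        )
    return fit_calibration(points, fit_config)


# -- CSV interchange for calibration points ------------------------------


def points_to_csv(points: Iterable[CalibrationPoint], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ph", "ratio", "weight", "n_pixels"])
        for p in points:
            writer.writerow([p.ph, p.ratio, p.weight, p.n_pixels])


def points_from_csv(path: str | Path) -> list[CalibrationPoint]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                CalibrationPoint(
                    ph=float(row["ph"]),
                    ratio=float(row["ratio"]),
                    weight=float(row.get("weight", 1.0)),
                    n_pixels=int(row.get("n_pixels", 0)),
                )
            )
    return out
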