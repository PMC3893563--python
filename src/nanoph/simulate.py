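"""Synthetic two-channel micrographs with known ground truth.

Emulates images of nanosensor-laden cells: an indicator channel whose
expected intensity follows a sum-of-sigmoids pH response (the dual
fluorophore design — an acidic-range dye, pKa 4.8, and a near-neutral dye,
pKa 6.5, with matched emission — keeps the combined response steep across
the whole physiological range) and a pH-insensitive reference channel
proportional to local sensor abundance.  A camera noise model (Poisson shot
noise on expected counts, additive Gaussian read noise, 16-bit quantization)
and per-channel background offsets complete the scene.

Everything is seeded and bit-reproducible; every generator returns the
ground truth alongside the images so pipeline accuracy can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .pipeline import ChannelPair

__all__ = [
    "Fluorophore",
    "SensorResponseSpec",
    "NoiseModel",
    "ScenePhantom",
    "CalibrationFrame",
    "response_curve",
    "simulate_calibration_stack",
    "simulate_cell_scene",
    "simulate_timelapse",
    "simulate_threshold_scene",
    "DEFAULT_DUAL_SPEC",
]


@dataclass(frozen=True)
class Fluorophore:
    """One pH-sensitive dye: sigmoidal contribution to the indicator channel."""

    amplitude: float
    pka: float
    hillslope: float = 1.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class SensorResponseSpec:
    """Expected channel intensities of a sensor pixel as a function of pH.

    indicator(pH) = baseline + sum_f amplitude_f / (1 + 10**((pKa_f - pH) h_f))
    reference(pH) = reference_amplitude  (pH-insensitive by construction)
    """

    fluorophores: tuple[Fluorophore, ...]
    reference_amplitude: float = 1000.0
    baseline: float = 100.0

    def __post_init__(self):
        if self.reference_amplitude <= 0:
            raise ValueError("reference amplitude must be > 0")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")


#: Dual-fluorophore default: equal amplitudes, pKa 4.8 (acidic range) and
#: 6.5 (near neutral), hillslope 1 — the extended-range sensor design.
DEFAULT_DUAL_SPEC = SensorResponseSpec(
    fluorophores=(Fluorophore(900.0, 4.8), Fluorophore(900.0, 6.5)),
    reference_amplitude=1000.0,
    baseline=100.0,
)


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise then Gaussian read noise.

    With ``shot=False`` and ``read_noise_sd=0`` images are the exact
    expected intensities (no quantization), which is what the noiseless
    pipeline-identity tests rely on.
    """

    shot: bool = True
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.read_noise_sd < 0:
            raise ValueError("read noise SD must be >= 0")

    @property
    def is_noiseless(self) -> bool:
        return not self.shot and self.read_noise_sd == 0


@dataclass(frozen=True)
class ScenePhantom:
    """Ground truth for one scene.

    density scales expected per-pixel photon counts (0 = no sensor there);
    truth_ph must be finite wherever density > 0.  bleed_through adds the
    given fraction of the indicator signal into the reference channel.
    """

    truth_ph: np.ndarray
    density: np.ndarray
    background: tuple[float, float] = (0.0, 0.0)  # (indicator, reference)
    bleed_through: float = 0.0

    def __post_init__(self):
        tp = np.asarray(self.truth_ph, dtype=float)
        dn = np.asarray(self.density, dtype=float)
        if tp.shape != dn.shape or tp.ndim != 2:
            raise ValueError("truth_ph and density must be 2-D arrays of equal shape")
        if np.any(dn < 0):
            raise ValueError("density must be >= 0")
        if np.any(~np.isfinite(tp[dn > 0])):
            raise ValueError("truth pH must be finite wherever density > 0")
        if not 0 <= self.bleed_through < 1:
            raise ValueError("bleed-through fraction must be in [0, 1)")
        object.__setattr__(self, "truth_ph", tp)
        object.__setattr__(self, "density", dn)

    @property
    def shape(self):
        return self.truth_ph.shape


def response_curve(spec: SensorResponseSpec, ph):
    """Expected (indicator, reference) intensities at the given pH.

    Vectorized over pH.  Each fluorophore contributes an independent
    sigmoid; the reference is constant.
    """
    ph_arr = np.asarray(ph, dtype=float)
    ind = np.full_like(ph_arr, float(spec.baseline))
    for f in spec.fluorophores:
        ind = ind + f.amplitude / (1.0 + 10.0 ** ((f.pka - ph_arr) * f.hillslope))
    ref = np.full_like(ph_arr, float(spec.reference_amplitude))
    if np.isscalar(ph) or ph_arr.ndim == 0:
        return float(ind), float(ref)
    return ind, ref


def _apply_noise(expected: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    if noise.is_noiseless:
        return expected.astype(float)
    img = expected.astype(float)
    if noise.shot:
        img = rng.poisson(img).astype(float)
    if noise.read_noise_sd > 0:
        img = img + rng.normal(0.0, noise.read_noise_sd, size=img.shape)
    # quantize to the 16-bit camera range
    return np.clip(np.rint(img), 0, 65535)


def _render(phantom: ScenePhantom, spec: SensorResponseSpec, noise: NoiseModel,
            rng: np.random.Generator) -> ChannelPair:
    ph = np.where(phantom.density > 0, phantom.truth_ph, 7.0)  # placeholder off-sensor
    ind_resp, ref_resp = response_curve(spec, ph)
    exp_ind = phantom.density * ind_resp + phantom.background[0]
    exp_ref = phantom.density * ref_resp + phantom.background[1]
    if phantom.bleed_through > 0:
        exp_ref = exp_ref + phantom.bleed_through * phantom.density * ind_resp
    return ChannelPair(
        indicator=_apply_noise(exp_ind, noise, rng),
        reference=_apply_noise(exp_ref, noise, rng),
    )


@dataclass(frozen=True)
class CalibrationFrame:
    pair: ChannelPair
    ph: float
    truth_ratio: float  # analytic indicator/reference of a sensor pixel
    sensor_mask: np.ndarray


def simulate_calibration_stack(
    spec: SensorResponseSpec = DEFAULT_DUAL_SPEC,
    ph_values: Sequence[float] = tuple(np.arange(2.5, 8.01, 0.5)),
    noise: NoiseModel = NoiseModel(),
    shape: tuple[int, int] = (64, 64),
    density: float = 0.1,
) -> list[CalibrationFrame]:
    """One uniform-pH image pair per buffer value, with analytic truth.

    Sensor pixels are placed by a Bernoulli(density) draw; each carries the
    expected intensities of the response curve at that frame's pH, before
    noise.  The same master seed always yields the same stack.
    """
    if len(ph_values) == 0:
        raise ValueError("ph_values must be nonempty")
    rng = np.random.default_rng(noise.seed)
    frames = []
    for ph in ph_values:
        sensor = rng.random(shape) < density
        phantom = ScenePhantom(
            truth_ph=np.full(shape, float(ph)),
            density=sensor.astype(float),
        )
        pair = _render(phantom, spec, noise, rng)
        ind, ref = response_curve(spec, float(ph))
        frames.append(
            CalibrationFrame(pair=pair, ph=float(ph), truth_ratio=ind / ref, sensor_mask=sensor)
        )
    return frames


def simulate_cell_scene(
    phantom: ScenePhantom,
    spec: SensorResponseSpec = DEFAULT_DUAL_SPEC,
    noise: NoiseModel = NoiseModel(),
) -> tuple[ChannelPair, np.ndarray]:
    """Render a phantom into a two-channel image; returns (pair, truth map).

    The truth map is NaN where the phantom holds no sensor.
    """
    rng = np.random.default_rng(noise.seed)
    pair = _render(phantom, spec, noise, rng)
    truth = np.where(phantom.density > 0, phantom.truth_ph, np.nan)
    return pair, truth


def simulate_timelapse(
    phantoms: Sequence[ScenePhantom],
    spec: SensorResponseSpec = DEFAULT_DUAL_SPEC,
    noise: NoiseModel = NoiseModel(),
) -> list[tuple[ChannelPair, np.ndarray]]:
    """Render a phantom sequence (e.g. progressive acidification).

    Per-frame seeds are spawned deterministically from the master seed, so
    frames are independent but the whole series reproduces bit-identically.
    """
    if len(phantoms) < 2:
        raise ValueError("a time series needs >= 2 time points")
    seeds = np.random.SeedSequence(noise.seed).spawn(len(phantoms))
    out = []
    for t, (phantom, ss) in enumerate(zip(phantoms, seeds)):
        rng = np.random.default_rng(ss)
        pair = _render(phantom, spec, noise, rng)
        pair = replace(pair, time_index=t)
        truth = np.where(phantom.density > 0, phantom.truth_ph, np.nan)
        out.append((pair, truth))
    return out


def simulate_threshold_scene(
    r_min: float,
    r_max: float,
    shape: tuple[int, int] = (128, 128),
    n_sensor: int = 500,
    n_noise: int = 2000,
    sensor_reference: float = 1000.0,
    noise_reference: float = 30.0,
    ratio_span: tuple[float, float] = (0.25, 0.75),
    seed: int = 42,
) -> ChannelPair:
    """Two-population scene for exercising the threshold-selection rule.

    ``n_sensor`` bright pixels carry ratios drawn inside the calibration
    range (at fractions ``ratio_span`` of the (r_min, r_max) interval, so
    their inverted pH is comfortably numeric) on a high reference intensity;
    ``n_noise`` dim pixels carry ratios outside the range on a low reference
    intensity.  The correct threshold separates the populations.
    """
    rng = np.random.default_rng(seed)
    n_pix = shape[0] * shape[1]
    if n_sensor + n_noise > n_pix:
        raise ValueError("more pixels requested than the image holds")
    flat_idx = rng.choice(n_pix, size=n_sensor + n_noise, replace=False)
    sensor_idx, noise_idx = flat_idx[:n_sensor], flat_idx[n_sensor:]

    ind = np.zeros(n_pix)
    ref = np.zeros(n_pix)
    span = r_max - r_min
    ratios = r_min + span * rng.uniform(*ratio_span, size=n_sensor)
    ref_s = sensor_reference * rng.uniform(0.8, 1.2, size=n_sensor)
    ref[sensor_idx] = ref_s
    ind[sensor_idx] = ratios * ref_s

    # dim population: half below r_min, half above r_max
    ref_n = noise_reference * rng.uniform(0.5, 1.5, size=n_noise)
    low = rng.random(n_noise) < 0.5
    bad_ratios = np.where(low, r_min * rng.uniform(0.1, 0.9, size=n_noise),
                          r_max * rng.uniform(1.2, 3.0, size=n_noise))
    ref[noise_idx] = ref_n
    ind[noise_idx] = bad_ratios * ref_n

    return ChannelPair(indicator=ind.reshape(shape), reference=ref.reshape(shape))
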