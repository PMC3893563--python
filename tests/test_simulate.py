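"""Synthetic image generation: response curves, noise, scenes, time series."""

import numpy as np
import pytest

from nanoph.calibration import CalibrationModel, forward_response
from nanoph.pipeline import build_mask, compute_ratio_field, make_histogram, ratios_to_ph, summarize
from nanoph.simulate import (
    DEFAULT_DUAL_SPEC,
    CalibrationFrame,
    Fluorophore,
    NoiseModel,
    ScenePhantom,
    SensorResponseSpec,
    response_curve,
    simulate_calibration_stack,
    simulate_cell_scene,
    simulate_timelapse,
)

NOISELESS = NoiseModel(shot=False, read_noise_sd=0.0, seed=0)


# ---------------------------------------------------------------- response curve


def test_single_fluorophore_reduces_to_sigmoid():
    """One term is the calibration sigmoid up to the baseline/amplitude affine map."""
    spec = SensorResponseSpec((Fluorophore(1800.0, 6.5, 1.0),), 1000.0, baseline=200.0)
    m = CalibrationModel(r_min=0.2, r_max=2.0, pka=6.5, hillslope=1.0)
    grid = np.linspace(2.0, 9.0, 40)
    ind, ref = response_curve(spec, grid)
    assert np.allclose(ind / ref, forward_response(m, grid), atol=1e-12)


def test_midpoint_contribution_at_pka():
    ind_at, _ = response_curve(DEFAULT_DUAL_SPEC, 4.8)
    # the pKa-4.8 term contributes exactly half its amplitude at its pKa
    other = 900.0 / (1 + 10 ** (6.5 - 4.8))
    assert ind_at == pytest.approx(100.0 + 450.0 + other, abs=1e-9)


def test_response_curve_matches_term_summation():
    grid = np.linspace(3.0, 8.0, 25)
    ind, ref = response_curve(DEFAULT_DUAL_SPEC, grid)
    manual = np.full_like(grid, 100.0)
    for f in DEFAULT_DUAL_SPEC.fluorophores:
        manual = manual + f.amplitude / (1 + 10.0 ** ((f.pka - grid) * f.hillslope))
    assert np.allclose(ind, manual)
    assert np.all(ref == 1000.0)


def test_dual_curve_monotone_and_sensitive():
    """Pairing pKa 4.8 and 6.5 keeps the response steep across pH 4-7.5."""
    grid = np.linspace(3.0, 8.0, 1001)
    ind, ref = response_curve(DEFAULT_DUAL_SPEC, grid)
    ratio = ind / ref
    assert np.all(np.diff(ratio) >= 0)
    slope = np.gradient(ratio, grid)
    window = (grid >= 4.0) & (grid <= 7.5)
    assert slope[window].min() >= 0.2 * slope.max()


# ---------------------------------------------------------------- calibration stack


def test_noiseless_stack_ratios_exact():
    frames = simulate_calibration_stack(
        DEFAULT_DUAL_SPEC, [4.0, 5.0, 6.0], NOISELESS, shape=(32, 32), density=0.2
    )
    for frame in frames:
        sel = frame.sensor_mask
        ratios = frame.pair.indicator[sel] / frame.pair.reference[sel]
        assert np.allclose(ratios, frame.truth_ratio, atol=1e-12)
        assert np.all(frame.pair.reference[~sel] == 0)


def test_stack_deterministic_given_seed():
    kwargs = dict(ph_values=[4.0, 6.0], shape=(16, 16), density=0.3)
    a = simulate_calibration_stack(noise=NoiseModel(seed=9), **kwargs)
    b = simulate_calibration_stack(noise=NoiseModel(seed=9), **kwargs)
    for fa, fb in zip(a, b):
        assert np.array_equal(fa.pair.indicator, fb.pair.indicator)
        assert np.array_equal(fa.pair.reference, fb.pair.reference)
    c = simulate_calibration_stack(noise=NoiseModel(seed=10), **kwargs)
    assert not np.array_equal(a[0].pair.indicator, c[0].pair.indicator)


def test_noisy_replicates_average_to_expectation():
    """Shot + read noise is unbiased: replicate means approach the clean image."""
    phantom = ScenePhantom(
        truth_ph=np.full((16, 16), 6.0), density=np.ones((16, 16))
    )
    clean, _ = simulate_cell_scene(phantom, noise=NOISELESS)
    n = 300
    acc = np.zeros((16, 16))
    for s in range(n):
        noisy, _ = simulate_cell_scene(phantom, noise=NoiseModel(seed=s))
        acc += noisy.indicator
    mean_img = acc / n
    sd = np.sqrt(clean.indicator)  # Poisson scale
    assert np.all(np.abs(mean_img - clean.indicator) < 5 * sd / np.sqrt(n))


# ---------------------------------------------------------------- scenes


def test_noiseless_scene_pipeline_recovers_truth(model):
    """End-to-end identity: measured pH equals the phantom's truth map."""
    rng = np.random.default_rng(1)
    shape = (40, 40)
    truth = rng.uniform(4.0, 7.5, shape)
    density = (rng.random(shape) < 0.3).astype(float)
    phantom = ScenePhantom(truth_ph=truth, density=density)
    spec = SensorResponseSpec((Fluorophore(1800.0, 6.5, 1.0),), 1000.0, baseline=200.0)
    pair, truth_map = simulate_cell_scene(phantom, spec, NOISELESS)
    field = compute_ratio_field(pair, build_mask(pair.reference, 0.0))
    ph = ratios_to_ph(field, model)
    expected = truth_map[field.coords[:, 0], field.coords[:, 1]]
    assert np.allclose(ph.ph, expected, atol=1e-6)


def test_two_compartment_scene_bimodal_histogram(model):
    shape = (40, 40)
    truth = np.where(np.arange(40)[None, :] < 20, 4.5, 7.0) * np.ones((40, 1))
    phantom = ScenePhantom(truth_ph=truth, density=np.ones(shape))
    spec = SensorResponseSpec((Fluorophore(1800.0, 6.5, 1.0),), 1000.0, baseline=200.0)
    pair, _ = simulate_cell_scene(phantom, spec, NOISELESS)
    field = compute_ratio_field(pair, build_mask(pair.reference, 0.0))
    hist = make_histogram(ratios_to_ph(field, model), bin_width=0.2)
    # the two occupied bins are exactly those containing pH 4.5 and 7.0
    occupied = np.nonzero(hist.masses > 0)[0]
    assert len(occupied) == 2
    lo_bin = int((4.5 - 2.5) / 0.2)
    hi_bin = int((7.0 - 2.5) / 0.2)
    assert set(occupied) == {lo_bin, hi_bin}


def test_bleed_through_control():
    """With zero bleed-through the reference is independent of truth pH."""
    shape = (10, 10)
    acid = ScenePhantom(truth_ph=np.full(shape, 4.0), density=np.ones(shape))
    base = ScenePhantom(truth_ph=np.full(shape, 7.5), density=np.ones(shape))
    ref_a = simulate_cell_scene(acid, noise=NOISELESS)[0].reference
    ref_b = simulate_cell_scene(base, noise=NOISELESS)[0].reference
    assert np.array_equal(ref_a, ref_b)
    bleed_a = ScenePhantom(
        truth_ph=np.full(shape, 4.0), density=np.ones(shape), bleed_through=0.1
    )
    bleed_b = ScenePhantom(
        truth_ph=np.full(shape, 7.5), density=np.ones(shape), bleed_through=0.1
    )
    ref_ba = simulate_cell_scene(bleed_a, noise=NOISELESS)[0].reference
    ref_bb = simulate_cell_scene(bleed_b, noise=NOISELESS)[0].reference
    assert not np.array_equal(ref_ba, ref_bb)


def test_background_offsets_added():
    shape = (8, 8)
    phantom = ScenePhantom(
        truth_ph=np.full(shape, 6.0), density=np.zeros(shape), background=(12.0, 34.0)
    )
    pair, truth = simulate_cell_scene(phantom, noise=NOISELESS)
    assert np.all(pair.indicator == 12.0)
    assert np.all(pair.reference == 34.0)
    assert np.all(np.isnan(truth))


def test_phantom_validation():
    with pytest.raises(ValueError):
        ScenePhantom(truth_ph=np.full((4, 4), np.nan), density=np.ones((4, 4)))
    with pytest.raises(ValueError):
        ScenePhantom(truth_ph=np.ones((4, 4)), density=-np.ones((4, 4)))


# ---------------------------------------------------------------- time series


def _acidification_series(n_frames=4, shape=(24, 24), noise=NOISELESS):
    rng = np.random.default_rng(5)
    density = (rng.random(shape) < 0.4).astype(float)
    trajectory = np.linspace(7.2, 4.6, n_frames)
    phantoms = [
        ScenePhantom(truth_ph=np.full(shape, ph), density=density) for ph in trajectory
    ]
    return simulate_timelapse(phantoms, noise=noise), trajectory


def test_timelapse_monotone_acidification():
    series, _ = _acidification_series()
    means = []
    for pair, _ in series:
        field = compute_ratio_field(pair, build_mask(pair.reference, 0.0))
        means.append(float(np.sum(field.ratios * field.weights)))
    # ratios (hence pH under a monotone calibration) strictly decrease
    assert np.all(np.diff(means) < 0)


def test_timelapse_frames_have_time_indices_and_reproduce():
    series1, _ = _acidification_series(noise=NoiseModel(seed=3))
    series2, _ = _acidification_series(noise=NoiseModel(seed=3))
    for t, ((p1, _), (p2, _)) in enumerate(zip(series1, series2)):
        assert p1.time_index == t
        assert np.array_equal(p1.indicator, p2.indicator)
    # different frames differ (independent per-frame streams)
    assert not np.array_equal(series1[0][0].indicator, series1[1][0].indicator)


def test_timelapse_requires_two_frames():
    phantom = ScenePhantom(truth_ph=np.ones((4, 4)), density=np.ones((4, 4)))
    with pytest.raises(ValueError):
        simulate_timelapse([phantom])
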