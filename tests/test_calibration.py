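"""Sigmoid evaluation, inversion, and least-squares fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanoph.calibration import (
    CalibrationModel,
    CalibrationPoint,
    FitConfig,
    FitError,
    fit_calibration,
    forward_response,
    invert_response,
    points_from_csv,
    points_to_csv,
)
from tests.conftest import BUFFER_PHS


# ---------------------------------------------------------------- forward


@pytest.mark.parametrize(
    "ph,expected",
    [
        (6.5, 1.1),  # midpoint (r_min + r_max) / 2 at pH = pKa
        (7.5, 0.2 + 1.8 / (1 + 10 ** (-1.0))),  # = 1.8363636...
        (5.5, 0.2 + 1.8 / (1 + 10 ** (1.0))),
    ],
)
def test_forward_response_values(model, ph, expected):
    assert forward_response(model, ph) == pytest.approx(expected, abs=1e-12)


def test_forward_response_asymptotes(model):
    assert model.r_max - forward_response(model, 20.0) == pytest.approx(0, abs=1e-9)
    assert forward_response(model, 20.0) < model.r_max
    assert forward_response(model, -10.0) - model.r_min == pytest.approx(0, abs=1e-9)
    assert forward_response(model, -10.0) > model.r_min


def test_forward_response_rejects_nonfinite(model):
    with pytest.raises(ValueError):
        forward_response(model, float("nan"))


@given(
    r_min=st.floats(0.01, 1.0),
    span=st.floats(0.1, 5.0),
    pka=st.floats(3.0, 9.0),
    hillslope=st.floats(0.2, 3.0),
    sign=st.sampled_from([1.0, -1.0]),
)
@settings(max_examples=50, deadline=None)
def test_forward_strictly_monotone(r_min, span, pka, hillslope, sign):
    """Increasing for positive hillslope, decreasing for negative."""
    m = CalibrationModel(r_min, r_min + span, pka, sign * hillslope)
    grid = np.linspace(0.0, 14.0, 1000)
    vals = forward_response(m, grid)
    assert np.all(np.diff(vals) * sign >= 0)
    # strictness holds wherever the response is numerically resolvable
    near = np.linspace(pka - 3 / hillslope, pka + 3 / hillslope, 1000)
    assert np.all(np.diff(forward_response(m, near)) * sign > 0)


# ---------------------------------------------------------------- inverse


def test_invert_midpoint_gives_pka(model):
    assert invert_response(model, 1.1) == pytest.approx(6.5, abs=1e-12)


@pytest.mark.parametrize("ratio", [0.2, 2.0, 0.05, 3.0, float("nan"), float("inf")])
def test_invert_out_of_range_is_sentinel(model, ratio):
    """Ratios at/beyond the asymptotes map to the out-of-range sentinel."""
    assert math.isnan(invert_response(model, ratio))


def test_invert_derived_value(model):
    assert invert_response(model, 1.8363636363636362) == pytest.approx(7.5, abs=1e-9)


@given(frac=st.floats(1e-6, 1 - 1e-6), hillslope=st.sampled_from([1.0, -1.0, 2.5, -0.7]))
@settings(max_examples=100, deadline=None)
def test_round_trip_forward_invert(frac, hillslope):
    m = CalibrationModel(0.2, 2.0, 6.5, hillslope)
    ratio = m.r_min + frac * (m.r_max - m.r_min)
    back = forward_response(m, invert_response(m, ratio))
    assert back == pytest.approx(ratio, rel=1e-9)


def test_invert_vectorized(model):
    out = invert_response(model, np.array([1.1, 0.1, 2.5]))
    assert out[0] == pytest.approx(6.5)
    assert np.isnan(out[1]) and np.isnan(out[2])


# ---------------------------------------------------------------- fitting


def _points_from_model(m, phs, noise=None, rng=None):
    ratios = forward_response(m, np.asarray(phs))
    if noise:
        ratios = ratios + rng.normal(0.0, noise, len(phs))
    return [CalibrationPoint(ph=p, ratio=max(r, 1e-9)) for p, r in zip(phs, ratios)]


def test_fit_recovers_noiseless_parameters(model):
    pts = _points_from_model(model, BUFFER_PHS)
    fit = fit_calibration(pts)
    for name in ("r_min", "r_max", "pka", "hillslope"):
        assert getattr(fit, name) == pytest.approx(getattr(model, name), abs=1e-6)
    assert fit.ph_range == (2.5, 8.0)


def test_fit_recovers_decreasing_response():
    truth = CalibrationModel(0.3, 1.5, 5.5, -1.2)
    fit = fit_calibration(_points_from_model(truth, BUFFER_PHS))
    assert fit.hillslope == pytest.approx(-1.2, abs=1e-6)
    assert fit.pka == pytest.approx(5.5, abs=1e-6)


def test_fit_midpoint_property(model):
    """Any converged fit passes through (r_min + r_max)/2 at pH = pKa."""
    rng = np.random.default_rng(7)
    fit = fit_calibration(_points_from_model(model, BUFFER_PHS, 0.05, rng))
    mid = forward_response(fit, fit.pka)
    assert mid == pytest.approx((fit.r_min + fit.r_max) / 2, rel=1e-12)


def _grid_search_oracle(points, iterations=9, n=9):
    """Independent zooming grid search over the 4-parameter box."""
    phs = np.array([p.ph for p in points])
    ratios = np.array([p.ratio for p in points])
    w = np.array([p.weight for p in points])
    w = w / w.max()

    def sse(r_min, r_max, pka, hill):
        pred = r_min + (r_max - r_min) / (1 + 10.0 ** ((pka - phs) * hill))
        return float(np.sum(w * (ratios - pred) ** 2))

    lo = np.array([0.0, ratios.max(), phs.min(), 0.2])
    hi = np.array([ratios.min(), 2 * ratios.max(), phs.max(), 3.0])
    best = None
    for _ in range(iterations):
        axes = [np.linspace(lo[i], hi[i], n) for i in range(4)]
        for a in axes[0]:
            for b in axes[1]:
                for c in axes[2]:
                    for d in axes[3]:
                        v = sse(a, b, c, d)
                        if best is None or v < best[0]:
                            best = (v, np.array([a, b, c, d]))
        width = (hi - lo) / (n - 1)
        lo = best[1] - width
        hi = best[1] + width
    return best


def test_fit_objective_matches_grid_oracle(model):
    """The optimizer's objective is at least as good as a brute-force scan."""
    rng = np.random.default_rng(3)
    pts = _points_from_model(model, BUFFER_PHS, 0.02, rng)
    fit = fit_calibration(pts)
    oracle_sse, _ = _grid_search_oracle(pts)
    assert fit.fit_stats.rss <= oracle_sse + 1e-6


def test_fit_deterministic(model):
    rng1 = np.random.default_rng(11)
    rng2 = np.random.default_rng(11)
    f1 = fit_calibration(_points_from_model(model, BUFFER_PHS, 0.02, rng1))
    f2 = fit_calibration(_points_from_model(model, BUFFER_PHS, 0.02, rng2))
    assert (f1.r_min, f1.r_max, f1.pka, f1.hillslope) == (
        f2.r_min,
        f2.r_max,
        f2.pka,
        f2.hillslope,
    )


def test_fit_weighting_changes_result(model):
    """Down-weighting a corrupted point pulls the fit back toward truth."""
    pts = _points_from_model(model, BUFFER_PHS)
    corrupted = [
        CalibrationPoint(p.ph, p.ratio * (1.5 if i == 6 else 1.0)) for i, p in enumerate(pts)
    ]
    reweighted = [
        CalibrationPoint(p.ph, p.ratio, weight=(1e-6 if i == 6 else 1.0))
        for i, p in enumerate(corrupted)
    ]
    bad = fit_calibration(corrupted)
    good = fit_calibration(reweighted)
    assert abs(good.pka - model.pka) < abs(bad.pka - model.pka)
    unweighted = fit_calibration(reweighted, FitConfig(weighted=False))
    assert abs(unweighted.pka - model.pka) == pytest.approx(abs(bad.pka - model.pka), abs=1e-6)


@pytest.mark.parametrize(
    "phs",
    [
        [5.0, 6.0, 7.0, 8.0],  # too few points
        [5.0, 5.0, 5.0, 6.0, 6.0],  # too few distinct pH values
    ],
)
def test_fit_input_validation(model, phs):
    pts = [CalibrationPoint(p, forward_response(model, p)) for p in phs]
    with pytest.raises(FitError):
        fit_calibration(pts)


def test_point_invariants():
    with pytest.raises(ValueError):
        CalibrationPoint(ph=5.0, ratio=-1.0)
    with pytest.raises(ValueError):
        CalibrationPoint(ph=5.0, ratio=1.0, weight=-0.1)


def test_model_invariants():
    with pytest.raises(ValueError):
        CalibrationModel(r_min=2.0, r_max=0.2, pka=6.5, hillslope=1.0)
    with pytest.raises(ValueError):
        CalibrationModel(r_min=0.2, r_max=2.0, pka=6.5, hillslope=0.0)


# ---------------------------------------------------------------- serialization


def test_model_json_round_trip(tmp_path, model):
    noisy = fit_calibration(
        _points_from_model(model, BUFFER_PHS, 0.02, np.random.default_rng(5))
    )
    path = tmp_path / "model.json"
    noisy.to_json(path)
    back = CalibrationModel.from_json(path)
    assert back.pka == noisy.pka
    assert back.ph_range == noisy.ph_range
    assert back.fit_stats.rss == noisy.fit_stats.rss


def test_points_csv_round_trip(tmp_path):
    pts = [CalibrationPoint(5.0, 1.2, 3.0, 42), CalibrationPoint(6.0, 1.5)]
    path = tmp_path / "points.csv"
    points_to_csv(pts, path)
    assert path.read_text().splitlines()[0] == "ph,ratio,weight,n_pixels"
    back = points_from_csv(path)
    assert back == pts
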