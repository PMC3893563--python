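# Methods

## Calibration model

The indicator/reference ratio of a pH nanosensor follows a four-parameter
logistic in pH: lower asymptote `r_min`, upper asymptote `r_max`,
inflection `pKa` (the pH of half-maximal response) and `hillslope`
(steepness; negative values model dyes whose emission falls with pH — the
same equation is used unchanged). The forward curve is strictly monotone
for nonzero hillslope and passes through `(r_min + r_max)/2` at `pH = pKa`
by construction.

Fitting minimises the weighted sum of squared ratio residuals with
`scipy.optimize.least_squares`. Initialisation is data-driven — asymptotes
from the observed ratio extremes (widened by 5 % of the spread so the span
is never degenerate), `pKa` from the point nearest the mid-ratio,
hillslope +1 — with a multi-start fallback over hillslope in {−2, −1, 1, 2}
if the first start fails. Convergence tolerances are 1e−14 so the fit is
limited by the data, not the stopping rule; the procedure is deterministic
for identical inputs. Parameter standard errors come from the Gauss–Newton
covariance `(JᵀJ)⁻¹·RSS/(n−4)`.

Weighting is on by default, with weights proportional to each calibration
point's total reference intensity — the same abundance-weighting principle
used per pixel — on the view that a point estimated from more sensor signal
is more reliable. A config flag disables it. When a calibration is built
from images, pixels are averaged (reference-weighted) within an image,
then images within a pH level weighted by their total reference intensity.

## Inversion and the out-of-range sentinel

The inverse curve is defined only for ratios strictly between the
asymptotes. Out-of-range ratios map to NaN rather than a clamped value or
an exception: clamping would fabricate extreme pH readings and an exception
would make routine images unprocessable. Numeric inversions falling outside
the calibrated buffer interval `[ph_lo, ph_hi]` are likewise demoted to the
sentinel — the sigmoid extrapolates smoothly there, but the calibration
data do not vouch for it. In reports the sentinel class is labelled
"pH > 10" and rendered black in colour maps; float TIFF outputs carry NaN
so no fake number enters downstream statistics.

## Measurement pipeline conventions

* Background is a scalar per channel (outside-cell ROI mean, sensor-free
  image mean, or constant). Subtraction clamps negatives to zero and logs
  the clamped fraction so systematic over-subtraction is visible.
* The sensor mask is `reference > threshold` (strict), so raising the
  threshold never adds pixels.
* Automatic threshold selection scans an integer-step grid from 0 to the
  reference maximum and returns the lowest threshold at which more than
  90 % of masked pixels invert to an in-range pH. Pixels are counted
  unweighted. "In range" means ratio strictly inside `(r_min, r_max)` and
  inverted pH inside `[ph_lo, ph_hi]`. The implementation sorts pixels by
  reference intensity once and evaluates every candidate from cumulative
  counts, which is exactly equivalent to the per-threshold scan but linear
  rather than quadratic in image size; the full scan curve is returned for
  diagnostics, and failure raises an error carrying the best achievable
  fraction (the remedy is recalibration over a wider range, not a lower
  bar).
* Masked pixels whose background-subtracted reference is zero cannot be
  ratioed; they are excluded and counted, never assigned infinity.
* Pixel weights are background-subtracted reference intensities normalised
  to unit sum per image, so the pH distribution weights sensors, not
  pixels. Cross-image aggregation re-weights by per-image total reference
  intensity.
* Histograms are weight-mass histograms over the calibrated interval with
  half-open bins `[lo, hi)` (final bin closed; the last edge may overshoot
  `ph_hi` by less than one bin width), plus a separate out-of-range bin;
  total mass is 1 to 1e−12. Default bin width 0.2 pH units.
* Regions are 8-connected components of the mask filtered by a pixel-count
  interval; per-region weighted and unweighted mean pH are both reported,
  as are weighted and unweighted image means, since either may be the
  replication unit of interest.
* Analysis runs in pixel, region, or whole-image mode (the whole-image mode
  averages ratios first and converts once).
* Focus selection in z-stacks is the analyst's responsibility via a
  slice-index setting; automatic focus metrics are out of scope, as are
  registration, flat-field and bleed-through corrections (the simulator can
  generate bleed-through; the pipeline deliberately does not correct it).

## Buffer equilibrium model

A mixture of the two stocks (0.2 M disodium hydrogen phosphate, 0.1 M
citric acid monohydrate) is solved for the pH at which net charge vanishes:
protons, hydroxide, 2 Na⁺ per phosphate formula unit, and the speciation of
both triprotic acids from their pKa ladders. Bisection on pH ∈ [0, 14]
drives the residual below 1e−12 eq/L.

Constants are standard 25 °C reference values (citric 3.13/4.76/6.40,
phosphoric 2.15/7.20/12.35, Kw 1e−14, molar masses 141.96 and
210.14 g/mol); they are package constants, kept in one place in
`buffers.py`. No temperature dependence is modelled.

The solver uses the constant-ionic-medium convention: all equilibria in
concentrations, pH reported as −log₁₀[H⁺], with activity effects entering
through Davies-conditional constants (A = 0.509, the 0.3·I linear term)
iterated on the ionic strength computed from the resulting speciation until
the pH moves < 1e−6. This convention was chosen over the activity-scale
alternative (pH = −log a_H) because it is the standard practice of buffer
recipe calculators and, at the ionic strengths these stocks produce
(I ≈ 0.05–0.6 M, at and beyond Davies' comfortable range), it reproduces
published citrate–phosphate tables markedly better: eleven of the twelve
recipe rows solve within ±0.14 pH of nominal, and the classical pH 7.0
recipe (16.47 ml phosphate per 20 ml) solves to −0.006. The remaining row
of the validation series (17.44 ml phosphate for pH 7.0) deviates by
+0.22; it is also the row most at odds with classical tables and with its
own neighbours (a 3.24 ml step into it, 0.54 ml out of it), so we treat it
as a bench outlier rather than tune the chemistry to it. With the
correction disabled the ideal-solution model runs 0.2–0.75 units basic of
the bench values mid-series — the expected size of activity effects at
these concentrations — so the correction should stay on for recipe work.

Recipe design exploits the strict monotonicity of solved pH in the
phosphate volume fraction (the basic stock): a bracketed Brent root find on
the fraction, to 1e−4 pH. Stock-mass arithmetic uses decimal half-up
rounding to 3 decimals, matching bench weighing conventions.

## Synthetic data

The simulator emulates the dual-fluorophore extended-range sensor: two
pH-sensitive dyes with matched emission but different pKa (defaults 4.8 and
6.5, equal amplitudes 900, hillslope 1, baseline 100) summed into the
indicator channel, and a constant reference amplitude (1000). Equal
amplitudes are a documented default — no quantitative amplitude ratio for
the real dye pair is claimed — chosen so the combined ratio curve is
monotone nondecreasing on pH 3–8 with local sensitivity above 20 % of its
peak across pH 4–7.5, the design goal of pairing the two dyes.

Scenes are rendered from a phantom (per-pixel truth pH, per-pixel sensor
density scaling expected counts, per-channel background, optional
indicator→reference bleed-through fraction). Noise is Poisson shot noise on
expected counts followed by additive Gaussian read noise (default SD 2) and
quantisation to the 16-bit camera range — a standard CCD/sCMOS model. With
noise disabled the expected intensities are returned unquantised, which is
what the exact pipeline-identity tests rely on. Calibration stacks place
sensor pixels by a Bernoulli(density) draw (default 0.1 on 64×64 frames)
at uniform truth pH per buffer. Time series spawn per-frame generators
deterministically from the master seed, so frames are independent but the
series is bit-reproducible.

What the simulator does not emulate: optics (no PSF, the "image" is the
focal plane itself), photobleaching, autofluorescence structure (background
is scalar), chromatic misregistration, and endosomal trafficking kinetics.
Passing tests therefore demonstrate the correctness of the analysis given
registered, in-focus, scalar-background images — not robustness to those
instrument effects, which the protocol controls upstream of analysis.

## Problem sizes and determinism

Test and acceptance runs use desk-scale problems chosen to exercise every
code path: 64–128 px frames, 12-level calibration series, 100-replicate
recovery studies (noise SD 0.02 on ratios, the scale of well-averaged
per-buffer means), 300-replicate noise-averaging checks on 16×16 frames.
All stochastic tests are seeded; the acceptance script derives every stream
from its `--seed` argument via `numpy` seed sequences.

## Known limitations

* The single-sigmoid fit applied to a dual-fluorophore sensor yields an
  apparent pKa between the two dye constants; a two-term sum-of-sigmoids
  is available in the simulator for generating such data, but fitting it
  is intentionally not offered as a measurement path.
* The buffer model's accuracy degrades toward the ends of the series where
  ionic strength leaves Davies territory; residuals up to ~0.2 pH against
  bench tables should be expected and recipes verified with a meter.
* The histogram-from-image-frequency background method referenced in the
  literature is not implemented; background is scalar per channel.
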