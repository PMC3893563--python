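"""Fit a sigmoidal calibration from a synthetic buffer-series image stack.

Simulates the twelve-buffer calibration experiment (pH 2.5-8.0 in 0.5
steps), runs each image through the pipeline (mask, ratio, weight), and
fits the four-parameter sigmoid to the per-buffer mean ratios.
"""

import numpy as np

from nanoph.calibration import calibrate_from_images
from nanoph.simulate import Fluorophore, NoiseModel, SensorResponseSpec, simulate_calibration_stack

# a single near-neutral dye (pKa 6.5) with a pH-insensitive reference
spec = SensorResponseSpec(
    fluorophores=(Fluorophore(amplitude=1800.0, pka=6.5),),
    reference_amplitude=1000.0,
    baseline=200.0,
)

frames = simulate_calibration_stack(
    spec,
    ph_values=np.arange(2.5, 8.01, 0.5),
    noise=NoiseModel(shot=True, read_noise_sd=2.0, seed=1),
    shape=(64, 64),
    density=0.1,
)

model = calibrate_from_images([(f.pair, f.ph) for f in frames])

print(f"r_min     = {model.r_min:.4f}   (lower ratio asymptote; truth 0.20)")
print(f"r_max     = {model.r_max:.4f}   (upper ratio asymptote; truth 2.00)")
print(f"pKa       = {model.pka:.4f}   (half-maximal response; truth 6.50)")
print(f"hillslope = {model.hillslope:.4f}   (steepness; truth 1.00)")
print(f"valid pH range: [{model.ph_range[0]:.1f}, {model.ph_range[1]:.1f}]")
print(f"residual sum of squares: {model.fit_stats.rss:.3e}")
# The fitted parameters sit within ~1% of the generating values: shot +
# read noise on thousands of pixels per buffer barely moves the fit.
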