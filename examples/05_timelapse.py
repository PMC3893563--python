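"""Track progressive acidification in a synthetic time series.

Simulates a cell whose compartments acidify from pH 7.2 to 4.6 over six
frames (the signature of endosomal maturation), measures each frame, and
prints the per-frame weighted mean pH.
"""

import numpy as np

from nanoph.calibration import CalibrationModel
from nanoph.pipeline import build_mask, compute_ratio_field, ratios_to_ph, summarize
from nanoph.simulate import Fluorophore, NoiseModel, ScenePhantom, SensorResponseSpec, simulate_timelapse

model = CalibrationModel(0.2, 2.0, 6.5, 1.0, ph_range=(2.5, 8.0))
spec = SensorResponseSpec((Fluorophore(1800.0, 6.5),), 1000.0, baseline=200.0)

shape = (64, 64)
rng = np.random.default_rng(3)
density = (rng.random(shape) < 0.25).astype(float)
trajectory = np.linspace(7.2, 4.6, 6)
phantoms = [ScenePhantom(truth_ph=np.full(shape, p), density=density) for p in trajectory]

series = simulate_timelapse(phantoms, spec, NoiseModel(seed=3))

print("frame   truth pH   measured weighted mean")
for (pair, _), truth in zip(series, trajectory):
    field = compute_ratio_field(pair, build_mask(pair.reference, 100.0))
    s = summarize(ratios_to_ph(field, model))
    print(f"  {pair.time_index}      {truth:.2f}       {s['weighted_mean_ph']:.3f}")
# The measured means track the acidification trajectory frame by frame;
# residual deviations reflect shot noise on individual pixels.
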