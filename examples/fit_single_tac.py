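"""Fit the RPM1 kinetic model to noisy tissue curves.

Builds a gamma-variate arterial input function (AIF) on a 30 s dynamic-CT
grid, synthesizes tissue time-attenuation curves with known parameters
(MBF 300 mL/min/100 g, delay 2 s, washout 0.15 1/s), adds 15 HU of CT noise
and fits the three-parameter model back — per curve, and on median curves of
25-voxel groups, the aggregation the SLICR map stage uses.
"""

import numpy as np

from ccperf import AIFParams, Rpm1Fitter, forward_tissue_curve, make_aif

times = np.arange(31.0)                       # one frame per second, 30 s
aif = make_aif(AIFParams(amplitude=350.0, onset_s=4.0), times)
truth = forward_tissue_curve(aif, mbf=300.0, delay_s=2.0, k_decay=0.15)

fitter = Rpm1Fitter(aif)
clean = fitter.fit(truth.values)
print(f"noiseless fit        : MBF {clean.params.mbf:5.1f} mL/min/100g "
      f"(truth 300.0; exact recovery)")

rng = np.random.default_rng(0)
single = [fitter.fit(truth.values + rng.normal(0, 15.0, 31)).params.mbf
          for _ in range(50)]
pooled = [fitter.fit(np.median(truth.values + rng.normal(0, 15.0, (25, 31)),
                               axis=0)).params.mbf
          for _ in range(50)]
print(f"single noisy curves  : median MBF {np.median(single):5.1f}, "
      f"IQR {np.percentile(single, 25):.0f}-{np.percentile(single, 75):.0f}")
print(f"median of 25 curves  : median MBF {np.median(pooled):5.1f}, "
      f"IQR {np.percentile(pooled, 25):.0f}-{np.percentile(pooled, 75):.0f}")
print("Single 15-HU-noise voxel fits scatter widely; fitting the median")
print("curve of a ~25-voxel supervoxel (the SLICR map stage) cuts the spread")
print("several-fold. The residual variability reflects the washout/flow")
print("trade-off identifiable only weakly within a 30 s acquisition window;")
print("segment and territory averaging in the AHA report reduce it further.")
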