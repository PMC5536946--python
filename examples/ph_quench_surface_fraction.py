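"""Measure the surface-exposed fraction of a GFP-tagged membrane protein via
pH quenching, and the cytosolic fraction from an x-z slice stack.

A pH 7.4 / pH 4.3 image pair of the same cells is simulated with 70% of each
cell's fluorophores exposed at the surface; acidic buffer quenches the exposed
pool, so the per-cell ratio reports the protected remainder.  Separately, a
slice stack with 40% internal antibody signal is analysed with the 5-px
contour expansion scheme.
"""

import numpy as np

from nanopack.localization import cytosolic_fraction, quench_fraction
from nanopack.simulate import (
    ImagingConfig,
    QuenchGroundTruth,
    simulate_quench_pair,
    simulate_slice_stack,
)

truth = QuenchGroundTruth(surface_fraction=0.7, quench_efficiency=1.0,
                          n_cells=50, seed=11)
i74, i43, mask, _ = simulate_quench_pair(truth, ImagingConfig())
records = quench_fraction(i74, i43, mask, background_region=((0, 6), (0, 6)))
fr = np.array([r.remaining_fraction for r in records])
print(f"cells analysed:            {len(fr)}")
print(f"remaining fraction pH 4.3: {fr.mean():.3f} +- {fr.std(ddof=1)/np.sqrt(len(fr)):.3f} (SEM)")
print(f"ground truth:              {truth.remaining_fraction:.2f} "
      "(= 1 - surface_fraction x quench_efficiency)")

stack = simulate_slice_stack(internal_fraction=0.40, seed=12)
res = cytosolic_fraction(stack)
print(f"cytosolic fraction:        {res.cytosolic_fraction:.3f}  (truth 0.40)")
print()
print("Both assays separate the plasma-membrane pool from internal pools: the")
print("quench ratio uses chemistry, the slice analysis uses geometry (inner")
print("ROI = membrane contour eroded 5 px, outer ROI = dilated 5 px).")
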