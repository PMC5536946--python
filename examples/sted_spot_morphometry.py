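"""Detect and size nanocluster spots on a synthetic STED membrane sheet.

Generates a clustered molecule field at a typical nanocluster density,
simulates antibody labelling under steric shielding, renders the
confocal/STED image pair, and runs the full spot pipeline.
"""

import numpy as np

from nanopack.simulate import (
    AntibodyModel,
    ImagingConfig,
    render_image_pair,
    simulate_antibody_binding,
    simulate_cluster_field,
)
from nanopack.spots import SpotAnalysisParams, analyze_sheet

# a 12.96 um^2 membrane sheet (180 px at 20 nm/px) with ~16 clusters/um^2
field = simulate_cluster_field(16.0, 12.96, seed=42, min_separation_nm=150.0)
field = simulate_antibody_binding(field, AntibodyModel(footprint_diameter_nm=12.0), seed=43)
cfg = ImagingConfig(photon_scale=50.0, rng_seed=44)
confocal, sted = render_image_pair(field, cfg)

params = SpotAnalysisParams.for_mode("cw", maxima_prominence=15.0)
spots, summary = analyze_sheet(sted, confocal, ((0, 20), (0, 20)), params, sheet_id="demo")

print(f"true clusters:        {field.n_clusters}  ({field.n_clusters / field.area_um2:.1f} /um^2)")
print(f"detected spots:       {summary.n_spots}  ({summary.density_per_um2:.1f} /um^2)")
print(f"mean spot intensity:  {summary.mean_spot_intensity:.1f} a.u.")
print(f"mean spot size:       {summary.mean_size_nm:.1f} nm "
      f"(from {summary.n_size_eligible} size-eligible spots)")
print(f"bound antibodies:     {int(field.occupancy.sum())} of {field.n_molecules} epitopes")
print()
print("The recovered density should sit near the generated 16 /um^2; the mean")
print("size reflects the 50-60 nm clusters convolved with the 60 nm STED PSF,")
print("and the low bound fraction shows antibody shielding inside tight clusters.")
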