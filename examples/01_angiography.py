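"""Doppler-variance angiography on a vessel phantom.

Builds a layered-tissue phantom with decorrelating vessel tubes, renders
repeated speckle frames, computes the inter-frame Doppler variance and
projects it en face.  Flow contrast should separate vessels from static
tissue by an order of magnitude.
"""

import numpy as np

from endooct import (
    PhantomGeometry,
    compute_ibdv_volume,
    enface_project,
    make_tissue_scene,
    render_frame_sequence,
)

geometry = PhantomGeometry()  # 256 x 256 x 64, 14 um axial, 4 repeats
scene = make_tissue_scene(geometry, thickness_um=150, vessel_fraction=0.2, seed=0)
volume = render_frame_sequence(scene, decorrelation=1.0, noise_floor=0.05, seed=1)

variance = compute_ibdv_volume(volume.frames.astype(float))
enface = enface_project(variance, z_lo=40, z_hi=100)

inside = variance.sigma2[scene.vessel_mask].mean()
outside = variance.sigma2[~scene.vessel_mask].mean()
print(f"mean sigma^2 inside vessels:  {inside:.4f}")
print(f"mean sigma^2 in static tissue: {outside:.4f}")
print(f"flow contrast ratio:           {inside / outside:.1f}x")
print(f"en-face map: {enface.values.shape}, depth slab {enface.z_bounds}")
# Moving blood decorrelates the speckle between repeated frames, driving
# sigma^2 toward the Rayleigh limit 1 - pi/4 ~ 0.215; static tissue stays
# near zero, so vessels light up in the en-face projection.
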