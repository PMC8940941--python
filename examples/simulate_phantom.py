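"""Generate a neuron phantom movie and measure the speed/SNR trade-off.

Builds a synthetic scene (elliptical somas + dendrites), simulates
GCaMP-like transients, applies dwell-time-dependent photon noise at two
scanning speeds, and prints the per-neuron SNR at each speed.
"""

import numpy as np

from fiberdl.metrics import RoiMask, annulus_background, snr_db
from fiberdl.phantom import (
    ActivityModel,
    NoiseModel,
    PhantomSpec,
    apply_noise_stack,
    generate_scene,
    simulate_activity,
)

scene = generate_scene(PhantomSpec(image_size=64, n_somas=3, seed=42))
movie, traces = simulate_activity(scene, ActivityModel(n_frames=30, seed=43))
noise = NoiseModel(seed=44)

print(f"scene: {len(scene.roi_masks)} neurons, "
      f"{(~scene.background_mask).sum()} structure pixels")
print(f"traces: peak dF/F {traces.max():.2f}")

exclude = ~scene.background_mask
for speed in (1650.0, 3360.0):
    noisy = apply_noise_stack(movie, noise, speed, seed=45)
    snrs = []
    for m in scene.roi_masks:
        roi = RoiMask(mask=m, background_mask=annulus_background(m, exclude=exclude))
        snrs.append(np.mean([snr_db(f, roi) for f in noisy[:10]]))
    print(f"speed {speed:6.0f} spirals/s: mean soma SNR {np.mean(snrs):5.2f} dB")

print(
    "\nDoubling the scanning speed halves the pixel dwell time, raising the "
    "shot-noise level — the quality cost that the restoration networks "
    "recover."
)
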