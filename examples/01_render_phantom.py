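"""Render a synthetic rod-cell scene and report its noise regime.

Builds a single stadium-shaped cell with two diffraction-limited spots,
adds Gaussian white noise at increasing levels, and prints the resulting
SNR labels — the series of conditions under which segmentation is
validated.
"""

import numpy as np

from rodcell import phantom as ph

cell = ph.CellPhantom(center=(48, 32), length=60, width=14)
spots = (ph.SpotPhantom(position=(30.0, 32.0)),
         ph.SpotPhantom(position=(66.0, 32.0)))

print("noise_std   SNR [dB]   (signal = cell contrast over background)")
for std in (10, 30, 60, 90, 120):
    spec = ph.PhantomSpec(image_shape=(64, 96), cells=(cell,), spots=spots,
                          noise_std=float(std), seed=1)
    clean, noisy, truth = ph.render(spec)
    yy, xx = np.mgrid[0:64, 0:96]
    support = truth["cells"][0].contains(np.stack([xx, yy], -1).astype(float))
    db = ph.snr(clean, std, background=spec.background_intensity,
                support=support)
    print(f"{std:9d}   {db:8.1f}")

print()
print("Spot PSNR at noise std 15:",
      f"{ph.psnr(ph.REFERENCE_PSF_AMPLITUDE, 15.0):.2f} dB",
      "(20*log10(A/sigma) for the reference spot amplitude 95.97)")
# The SNR drops by 20*log10(3) ~ 9.5 dB each time the noise std triples;
# at std 120 the cell is barely visible by eye yet still segmentable.
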