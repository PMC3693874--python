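"""Estimate spot intensities: PSF fit versus the naive maximum.

Fits the rotated-2D-Gaussian-plus-offset PSF model to the built-in 5x5
reference kernel (noise-free, then with an 80 gray-level offset), and runs
the 38-spot noisy comparison experiment against the max-intensity baseline.
"""

from rodcell import experiments as ex
from rodcell import phantom as ph

f = ex.fit_reference_kernel(with_offset=False)
print("noise-free kernel:   A = "
      f"{f.amplitude:.4f} (truth {ph.REFERENCE_PSF_AMPLITUDE}), "
      f"B = {f.offset:.4f} (truth 0)")
f = ex.fit_reference_kernel(with_offset=True)
print("kernel + offset 80:  A = "
      f"{f.amplitude:.4f}, B = {f.offset:.4f} (truth 80)")

mae_fit, mae_max = ex.spot_intensity_experiment(seed=0, n_seeds=10)
print()
print("38 spots in cells, additive noise std 15, 10 seeds:")
print(f"  PSF-fit estimator     mean |error| = {mae_fit.mean():6.2f} "
      "gray levels")
print(f"  max-intensity (5x5)   mean |error| = {mae_max.mean():6.2f} "
      "gray levels")
# The PSF fit absorbs the local background into its offset parameter, so
# its error reflects only noise; the raw maximum carries the full ~80
# gray-level cytoplasm offset plus the positive bias of the max statistic.
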