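"""Closed-loop force recovery from synthetic meridional profiles.

Generates a relaxed/contracted reflection pair from a known per-filament
force distribution (mean 300 pN, SD 40 pN), smears it with a Gaussian beam,
adds 0.05%-scale multiplicative noise, and runs the estimation chain the
other way: spacing shift -> plateau strain -> force -> tension.
"""
import numpy as np

import myoxray as mx

beam = mx.BeamModel(fwhm=0.002)
relaxed, contracted, truth = mx.synthetic_experiment(
    mean_force_pN=300.0, sd_force_pN=40.0, n_filaments=300,
    beam=beam, noise_rel_sd=5e-4, seed=42)

est = mx.estimate_from_profiles(relaxed, contracted)
true_mean = truth.forces_pN.mean()
print(f"true mean force:      {true_mean:.1f} pN")
print(f"recovered mean force: {est.mean_force_pN:.1f} pN "
      f"({100*(est.mean_force_pN/true_mean - 1):+.1f}%)")
print(f"recovered tension:    {est.tension_kPa:.1f} kPa")
print(f"mean spacing change:  {est.mean_strain*2.73*1e3:.2f} x10^-3 nm "
      f"(strain {100*est.mean_strain:.3f}%, g = {est.g:.3f})")
# width comparison on the un-smeared pattern (the beam, not the filament
# structure, dominates the order-1 width after convolution)
_, contracted_raw, _ = mx.synthetic_experiment(
    mean_force_pN=300.0, sd_force_pN=40.0, n_filaments=300,
    beam=None, noise_rel_sd=0.0, seed=42)
for order in (1, 2):
    m = mx.peak_top_half_centroid(contracted_raw,
                                  mx.peak_order_window(order, 2.73), order=order)
    print(f"order {order}: relative width {m.fwhm_Z/m.Z_center:.5f} (no beam)")
print("The second order is relatively broader than the first: spacing "
      "nonuniformity along and between filaments grows with reflection order.")
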