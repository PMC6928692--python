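"""Meridional diffraction of a relaxed actin filament.

Builds a uniform 364-monomer filament at the 2.73 nm monomer repeat,
computes its meridional intensity around the first three reflection orders
and reads each peak back with the top-half-centroid estimator.  The printed
spacings (2.73, 1.365, 0.91 nm) are the axial reflection positions of
relaxed vertebrate actin.
"""
import myoxray as mx

filament = mx.uniform_filament(364, 2.73)
for order in (1, 2, 3):
    grid = mx.order_window_grid(order, 2.73)
    profile = mx.meridional_intensity([filament], grid)
    m = mx.peak_top_half_centroid(profile, order=order)
    print(f"order {order}: Z = {m.Z_center:.5f} nm^-1, "
          f"spacing = {m.spacing:.4f} nm, FWHM = {m.fwhm_Z*1e3:.3f} x10^-3 nm^-1")
print("Each order n sits at Z = n/2.73 nm^-1; the FWHM here is the "
      "finite-length (364-monomer) width of a perfectly ordered filament.")
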