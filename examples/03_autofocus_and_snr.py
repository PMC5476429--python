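"""In-line auto-optimization and shot-noise-limited image quality.

The focus index (FI) measures high-spatial-frequency power as the mean
squared difference of two Gaussian smoothings.  Sweeping defocus, fitting
a parabola and jumping to the vertex recovers best focus without pausing
the acquisition; the same scheme corrects stigmation.
"""

from fibsem_phys import image_quality as iq

imager = iq.SimulatedImager(true_focus=0.4, true_stig_x=-0.2, seed=3)
print("before:", {k: round(v, 3) for k, v in imager.settings.items()})
settings = imager.optimize(("focus", "stig_x"), iterations=3)
print("after: ", {k: round(v, 3) for k, v in settings.items()})
print("(true optimum: focus 0.4, stig_x -0.2)\n")

# membrane vs cytosol counts from a typical biased-detector image
n_m, n_c = 720.0, 630.0
snr, contrast = iq.snr_contrast(n_m, n_c)
dose = iq.electrons_per_pixel(current_na=1.0, dwell_us=2.0)
print(f"primary dose: {dose:,.0f} electrons/pixel (1 nA, 2 us)")
print(f"membrane {n_m:.0f} e-, cytosol {n_c:.0f} e- -> "
      f"SNR {snr:.2f}, contrast {100 * contrast:.1f}%")
print("SNR ~3.5 at 13% contrast is marginal for automatic segmentation;")
print("SNR grows with the square root of dose, so 4x dose doubles it.")
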