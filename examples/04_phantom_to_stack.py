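"""From a neuropil phantom to a noisy image stack, and the voxel trade-off.

A Voronoi-cell phantom with stained-lipid membranes is imaged slice by
slice with Poisson shot noise, then binned and dose-thinned to emulate
faster, coarser acquisitions.
"""

import numpy as np

from fibsem_phys import acquisition_sim as aq
from fibsem_phys import image_quality as iq

phantom = aq.generate_phantom(48, voxel_size=4.0, seed=4, n_cells=16)
print("volume fractions:",
      {k: round(v, 3) for k, v in phantom.volume_fractions.items()},
      "(0 = cytosol/resin, 1 = stained membrane)")

config = aq.AcquisitionConfig(current=4.0, dwell=2.0, slice_thickness=4.0,
                              yield_table={0: 0.040, 1: 0.055})
stack = aq.render_stack(phantom, config, seed=5)
mem = stack.values[phantom.labels == 1].mean()
cyt = stack.values[phantom.labels == 0].mean()
snr, contrast = iq.snr_contrast(mem, cyt)
print(f"rendered stack {stack.values.shape}, membrane {mem:.0f} e-, "
      f"cytosol {cyt:.0f} e-, SNR {snr:.1f}")

binned = aq.bin_z(aq.bin_xy(stack, 2), 2)
thinned = aq.thin_dose(stack, p=0.25, seed=6)
print(f"2x2x2 binning -> {binned.values.shape} at "
      f"{binned.pixel_size:.0f} nm pixels")
print(f"dose thinning to 25% -> mean count {thinned.values.mean():.0f} "
      f"(was {stack.values.mean():.0f})")

fi_xy = aq.resliced_focus_index(stack, "xy")
fi_xz = [aq.resliced_focus_index(aq.emulate_anisotropy(stack, k), "xz")
         for k in (1, 2, 4)]
print(f"\nre-sliced xz sharpness vs z-binning 1/2/4: "
      f"{fi_xz[0]:.0f} / {fi_xz[1]:.0f} / {fi_xz[2]:.0f}")
print("z-binning emulates thick physical sections: the imaging plane stays")
print("sharp but any re-sliced view blurs, which is what isotropic voxels")
print("are for.")
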