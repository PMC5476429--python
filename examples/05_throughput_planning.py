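"""Resolution-volume-time planning with the cubic rate law.

At constant signal-to-noise the volume rate scales as dV/dt ~ delta^3 I:
fewer voxels to the third power, and the current the smaller beam spot
supports.  An anchor operating point calibrates absolute times.
"""

from fibsem_phys import acquisition_sim as aq

anchor = aq.DEFAULT_ANCHOR
print(f"anchor: {anchor.volume:,.0f} um^3 at {anchor.delta:.0f} nm voxels, "
      f"{anchor.current:.0f} nA -> {anchor.duration:.0f} days")

ratio = aq.volume_rate(5.5, 4.0) / aq.volume_rate(5.5 / 2, 0.08)
print(f"2x finer voxels (current 4.0 -> 0.08 nA): {ratio:.0f}x slower\n")

for volume, delta in [(8 * 8 * 8, 4.0), (30 * 30 * 60, 10.0),
                      (1e9, 16.0)]:
    days = aq.acquisition_time(volume, delta, anchor.current)
    label = f"{volume:,.0f} um^3 at {delta:.0f} nm"
    print(f"{label:28s} -> {days:10.1f} days ({days / 365:6.2f} years)")

print("\nThe 1 mm^3 (=1e9 um^3) connectomics milestone at 16 nm voxels is")
print("a multi-year single-machine run; the cubic law is why voxel choice")
print("dominates every planning decision.")
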